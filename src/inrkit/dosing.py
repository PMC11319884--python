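"""Rule-based warfarin dose titration with the INR>3 hold/recheck state machine.

Six general principles, applied in priority order at each INR check:

1. INR within ±0.2 of the target limits → dose unchanged.
2. INR below (lower − 0.2) → increase by 0.25 tablets.
3. INR in ((upper + 0.2), 3] → decrease by 0.25 tablets.
4. INR > 3 → stop the drug for 1 day, recheck next day.
5. While holding, next-day INR ≤ 3 → resume at 0.25 tablets below the
   pre-hold dose.
6. While holding, next-day INR > 3 → keep holding, recheck daily.

For wide ranges (upper ≥ 2.8) rule 4 takes precedence over the tail of the
no-change zone, so rule 3's window may be empty; the hold rule is stated
unconditionally.  Doses are in tablets/day at quarter-tablet resolution and
are floored at zero.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import List, Optional, Sequence, Tuple

from .domain import DateLike, RANGE_MARGIN, TargetRange

__all__ = [
    "DoseAction",
    "DoseState",
    "DoseRecommendation",
    "HOLD_INR_CUTOFF",
    "DOSE_STEP",
    "recommend_dose",
    "apply_recommendation",
    "run_titration",
]

logger = logging.getLogger(__name__)

#: INR above this triggers a drug hold regardless of the target range.
HOLD_INR_CUTOFF: float = 3.0

#: Titration step, in tablets/day.
DOSE_STEP: float = 0.25


class DoseAction(Enum):
    NO_CHANGE = "no_change"
    INCREASE_QUARTER = "increase_quarter"
    DECREASE_QUARTER = "decrease_quarter"
    HOLD_ONE_DAY = "hold_one_day"
    CONTINUE_HOLD = "continue_hold"
    RESUME_MINUS_QUARTER = "resume_minus_quarter"


def _quantized(dose: float) -> bool:
    return abs(dose / DOSE_STEP - round(dose / DOSE_STEP)) < 1e-9


@dataclass(frozen=True)
class DoseState:
    """Current prescription state.

    ``dose`` is the prescribed maintenance dose (tablets/day); while
    ``holding`` the patient takes nothing but ``dose`` remembers the
    pre-hold prescription so that resumption can subtract one step from it.
    """

    dose: float
    holding: bool = False
    hold_start: Optional[DateLike] = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose!r}")
        if not _quantized(self.dose):
            raise ValueError(f"dose must be a multiple of {DOSE_STEP} tablets, got {self.dose!r}")
        if self.holding and self.hold_start is None:
            raise ValueError("holding state requires hold_start")


@dataclass(frozen=True)
class DoseRecommendation:
    """Engine output for one INR check.

    ``new_dose`` is the intake going forward (0 while holding); for hold
    actions ``recheck_in_days`` is always 1, otherwise it is ``None`` and the
    monitoring-schedule engine decides the next check.
    """

    action: DoseAction
    new_dose: float
    recheck_in_days: Optional[int] = None

    def __post_init__(self) -> None:
        if self.new_dose < 0 or not _quantized(self.new_dose):
            raise ValueError(f"invalid recommended dose {self.new_dose!r}")
        if self.action in (DoseAction.HOLD_ONE_DAY, DoseAction.CONTINUE_HOLD):
            if self.recheck_in_days != 1:
                raise ValueError("hold actions must recheck in 1 day")


def recommend_dose(inr: float, target: TargetRange, state: DoseState) -> DoseRecommendation:
    """Apply the titration rules to one INR value.

    Raises
    ------
    ValueError
        For non-positive ``inr`` or an inconsistent ``state``.
    """
    if not inr > 0:
        raise ValueError(f"INR must be positive, got {inr!r}")

    if state.holding:
        if inr > HOLD_INR_CUTOFF:
            return DoseRecommendation(DoseAction.CONTINUE_HOLD, 0.0, recheck_in_days=1)
        resumed = max(0.0, state.dose - DOSE_STEP)
        if state.dose - DOSE_STEP < 0:
            logger.warning("resume dose floored at 0 tablets (pre-hold dose %.2f)", state.dose)
        return DoseRecommendation(DoseAction.RESUME_MINUS_QUARTER, resumed)

    if inr > HOLD_INR_CUTOFF:
        return DoseRecommendation(DoseAction.HOLD_ONE_DAY, 0.0, recheck_in_days=1)
    if inr < target.lower - RANGE_MARGIN:
        return DoseRecommendation(DoseAction.INCREASE_QUARTER, state.dose + DOSE_STEP)
    if inr > target.upper + RANGE_MARGIN:
        decreased = max(0.0, state.dose - DOSE_STEP)
        if state.dose - DOSE_STEP < 0:
            logger.warning("decrease floored at 0 tablets (current dose %.2f)", state.dose)
        return DoseRecommendation(DoseAction.DECREASE_QUARTER, decreased)
    return DoseRecommendation(DoseAction.NO_CHANGE, state.dose)


def apply_recommendation(
    state: DoseState, rec: DoseRecommendation, date: Optional[DateLike] = None
) -> DoseState:
    """Thread a recommendation through the prescription state."""
    if rec.action == DoseAction.HOLD_ONE_DAY:
        return replace(state, holding=True, hold_start=date if date is not None else 0)
    if rec.action == DoseAction.CONTINUE_HOLD:
        return state
    if rec.action == DoseAction.RESUME_MINUS_QUARTER:
        return DoseState(dose=rec.new_dose, holding=False, hold_start=None)
    return replace(state, dose=rec.new_dose)


def run_titration(
    inr_stream: Sequence[Tuple[DateLike, float]],
    target: TargetRange,
    initial: DoseState,
) -> List[Tuple[DateLike, DoseRecommendation, DoseState]]:
    """Replay the rule engine over a measurement sequence, threading hold state.

    Returns one ``(date, recommendation, state_after)`` triple per
    measurement; the emitted dose history is reconstructible from the
    actions alone.

    Raises
    ------
    ValueError
        If the stream is not sorted by date.
    """
    from .domain import _date_to_days

    days = [_date_to_days(d) for d, _ in inr_stream]
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("INR stream must be sorted by date")

    out: List[Tuple[DateLike, DoseRecommendation, DoseState]] = []
    state = initial
    for date, inr in inr_stream:
        rec = recommend_dose(inr, target, state)
        state = apply_recommendation(state, rec, date)
        out.append((date, rec, state))
    return out
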