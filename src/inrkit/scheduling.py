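"""INR monitoring-interval ladder.

Monitoring starts weekly after discharge.  Each time two consecutive INR
values at the current interval fall within the patient's target range, the
interval extends by one week (weekly → biweekly → every 3 weeks → every
4 weeks), capped at 4 weeks (at least one check per month).  Any dose
adjustment resets the ladder to weekly until the dose stabilises again.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

__all__ = ["MonitoringState", "MAX_INTERVAL_WEEKS", "next_interval", "schedule_trace"]

#: "At least once a month" cap, encoded in whole weeks (28 days).
MAX_INTERVAL_WEEKS: int = 4


@dataclass(frozen=True)
class MonitoringState:
    """Current testing interval and the in-range streak at that interval."""

    interval_weeks: int = 1
    consecutive_in_range: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.interval_weeks <= MAX_INTERVAL_WEEKS:
            raise ValueError(f"interval must be in [1, {MAX_INTERVAL_WEEKS}] weeks")
        if self.consecutive_in_range not in (0, 1):
            raise ValueError("in-range streak counter must be 0 or 1")


def next_interval(state: MonitoringState, in_range: bool, dose_changed: bool) -> MonitoringState:
    """Advance the monitoring state after one INR check.

    A dose change resets to weekly; an out-of-range value resets the streak
    but keeps the interval; the second consecutive in-range value extends
    the interval by one week up to the 4-week cap.
    """
    if dose_changed:
        return MonitoringState(interval_weeks=1, consecutive_in_range=0)
    if not in_range:
        return MonitoringState(interval_weeks=state.interval_weeks, consecutive_in_range=0)
    if state.consecutive_in_range == 0:
        return MonitoringState(interval_weeks=state.interval_weeks, consecutive_in_range=1)
    return MonitoringState(
        interval_weeks=min(state.interval_weeks + 1, MAX_INTERVAL_WEEKS),
        consecutive_in_range=0,
    )


def schedule_trace(events: Iterable[Tuple[bool, bool]]) -> List[int]:
    """Fold :func:`next_interval` over ``(in_range, dose_changed)`` events.

    Element *k* of the result is the interval (weeks) in effect when
    measurement *k* is taken — i.e. the gap that preceded it — starting from
    the initial weekly state; the state update is applied after each
    measurement.  Four consecutive in-range checks therefore trace
    ``[1, 1, 2, 2]`` with the next check due at 3 weeks.
    """
    state = MonitoringState()
    out: List[int] = []
    for in_range, dose_changed in events:
        out.append(state.interval_weeks)
        state = next_interval(state, in_range, dose_changed)
    return out
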