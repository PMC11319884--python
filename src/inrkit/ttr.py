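"""Rosendaal linear-interpolation time in therapeutic range (TTR).

Between two consecutive INR measurements the INR is modelled as a linear
function of time; each day of the interval is allocated to below-range,
in-range or above-range according to where the interpolated line sits.
TTR is the in-range fraction of the total interpolated person-time.  A TTR
above 65% is the conventional benchmark for effective anticoagulation
management.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

from .domain import INRMeasurement, TargetRange, _date_to_days

__all__ = ["TTRResult", "EffectivenessFlag", "rosendaal_ttr", "is_effective", "EFFECTIVE_TTR_THRESHOLD"]

logger = logging.getLogger(__name__)

#: Conventional benchmark: TTR strictly above 65% counts as effective management.
EFFECTIVE_TTR_THRESHOLD: float = 0.65

SeriesItem = Union[INRMeasurement, Tuple[object, float]]


@dataclass(frozen=True)
class TTRResult:
    """Person-time decomposition of an interpolated INR trajectory.

    ``days_below + days_in + days_above`` equals the total interpolated time
    exactly (the crossing arithmetic is analytic, never discretized).
    ``ttr`` is ``None`` when fewer than two usable measurements leave the
    denominator undefined.
    """

    days_below: float
    days_in: float
    days_above: float
    n_pairs_used: int
    n_pairs_excluded: int
    n_duplicates_dropped: int = 0

    @property
    def total_days(self) -> float:
        return self.days_below + self.days_in + self.days_above

    @property
    def ttr(self) -> Optional[float]:
        total = self.total_days
        if total <= 0:
            return None
        return self.days_in / total

    @property
    def undefined(self) -> bool:
        return self.total_days <= 0


@dataclass(frozen=True)
class EffectivenessFlag:
    """Whether a TTR clears the effectiveness benchmark (strict inequality)."""

    effective: Optional[bool]
    threshold: float = EFFECTIVE_TTR_THRESHOLD

    @property
    def undefined(self) -> bool:
        return self.effective is None


def _segment_split(
    duration: float, i1: float, i2: float, lower: float, upper: float
) -> Tuple[float, float, float]:
    """Split a linear INR segment's duration into (below, in, above) time.

    The segment runs from INR ``i1`` to ``i2`` over ``duration`` days.  The
    crossing times of ``lower`` and ``upper`` are computed in continuous
    days; boundary instants have measure zero so open/closed choices do not
    affect the allocation.
    """
    if i1 == i2:
        if i1 < lower:
            return duration, 0.0, 0.0
        if i1 > upper:
            return 0.0, 0.0, duration
        return 0.0, duration, 0.0

    slope = (i2 - i1) / duration
    t_lower = (lower - i1) / slope
    t_upper = (upper - i1) / slope

    def clip(t: float) -> float:
        return min(max(t, 0.0), duration)

    if slope > 0:
        below = clip(t_lower)
        above = duration - clip(t_upper)
    else:
        below = duration - clip(t_lower)
        above = clip(t_upper)
    inside = duration - below - above
    return below, inside, above


def _coerce_series(series: Iterable[SeriesItem]) -> list[Tuple[float, float]]:
    out: list[Tuple[float, float]] = []
    for item in series:
        if isinstance(item, INRMeasurement):
            out.append((_date_to_days(item.date), float(item.inr)))
        else:
            t, inr = item
            out.append((_date_to_days(t), float(inr)))
    return out


def rosendaal_ttr(
    series: Sequence[SeriesItem],
    target: TargetRange,
    max_gap_days: Optional[float] = None,
) -> TTRResult:
    """Compute the Rosendaal person-time decomposition of an INR series.

    Parameters
    ----------
    series
        INR measurements sorted by date; items are :class:`INRMeasurement`
        or ``(date, inr)`` pairs (dates may be calendar dates or numeric day
        offsets).  Same-day duplicates are collapsed to the last value of the
        day (logged).
    target
        The patient's therapeutic range.
    max_gap_days
        Consecutive pairs further apart than this are excluded from the
        interpolation.  ``None`` (the default) interpolates across any gap,
        as in the original formulation; a cap of 56 days is a common
        alternative elsewhere.

    Each included pair contributes the half-open interval ``[t1, t2)`` so
    consecutive pairs never double-count a day.

    Raises
    ------
    ValueError
        If the series is not sorted by date, or an INR is non-positive.
    """
    pts = _coerce_series(series)
    for _, inr in pts:
        if not inr > 0:
            raise ValueError(f"INR must be positive, got {inr!r}")
    for a, b in zip(pts, pts[1:]):
        if b[0] < a[0]:
            raise ValueError("INR series must be sorted by date")

    # collapse same-day duplicates, keeping the last value of the day
    deduped: list[Tuple[float, float]] = []
    n_dupes = 0
    for t, inr in pts:
        if deduped and deduped[-1][0] == t:
            deduped[-1] = (t, inr)
            n_dupes += 1
        else:
            deduped.append((t, inr))
    if n_dupes:
        logger.warning("dropped %d same-day duplicate INR measurement(s), kept last of day", n_dupes)

    below = inside = above = 0.0
    used = excluded = 0
    for (t1, i1), (t2, i2) in zip(deduped, deduped[1:]):
        duration = t2 - t1
        if max_gap_days is not None and duration > max_gap_days:
            excluded += 1
            continue
        b, i, a = _segment_split(duration, i1, i2, target.lower, target.upper)
        below += b
        inside += i
        above += a
        used += 1

    result = TTRResult(
        days_below=below,
        days_in=inside,
        days_above=above,
        n_pairs_used=used,
        n_pairs_excluded=excluded,
        n_duplicates_dropped=n_dupes,
    )
    if result.undefined:
        logger.info("TTR undefined: fewer than 2 usable measurements span nonzero time")
    return result


def is_effective(
    result: TTRResult, threshold: float = EFFECTIVE_TTR_THRESHOLD
) -> EffectivenessFlag:
    """Flag whether a TTR result clears the benchmark (``ttr > threshold``).

    An undefined TTR yields an undefined flag, which downstream proportions
    must exclude from their denominators.
    """
    ttr = result.ttr
    if ttr is None:
        return EffectivenessFlag(effective=None, threshold=threshold)
    return EffectivenessFlag(effective=bool(ttr > threshold), threshold=threshold)
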