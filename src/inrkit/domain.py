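"""Core warfarin-management domain: indications, INR target ranges, 5-level INR classification.

The anticoagulant intensity of warfarin is measured by the international
normalized ratio (INR).  Each anticoagulation indication carries a target
INR interval; a patient with several indications is managed to the most
intense (highest) of their ranges.  Observed INR values are classified into
five levels — extreme subtherapeutic, subtherapeutic, therapeutic,
supratherapeutic, extreme supratherapeutic — with a 0.2-INR-unit margin
defining the "near-range" sub band and 4.5 the extreme upper cut-off.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Mapping, Optional, Sequence, Union

__all__ = [
    "Indication",
    "TargetRange",
    "INRMeasurement",
    "INRClass",
    "DEFAULT_TARGET_RANGES",
    "RANGE_MARGIN",
    "EXTREME_SUPRA_CUTOFF",
    "resolve_target_range",
    "classify_inr",
]

#: Symmetric margin (INR units) around the target limits used both by the
#: classification bands and by the dose engine's no-change zone.
RANGE_MARGIN: float = 0.2

#: INR above this value is classified as extreme supratherapeutic.
EXTREME_SUPRA_CUTOFF: float = 4.5


class Indication(str, Enum):
    """Anticoagulation indication requiring warfarin therapy."""

    AORTIC_VALVE = "aortic_valve"
    MITRAL_VALVE = "mitral_valve"
    TRICUSPID_VALVE = "tricuspid_valve"
    ATRIAL_FIBRILLATION = "atrial_fibrillation"
    VTE = "vte"


@dataclass(frozen=True, order=True)
class TargetRange:
    """Therapeutic INR interval ``[lower, upper]`` (dimensionless ratio)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(
                f"invalid target range ({self.lower}, {self.upper}): need 0 < lower < upper"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def contains(self, inr: float) -> bool:
        """Strict therapeutic membership (both limits inclusive)."""
        return self.lower <= inr <= self.upper

    def contains_with_margin(self, inr: float, margin: float = RANGE_MARGIN) -> bool:
        """Membership of the widened band ``[lower - margin, upper + margin]``."""
        return self.lower - margin <= inr <= self.upper + margin


#: Default indication -> target range table.  Valve ranges follow the
#: operating centre's long-standing clinical practice and are narrower/lower
#: than some guideline ranges; deployments may override via the ranges config.
DEFAULT_TARGET_RANGES: Mapping[Indication, TargetRange] = {
    Indication.AORTIC_VALVE: TargetRange(1.5, 2.0),
    Indication.MITRAL_VALVE: TargetRange(1.7, 2.5),
    Indication.TRICUSPID_VALVE: TargetRange(2.0, 2.5),
    Indication.ATRIAL_FIBRILLATION: TargetRange(2.0, 3.0),
    Indication.VTE: TargetRange(2.0, 3.0),
}


DateLike = Union[datetime.date, float, int]


@dataclass(frozen=True)
class INRMeasurement:
    """One dated INR observation with the dose in effect when it was drawn.

    ``date`` may be a calendar date or a numeric day offset; all duration
    arithmetic downstream is done in days.  ``dose_in_effect`` is in tablets
    per day at quarter-tablet resolution (the tablet strength in mg is
    deliberately not modelled).
    """

    patient_id: str
    date: DateLike
    inr: float
    dose_in_effect: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.inr > 0:
            raise ValueError(f"INR must be positive, got {self.inr!r}")


class INRClass(IntEnum):
    """Five-level INR classification; ordered from lowest to highest intensity."""

    EXTREME_SUB = 0
    SUB = 1
    THERAPEUTIC = 2
    SUPRA = 3
    EXTREME_SUPRA = 4


def resolve_target_range(
    indications: Sequence[Indication],
    ranges: Optional[Mapping[Indication, TargetRange]] = None,
) -> TargetRange:
    """Resolve a patient's target range from their indication list.

    With multiple indications the most intense range applies: the one with
    the maximal upper limit, ties broken by the maximal lower limit.  The
    result is order-invariant in the input.

    Raises
    ------
    ValueError
        If ``indications`` is empty (the patient cannot be managed).
    """
    if not indications:
        raise ValueError("cannot resolve a target range from an empty indication list")
    table = DEFAULT_TARGET_RANGES if ranges is None else ranges
    resolved = [table[ind] for ind in indications]
    return max(resolved, key=lambda r: (r.upper, r.lower))


def classify_inr(
    inr: float,
    target: TargetRange,
    *,
    extended_therapeutic: bool = False,
) -> INRClass:
    """Classify an INR value against a target range into the five levels.

    Bands (with margin 0.2 and extreme cut-off 4.5)::

        EXTREME_SUB    inr < lower - 0.2
        SUB            lower - 0.2 <= inr < lower
        THERAPEUTIC    lower <= inr <= upper
        SUPRA          upper < inr <= 4.5
        EXTREME_SUPRA  inr > 4.5

    ``extended_therapeutic=True`` moves the band ``(upper, upper + 0.2]``
    from SUPRA into THERAPEUTIC, mirroring the dose engine's no-change zone;
    the default keeps it supratherapeutic.

    Raises
    ------
    ValueError
        For non-positive ``inr``.
    """
    if not inr > 0:
        raise ValueError(f"INR must be positive, got {inr!r}")
    if inr > EXTREME_SUPRA_CUTOFF:
        return INRClass.EXTREME_SUPRA
    if inr < target.lower - RANGE_MARGIN:
        return INRClass.EXTREME_SUB
    if inr < target.lower:
        return INRClass.SUB
    upper_cut = target.upper + RANGE_MARGIN if extended_therapeutic else target.upper
    if inr <= upper_cut:
        return INRClass.THERAPEUTIC
    return INRClass.SUPRA


def _date_to_days(d: DateLike) -> float:
    """Convert a calendar date or numeric day offset to float days."""
    if isinstance(d, datetime.datetime):
        return d.timestamp() / 86400.0
    if isinstance(d, datetime.date):
        return float(d.toordinal())
    return float(d)
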