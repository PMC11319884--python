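"""Two-arm cohort comparison statistics.

Implements the comparison layer of an anticoagulation-management cohort
study: the normality-gated continuous comparison (Kolmogorov–Smirnov gate,
then Student t or Mann–Whitney U), the expected-count-gated categorical
comparison (chi-square with Yates continuity correction, or Fisher exact),
the 5-level INR distribution table with per-row tests, the first-event
clinical outcome table, Kaplan–Meier cumulative-event curves with log-rank
comparison, and the pooled two-proportion sample-size calculation with
attrition inflation.

Per-arm denominators are always taken from the data at analysis time and
never hard-coded.  No multiple-testing adjustment is applied: per-row
p-values are reported unadjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .domain import INRClass, Indication, TargetRange, classify_inr, resolve_target_range

__all__ = [
    "StatTest",
    "GroupComparison",
    "INRDistributionTable",
    "EventCurves",
    "SampleSizeResult",
    "compare_continuous",
    "compare_categorical",
    "inr_distribution",
    "event_summary",
    "cumulative_event_curves",
    "sample_size_two_proportions",
    "percent",
]

EVENT_TYPES = ("minor_bleed", "severe_bleed", "thromboembolic", "death")


class StatTest(Enum):
    T_TEST = "t_test"
    MANN_WHITNEY = "mann_whitney"
    CHI_SQUARE = "chi_square"
    FISHER_EXACT = "fisher_exact"
    LOG_RANK = "log_rank"
    NONE = "none"


@dataclass(frozen=True)
class GroupComparison:
    """One metric compared across two groups: summaries, test used, p-value."""

    metric: str
    summaries: Mapping[str, Mapping[str, float]]
    test: StatTest
    p_value: Optional[float]
    statistic: Optional[float] = None
    note: str = ""


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage recomputed from counts (never stored), rounded half-up."""
    if total <= 0:
        return 0.0
    raw = 100.0 * count / total
    scale = 10 ** decimals
    return math.floor(raw * scale + 0.5) / scale


def compare_continuous(
    x: Sequence[float],
    y: Sequence[float],
    alpha_normality: float = 0.05,
    labels: Tuple[str, str] = ("group1", "group2"),
    metric: str = "",
) -> GroupComparison:
    """Normality-gated two-sample comparison.

    Each sample is tested against a normal distribution with its own fitted
    mean and SD by the Kolmogorov–Smirnov test (plain KS against the fitted
    normal — an approximation, since the parameters are estimated).  If both
    samples pass at ``alpha_normality`` the Student t test is used and the
    groups summarised as mean (SD); otherwise the Mann–Whitney U test with
    median (IQR) summaries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if x.size < 3 or y.size < 3:
        return GroupComparison(
            metric=metric,
            summaries={labels[0]: {"n": x.size}, labels[1]: {"n": y.size}},
            test=StatTest.NONE,
            p_value=None,
            note="insufficient data (n < 3 in a group)",
        )

    def ks_normal_p(sample: np.ndarray) -> float:
        sd = sample.std(ddof=1)
        if sd == 0:
            return 0.0  # degenerate sample is certainly non-normal
        return stats.kstest(sample, "norm", args=(sample.mean(), sd)).pvalue

    both_normal = ks_normal_p(x) > alpha_normality and ks_normal_p(y) > alpha_normality
    if both_normal:
        stat, p = stats.ttest_ind(x, y)
        summaries = {
            lab: {"n": s.size, "mean": float(s.mean()), "sd": float(s.std(ddof=1))}
            for lab, s in zip(labels, (x, y))
        }
        return GroupComparison(metric, summaries, StatTest.T_TEST, float(p), float(stat))
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    summaries = {
        lab: {
            "n": s.size,
            "median": float(np.median(s)),
            "q1": float(np.percentile(s, 25)),
            "q3": float(np.percentile(s, 75)),
        }
        for lab, s in zip(labels, (x, y))
    }
    return GroupComparison(metric, summaries, StatTest.MANN_WHITNEY, float(p), float(stat))


def compare_categorical(
    table: Sequence[Sequence[int]],
    yates: bool = True,
    metric: str = "",
    labels: Tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """2x2 contingency comparison with the conventional test gate.

    Fisher's exact test is used when any expected cell count is below 5 or
    any observed cell is zero (the chi-square approximation is unreliable
    there); otherwise the chi-square test with Yates continuity correction
    (``yates=False`` disables it).  A table with a zero margin is degenerate
    and returns no test.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    row_totals = t.sum(axis=1)
    col_totals = t.sum(axis=0)
    n = t.sum()
    summaries = {
        labels[0]: {"count": int(t[0, 0]), "total": int(row_totals[0]),
                    "percent": percent(int(t[0, 0]), int(row_totals[0]))},
        labels[1]: {"count": int(t[1, 0]), "total": int(row_totals[1]),
                    "percent": percent(int(t[1, 0]), int(row_totals[1]))},
    }
    if (row_totals == 0).any() or (col_totals == 0).any():
        return GroupComparison(metric, summaries, StatTest.NONE, None, note="degenerate table (zero margin)")

    expected = np.outer(row_totals, col_totals) / n
    if (expected < 5).any() or (t == 0).any():
        stat, p = stats.fisher_exact(t)
        return GroupComparison(metric, summaries, StatTest.FISHER_EXACT, float(p), float(stat))
    chi2, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return GroupComparison(metric, summaries, StatTest.CHI_SQUARE, float(p), float(chi2))


@dataclass(frozen=True)
class INRDistributionTable:
    """Per-class INR record counts and percents per arm, with per-row tests.

    ``counts`` is indexed by the five class levels with one column per arm;
    percents are always recomputed from the counts.  Row tests compare each
    class against the rest (2x2).
    """

    counts: pd.DataFrame
    row_tests: Mapping[str, GroupComparison]
    n_excluded: int = 0

    @property
    def percents(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts.apply(
            lambda col: [percent(c, int(totals[col.name])) for c in col], axis=0
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: class x arm with count, percent, and row p-value."""
        pct = self.percents
        rows = []
        for cls in self.counts.index:
            row: Dict[str, object] = {"inr_class": cls}
            for arm in self.counts.columns:
                row[f"count_{arm}"] = int(self.counts.loc[cls, arm])
                row[f"percent_{arm}"] = pct.loc[cls, arm]
            row["p_value"] = self.row_tests[cls].p_value
            row["test"] = self.row_tests[cls].test.value
            rows.append(row)
        return pd.DataFrame(rows)


def _patient_targets(
    registry: pd.DataFrame,
    ranges: Optional[Mapping[Indication, TargetRange]] = None,
) -> Dict[str, TargetRange]:
    targets: Dict[str, TargetRange] = {}
    for _, row in registry.iterrows():
        raw = row["indications"]
        codes = [Indication(c.strip()) for c in str(raw).split(";") if c.strip()]
        if codes:
            targets[str(row["patient_id"])] = resolve_target_range(codes, ranges)
    return targets


def inr_distribution(
    inr_log: pd.DataFrame,
    registry: pd.DataFrame,
    ranges: Optional[Mapping[Indication, TargetRange]] = None,
    arms: Tuple[str, str] = ("non_web", "web"),
    extended_therapeutic: bool = False,
) -> INRDistributionTable:
    """Classify every INR record and tabulate counts per class per arm.

    Records belonging to patients whose target range cannot be resolved are
    excluded (their number is reported on the result).  Each class row gets
    a 2x2 class-vs-rest test across arms.
    """
    targets = _patient_targets(registry, ranges)
    arm_of = dict(zip(registry["patient_id"].astype(str), registry["arm"].astype(str)))

    class_names = [c.name for c in INRClass]
    counts = pd.DataFrame(0, index=class_names, columns=list(arms), dtype=np.int64)
    excluded = 0
    for _, rec in inr_log.iterrows():
        pid = str(rec["patient_id"])
        target = targets.get(pid)
        arm = arm_of.get(pid)
        if target is None or arm not in arms:
            excluded += 1
            continue
        cls = classify_inr(float(rec["inr"]), target, extended_therapeutic=extended_therapeutic)
        counts.loc[cls.name, arm] += 1

    totals = counts.sum(axis=0)
    row_tests: Dict[str, GroupComparison] = {}
    for cls in class_names:
        table = [
            [int(counts.loc[cls, arms[0]]), int(totals[arms[0]] - counts.loc[cls, arms[0]])],
            [int(counts.loc[cls, arms[1]]), int(totals[arms[1]] - counts.loc[cls, arms[1]])],
        ]
        row_tests[cls] = compare_categorical(table, metric=cls, labels=arms)
    return INRDistributionTable(counts=counts, row_tests=row_tests, n_excluded=excluded)


def event_summary(
    events: pd.DataFrame,
    registry: pd.DataFrame,
    arms: Tuple[str, str] = ("non_web", "web"),
) -> Dict[str, GroupComparison]:
    """Per-event-type first-event incidence table with categorical tests.

    Each patient counts at most once per event type.  Denominators are the
    per-arm registry sizes at analysis time.

    Raises
    ------
    ValueError
        If any event references a patient absent from the registry.
    """
    known = set(registry["patient_id"].astype(str))
    if len(events):
        offenders = sorted(set(events["patient_id"].astype(str)) - known)
        if offenders:
            raise ValueError(f"events reference unknown patients: {offenders}")

    arm_of = dict(zip(registry["patient_id"].astype(str), registry["arm"].astype(str)))
    denominators = registry["arm"].astype(str).value_counts().to_dict()

    out: Dict[str, GroupComparison] = {}
    for etype in EVENT_TYPES:
        sub = events[events["event_type"] == etype] if len(events) else events
        affected: Dict[str, set] = {a: set() for a in arms}
        if len(sub):
            for pid in sub["patient_id"].astype(str):
                arm = arm_of[pid]
                if arm in affected:
                    affected[arm].add(pid)
        table = [
            [len(affected[a]), denominators.get(a, 0) - len(affected[a])] for a in arms
        ]
        out[etype] = compare_categorical(table, metric=etype, labels=arms)
    return out


@dataclass(frozen=True)
class EventCurves:
    """Per-arm Kaplan–Meier event-free curves with the log-rank comparison.

    ``curves`` maps arm -> DataFrame with columns ``time`` (days) and
    ``survival`` (event-free probability step function).  ``p_value`` is
    ``None`` when no events occurred in either arm (test skipped).
    """

    event_type: str
    curves: Mapping[str, pd.DataFrame]
    p_value: Optional[float]
    statistic: Optional[float] = None


def cumulative_event_curves(
    events: pd.DataFrame,
    registry: pd.DataFrame,
    event_type: str,
    arms: Tuple[str, str] = ("non_web", "web"),
) -> EventCurves:
    """Time-to-first-event Kaplan–Meier estimate per arm plus log-rank test.

    Follow-up runs from ``enroll_day`` to ``exit_day`` per the registry;
    patients without the event are censored at exit (including death from
    another cause).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    first_event: Dict[str, float] = {}
    if len(events):
        sub = events[events["event_type"] == event_type]
        for pid, grp in sub.groupby(sub["patient_id"].astype(str)):
            first_event[pid] = float(grp["day"].min())

    durations: Dict[str, List[float]] = {a: [] for a in arms}
    observed: Dict[str, List[int]] = {a: [] for a in arms}
    for _, row in registry.iterrows():
        pid = str(row["patient_id"])
        arm = str(row["arm"])
        if arm not in arms:
            continue
        follow = float(row["exit_day"]) - float(row.get("enroll_day", 0.0))
        t_event = first_event.get(pid)
        if t_event is not None and t_event <= follow:
            durations[arm].append(t_event)
            observed[arm].append(1)
        else:
            durations[arm].append(follow)
            observed[arm].append(0)

    curves: Dict[str, pd.DataFrame] = {}
    for arm in arms:
        kmf = KaplanMeierFitter()
        kmf.fit(durations[arm], observed[arm])
        sf = kmf.survival_function_
        curves[arm] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )

    total_events = sum(sum(o) for o in observed.values())
    if total_events == 0:
        return EventCurves(event_type, curves, p_value=None)
    res = logrank_test(
        durations[arms[0]], durations[arms[1]], observed[arms[0]], observed[arms[1]]
    )
    return EventCurves(event_type, curves, float(res.p_value), float(res.test_statistic))


@dataclass(frozen=True)
class SampleSizeResult:
    """Two-proportion sample size with attrition inflation.

    ``n_enrolled_per_group = ceil(n_evaluable / (1 - attrition))`` and
    ``n_total = 2 * n_enrolled_per_group``.
    """

    alpha: float
    power: float
    p1: float
    p2: float
    n_evaluable_per_group: int
    attrition: float
    n_enrolled_per_group: int
    n_total: int

    @classmethod
    def from_evaluable(
        cls,
        n_evaluable: int,
        attrition: float,
        alpha: float = 0.05,
        power: float = 0.80,
        p1: float = float("nan"),
        p2: float = float("nan"),
    ) -> "SampleSizeResult":
        """Attrition-inflation arithmetic from a given evaluable group size."""
        if not 0 <= attrition < 1:
            raise ValueError("attrition must be in [0, 1)")
        enrolled = math.ceil(n_evaluable / (1.0 - attrition))
        return cls(alpha, power, p1, p2, int(n_evaluable), attrition, enrolled, 2 * enrolled)


def sample_size_two_proportions(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    attrition: float = 0.0,
) -> SampleSizeResult:
    """Normal-approximation two-proportion sample size (pooled-variance form).

    Per-group evaluable size for a two-sided test at level ``alpha`` with the
    given power, superiority framing ``p1 > p2``::

        n = ( z_{1-a/2} * sqrt(2 pbar qbar) + z_{power} * sqrt(p1 q1 + p2 q2) )^2
            / (p1 - p2)^2

    then inflated for attrition: ``ceil(n / (1 - attrition))`` enrolled per
    group, doubled for the total.

    Raises
    ------
    ValueError
        Unless ``0 < p2 < p1 < 1`` (the superiority framing is assumed).
    """
    if not (0.0 < p2 < p1 < 1.0):
        raise ValueError("require 0 < p2 < p1 < 1 for the superiority framing")
    if not 0 <= attrition < 1:
        raise ValueError("attrition must be in [0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    pbar = 0.5 * (p1 + p2)
    num = z_a * math.sqrt(2.0 * pbar * (1.0 - pbar)) + z_b * math.sqrt(
        p1 * (1.0 - p1) + p2 * (1.0 - p2)
    )
    n_evaluable = math.ceil((num / (p1 - p2)) ** 2)
    enrolled = math.ceil(n_evaluable / (1.0 - attrition))
    return SampleSizeResult(alpha, power, p1, p2, n_evaluable, attrition, enrolled, 2 * enrolled)
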