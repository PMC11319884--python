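"""End-to-end cohort report assembly.

Glues the layers together: per-patient Rosendaal TTR and effectiveness
flags, the arm-level TTR comparison, the 5-level INR distribution table,
the first-event clinical outcome table and Kaplan–Meier curves — producing
the table set a cohort comparison reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import analysis as an
from .analysis import EVENT_TYPES, GroupComparison, StatTest
from .io import RangesConfig
from .ttr import is_effective, rosendaal_ttr

__all__ = ["CohortReport", "patient_ttr_table", "analyze_cohort"]


@dataclass
class CohortReport:
    """Analysis output: named tables plus per-event-type KM curves."""

    tables: Dict[str, pd.DataFrame]
    curves: Dict[str, Dict[str, pd.DataFrame]]
    ttr_comparison: GroupComparison
    effectiveness_comparison: GroupComparison
    inr_table: "an.INRDistributionTable"
    event_comparisons: Mapping[str, GroupComparison]
    logrank_p: Mapping[str, Optional[float]]


def _day_numbers(dates: pd.Series) -> np.ndarray:
    """ISO date strings (or day offsets) -> float day numbers."""
    if np.issubdtype(dates.dtype, np.number):
        return dates.to_numpy(dtype=float)
    parsed = pd.to_datetime(dates)
    return (parsed - parsed.min()).dt.days.to_numpy(dtype=float) if len(parsed) else np.array([])


def patient_ttr_table(
    inr_log: pd.DataFrame,
    registry: pd.DataFrame,
    config: Optional[RangesConfig] = None,
) -> pd.DataFrame:
    """Per-patient Rosendaal TTR decomposition with the effectiveness flag.

    Columns: patient_id, arm, days_below/in/above, ttr, effective (NaN when
    TTR is undefined, i.e. fewer than two measurements).
    """
    config = config or RangesConfig()
    targets = an._patient_targets(registry, config.ranges)
    arm_of = dict(zip(registry["patient_id"].astype(str), registry["arm"].astype(str)))

    if "day" in inr_log.columns:
        days = inr_log["day"].to_numpy(dtype=float)
    else:
        parsed = pd.to_datetime(inr_log["date"])
        days = (parsed - parsed.min()).dt.days.to_numpy(dtype=float)
    log = inr_log.assign(_day=days)

    rows: List[dict] = []
    for pid, grp in log.groupby(log["patient_id"].astype(str)):
        target = targets.get(pid)
        if target is None:
            continue
        grp = grp.sort_values("_day")
        series = list(zip(grp["_day"], grp["inr"].astype(float)))
        res = rosendaal_ttr(series, target, max_gap_days=config.max_gap_days)
        flag = is_effective(res)
        rows.append(
            {
                "patient_id": pid,
                "arm": arm_of.get(pid, ""),
                "n_measurements": len(series),
                "days_below": res.days_below,
                "days_in": res.days_in,
                "days_above": res.days_above,
                "ttr": np.nan if res.ttr is None else res.ttr,
                "effective": np.nan if flag.undefined else float(flag.effective),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "arm", "n_measurements", "days_below", "days_in",
                 "days_above", "ttr", "effective"],
    )


def analyze_cohort(
    registry: pd.DataFrame,
    inr_log: pd.DataFrame,
    events: pd.DataFrame,
    config: Optional[RangesConfig] = None,
    arms: Tuple[str, str] = ("non_web", "web"),
) -> CohortReport:
    """Run the full two-arm comparison and assemble the report tables."""
    config = config or RangesConfig()

    ttr_table = patient_ttr_table(inr_log, registry, config)
    defined = ttr_table.dropna(subset=["ttr"])
    x = defined.loc[defined["arm"] == arms[0], "ttr"].to_numpy() * 100.0
    y = defined.loc[defined["arm"] == arms[1], "ttr"].to_numpy() * 100.0
    ttr_cmp = an.compare_continuous(x, y, labels=arms, metric="ttr_percent")

    eff = defined.dropna(subset=["effective"])
    eff_table = [
        [int(eff.loc[eff["arm"] == a, "effective"].sum()),
         int((eff["arm"] == a).sum() - eff.loc[eff["arm"] == a, "effective"].sum())]
        for a in arms
    ]
    eff_cmp = an.compare_categorical(eff_table, metric="effective_anticoagulation", labels=arms)

    inr_table = an.inr_distribution(
        inr_log, registry, ranges=config.ranges, arms=arms,
        extended_therapeutic=config.extended_therapeutic,
    )
    event_cmp = an.event_summary(events, registry, arms=arms)

    curves: Dict[str, Dict[str, pd.DataFrame]] = {}
    logrank_p: Dict[str, Optional[float]] = {}
    for etype in EVENT_TYPES:
        ec = an.cumulative_event_curves(events, registry, etype, arms=arms)
        curves[etype] = dict(ec.curves)
        logrank_p[etype] = ec.p_value

    def _cmp_row(c: GroupComparison) -> dict:
        row: dict = {"metric": c.metric, "test": c.test.value, "p_value": c.p_value}
        for arm in arms:
            for k, v in c.summaries[arm].items():
                row[f"{k}_{arm}"] = v
        return row

    tables = {
        "ttr_per_patient": ttr_table,
        "ttr_comparison": pd.DataFrame([_cmp_row(ttr_cmp), _cmp_row(eff_cmp)]),
        "inr_distribution": inr_table.to_frame(),
        "clinical_events": pd.DataFrame(
            [_cmp_row(event_cmp[e]) | {"logrank_p": logrank_p[e]} for e in EVENT_TYPES]
        ),
    }
    return CohortReport(
        tables=tables,
        curves=curves,
        ttr_comparison=ttr_cmp,
        effectiveness_comparison=eff_cmp,
        inr_table=inr_table,
        event_comparisons=event_cmp,
        logrank_p=logrank_p,
    )
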