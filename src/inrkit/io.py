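"""Readers, writers and configuration for the anticoagulation pipeline.

File formats are deliberately plain: CSV for the INR log, registry and
event log (the domain has no standard interchange format), JSON or YAML for
the ranges/engine configuration.  Dates are ISO-8601 calendar dates; all
durations are days internally.  Report writing is deterministic and emits a
manifest of SHA-256 checksums so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .domain import DEFAULT_TARGET_RANGES, INRMeasurement, Indication, TargetRange

__all__ = [
    "RangesConfig",
    "load_ranges",
    "read_inr_log",
    "read_registry",
    "read_events",
    "write_cohort",
    "write_report",
    "inr_log_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RangesConfig:
    """Target-range table plus engine switches, overridable per deployment.

    ``boundary_policy`` selects whether the band ``(upper, upper+0.2]``
    counts as supratherapeutic (default) or therapeutic;
    ``schedule_in_range`` selects whether the monitoring ladder judges
    "in range" against the strict range (default) or the ±0.2 band.
    """

    version: int = 1
    ranges: Mapping[Indication, TargetRange] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_RANGES)
    )
    boundary_policy: str = "supra"  # "supra" | "therapeutic"
    max_gap_days: Optional[float] = None
    schedule_in_range: str = "strict"  # "strict" | "margin"

    @property
    def extended_therapeutic(self) -> bool:
        return self.boundary_policy == "therapeutic"


_ALLOWED_TOP_KEYS = {"version", "ranges", "engine"}
_ALLOWED_ENGINE_KEYS = {"boundary_policy", "max_gap_days", "schedule_in_range"}


def load_ranges(path: Optional[Union[str, Path]] = None) -> RangesConfig:
    """Load a ranges/engine config (JSON or YAML by extension).

    Omitted indications fall back to the built-in defaults; unknown keys or
    invalid range values are rejected.
    """
    if path is None:
        return RangesConfig()
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - _ALLOWED_TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")

    ranges = dict(DEFAULT_TARGET_RANGES)
    for code, bounds in (data.get("ranges") or {}).items():
        try:
            ind = Indication(code)
        except ValueError:
            raise ValueError(f"{path}: unknown indication code {code!r}") from None
        if not (isinstance(bounds, (list, tuple)) and len(bounds) == 2):
            raise ValueError(f"{path}: range for {code!r} must be [lower, upper]")
        ranges[ind] = TargetRange(float(bounds[0]), float(bounds[1]))

    engine = data.get("engine") or {}
    unknown = set(engine) - _ALLOWED_ENGINE_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown engine keys {sorted(unknown)}")
    boundary = engine.get("boundary_policy", "supra")
    if boundary not in ("supra", "therapeutic"):
        raise ValueError(f"{path}: boundary_policy must be 'supra' or 'therapeutic'")
    sched = engine.get("schedule_in_range", "strict")
    if sched not in ("strict", "margin"):
        raise ValueError(f"{path}: schedule_in_range must be 'strict' or 'margin'")
    gap = engine.get("max_gap_days")
    return RangesConfig(
        version=int(data.get("version", 1)),
        ranges=ranges,
        boundary_policy=boundary,
        max_gap_days=None if gap is None else float(gap),
        schedule_in_range=sched,
    )


def _parse_date(raw: str, path: Path, line_no: int) -> datetime.date:
    try:
        return datetime.date.fromisoformat(raw.strip())
    except ValueError:
        raise ValueError(f"{path}:{line_no}: unparseable ISO-8601 date {raw!r}") from None


def read_inr_log(path: Union[str, Path]) -> List[INRMeasurement]:
    """Read an INR log CSV (``patient_id,date,inr[,dose_tablets]``).

    Rows are sorted per patient by date and same-day duplicates collapsed to
    the last value of the day (logged).  Malformed rows raise with their
    line number.
    """
    path = Path(path)
    measurements: List[INRMeasurement] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        required = {"patient_id", "date", "inr"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        for row in reader:
            line_no = reader.line_num
            pid = (row.get("patient_id") or "").strip()
            if not pid:
                raise ValueError(f"{path}:{line_no}: empty patient_id")
            date = _parse_date(row["date"] or "", path, line_no)
            try:
                inr = float(row["inr"])
            except (TypeError, ValueError):
                raise ValueError(f"{path}:{line_no}: unparseable INR {row.get('inr')!r}") from None
            if inr <= 0:
                raise ValueError(f"{path}:{line_no}: non-positive INR {inr}")
            dose_raw = (row.get("dose_tablets") or "").strip()
            dose = float(dose_raw) if dose_raw else None
            measurements.append(INRMeasurement(pid, date, inr, dose))

    # sort per patient by date, preserving input order within a day
    measurements.sort(key=lambda m: (m.patient_id, m.date))
    deduped: List[INRMeasurement] = []
    n_dupes = 0
    for m in measurements:
        if deduped and deduped[-1].patient_id == m.patient_id and deduped[-1].date == m.date:
            deduped[-1] = m
            n_dupes += 1
        else:
            deduped.append(m)
    if n_dupes:
        logger.warning("%s: collapsed %d same-day duplicate measurement(s)", path, n_dupes)
    return deduped


def inr_log_to_frame(measurements: Sequence[INRMeasurement]) -> pd.DataFrame:
    """Measurement list -> the DataFrame schema the analysis layer consumes."""
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in measurements],
            "date": [m.date.isoformat() if isinstance(m.date, datetime.date) else m.date
                     for m in measurements],
            "inr": [m.inr for m in measurements],
            "dose_tablets": [m.dose_in_effect for m in measurements],
        }
    )


def read_registry(path: Union[str, Path]) -> pd.DataFrame:
    """Read the patient registry CSV; validates required columns."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "arm", "indications"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"{path}: duplicate patient ids {dupes}")
    if "enroll_day" not in df.columns:
        df["enroll_day"] = 0
    if "exit_day" not in df.columns:
        if {"enroll_date", "exit_date"} <= set(df.columns):
            enroll = pd.to_datetime(df["enroll_date"])
            exit_ = pd.to_datetime(df["exit_date"])
            df["exit_day"] = (exit_ - enroll).dt.days
        else:
            raise ValueError(f"{path}: need exit_day or enroll_date/exit_date columns")
    return df


def read_events(path: Union[str, Path]) -> pd.DataFrame:
    """Read the clinical-event CSV; validates required columns."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "event_type", "day"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")


def write_cohort(cohort, out_dir: Union[str, Path]) -> Dict[str, str]:
    """Write a simulated cohort as registry/inr_log/events CSVs + provenance.

    The provenance JSON embeds the full simulation config so any cohort can
    be regenerated.  Returns the file->sha256 manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_frame(cohort.registry, out_dir / "registry.csv")
    _write_frame(cohort.inr_log.drop(columns=["day"]), out_dir / "inr_log.csv")
    _write_frame(cohort.events, out_dir / "events.csv")
    cfg = dataclasses.asdict(cohort.config)
    (out_dir / "provenance.json").write_text(
        json.dumps(cfg, indent=2, sort_keys=True, default=str) + "\n"
    )
    return _manifest(out_dir, ["registry.csv", "inr_log.csv", "events.csv", "provenance.json"])


def _manifest(out_dir: Path, names: Sequence[str]) -> Dict[str, str]:
    manifest = {name: _sha256(out_dir / name) for name in sorted(names)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def write_report(
    tables: Mapping[str, pd.DataFrame],
    curves: Mapping[str, Mapping[str, pd.DataFrame]],
    out_dir: Union[str, Path],
) -> Dict[str, str]:
    """Write analysis tables and KM curve points as CSVs with a manifest.

    ``tables`` maps name -> DataFrame (one CSV each); ``curves`` maps event
    type -> arm -> step-function DataFrame.  Output is deterministic: the
    same inputs always yield an identical manifest.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out_dir}: {exc}") from exc

    names: List[str] = []
    for name in sorted(tables):
        fname = f"{name}.csv"
        _write_frame(tables[name], out_dir / fname)
        names.append(fname)
    for etype in sorted(curves):
        for arm in sorted(curves[etype]):
            fname = f"km_{etype}_{arm}.csv"
            _write_frame(curves[etype][arm], out_dir / fname)
            names.append(fname)
    return _manifest(out_dir, names)
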