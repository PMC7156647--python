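"""Cohort CSV reading and writing.

One row per patient, column names exactly matching the
:class:`~chorscore.records.PatientRecord` field names; missing values are
empty cells.  A YAML units sidecar must declare the dFLC units
(``dflc_units: mg/dL`` or ``mg/L``) — unit conversion is explicit, never
guessed from magnitudes.  The simulator writes the same dialect, so
generated cohorts exercise the identical I/O path as external data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .errors import CohortValidationError
from .records import PatientRecord

__all__ = ["read_cohort", "write_cohort", "CohortValidationReport", "REQUIRED_COLUMNS"]

_BOOL_COLUMNS = (
    "heart_involved",
    "kidney_involved",
    "liver_involved",
    "on_dialysis_at_baseline",
    "baseline_ifix_negative",
    "baseline_flc_ratio_normal",
    "landmark_ifix_negative",
    "landmark_flc_ratio_normal",
    "os_event",
    "dialysis_event",
)

_FLOAT_COLUMNS = (
    "baseline_dflc",
    "landmark_dflc",
    "baseline_ntprobnp",
    "landmark_ntprobnp",
    "baseline_proteinuria",
    "landmark_proteinuria",
    "baseline_egfr",
    "landmark_egfr",
    "baseline_alp",
    "landmark_alp",
    "os_time",
    "dialysis_time",
    "landmark_months",
)

REQUIRED_COLUMNS = ("patient_id",) + _BOOL_COLUMNS + _FLOAT_COLUMNS

#: descriptive columns tolerated in a cohort file but not used by the model
OPTIONAL_COLUMNS = ("age", "sex", "assessment_months")

_DFLC_COLUMNS = ("baseline_dflc", "landmark_dflc")

#: half-width (months) of the acceptable assessment window around the landmark
LANDMARK_WINDOW = 2.0


@dataclass
class CohortValidationReport:
    """Per-row soft issues discovered while reading a cohort."""

    n_rows: int = 0
    issues: list[str] = field(default_factory=list)
    ineligible_ids: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.issues


def _parse_bool(value, column: str, row_id: str) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool,)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "t", "1.0"):
        return True
    if s in ("false", "0", "no", "f", "0.0"):
        return False
    raise CohortValidationError(
        f"row {row_id}: cannot parse boolean {column}={value!r}"
    )


def _load_units(units: Union[str, Path, dict, None], csv_path: Path) -> dict:
    if isinstance(units, dict):
        return units
    if units is None:
        sidecar = csv_path.with_suffix(csv_path.suffix + ".units.yaml")
        if not sidecar.exists():
            raise CohortValidationError(
                f"units undeclared: no sidecar found at {sidecar}; pass a units "
                "mapping or sidecar path declaring dflc_units"
            )
        units = sidecar
    with open(units) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise CohortValidationError(f"units sidecar {units} is not a mapping")
    return loaded


def read_cohort(
    path: Union[str, Path],
    units: Union[str, Path, dict, None] = None,
) -> tuple[list[PatientRecord], CohortValidationReport]:
    """Read and validate a cohort CSV into typed patient records.

    ``units`` may be a mapping, a path to a YAML sidecar, or ``None`` to
    look for ``<path>.units.yaml``.  Hard failures (missing or unknown
    columns, undeclared units, unparsable or negative values) raise
    :class:`CohortValidationError` listing every offending item; soft
    issues (missing organ involvement, assessment outside the landmark
    window, follow-up shorter than the landmark) go into the returned
    report, and the affected ids into ``report.ineligible_ids``.
    """
    path = Path(path)
    if not path.exists():
        raise CohortValidationError(f"cohort file not found: {path}")
    units_map = _load_units(units, path)
    dflc_units = units_map.get("dflc_units")
    if dflc_units not in ("mg/dL", "mg/L"):
        raise CohortValidationError(
            f"dflc_units must be declared as 'mg/dL' or 'mg/L', got {dflc_units!r}"
        )

    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    unknown = [
        c for c in df.columns if c not in REQUIRED_COLUMNS and c not in OPTIONAL_COLUMNS
    ]
    problems = [f"missing required column: {c}" for c in missing]
    problems += [f"unknown column: {c}" for c in unknown]
    if problems:
        raise CohortValidationError(f"invalid cohort file {path}", problems)

    if dflc_units == "mg/L":
        for c in _DFLC_COLUMNS:
            df[c] = df[c] / 10.0  # 1 mg/dL = 10 mg/L

    records: list[PatientRecord] = []
    report = CohortValidationReport(n_rows=len(df))
    negative_items: list[str] = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        kwargs: dict = {"patient_id": pid}
        for c in _BOOL_COLUMNS:
            kwargs[c] = _parse_bool(row[c], c, pid)
        for c in ("heart_involved", "kidney_involved", "liver_involved",
                  "on_dialysis_at_baseline"):
            kwargs[c] = bool(kwargs[c])
        for c in _FLOAT_COLUMNS:
            v = row[c]
            kwargs[c] = None if pd.isna(v) else float(v)
        if kwargs["landmark_months"] is None:
            kwargs["landmark_months"] = 6.0
        rec = PatientRecord(**kwargs)
        for msg in rec.validate():
            if "negative" in msg:
                negative_items.append(f"row {pid}: {msg}")
            else:
                report.issues.append(f"row {pid}: {msg}")
                report.ineligible_ids.append(pid)
        if rec.os_time is not None and rec.os_time < rec.landmark_months:
            report.issues.append(
                f"row {pid}: follow-up ({rec.os_time}) shorter than landmark "
                f"({rec.landmark_months}); not analysis-eligible"
            )
            report.ineligible_ids.append(pid)
        if "assessment_months" in df.columns and not pd.isna(row["assessment_months"]):
            off = abs(float(row["assessment_months"]) - rec.landmark_months)
            if off > LANDMARK_WINDOW:
                report.issues.append(
                    f"row {pid}: assessment at {row['assessment_months']} months is "
                    f"outside the landmark window ±{LANDMARK_WINDOW}"
                )
                report.ineligible_ids.append(pid)
        records.append(rec)

    if negative_items:
        raise CohortValidationError(
            f"negative biomarker values in {path}", negative_items
        )
    report.ineligible_ids = sorted(set(report.ineligible_ids))
    return records, report


def write_cohort(
    df: pd.DataFrame, path: Union[str, Path], dflc_units: str = "mg/dL"
) -> Path:
    """Write a cohort table plus its units sidecar; returns the sidecar path."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".units.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"dflc_units": dflc_units}, fh)
    return sidecar
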