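"""Domain types for per-patient response assessment.

A :class:`PatientRecord` holds one patient's baseline and landmark biomarker
values together with organ-involvement flags and survival follow-up.  Values
measured in the clinic but absent from the chart are represented as ``None``
(never zero): evaluability rules downstream depend on the distinction.

Units follow the conventions of the field: dFLC in mg/dL (1 mg/dL = 10 mg/L),
NT-proBNP in pg/mL, 24-h proteinuria in mg, eGFR in mL/min/1.73 m2, alkaline
phosphatase in U/L, all times in months from start of treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class HematologicResponse(str, Enum):
    """Depth of plasma-cell clone response."""

    CR = "CR"
    VGPR = "VGPR"
    PR = "PR"
    NR = "NR"


class OrganStatus(str, Enum):
    """Response status of a single involved organ at the landmark."""

    RESPONSE = "RESPONSE"
    NO_RESPONSE = "NO_RESPONSE"
    NOT_EVALUABLE = "NOT_EVALUABLE"


@dataclass(frozen=True)
class HematologicCategory:
    """Hematologic response category plus the pathway used to reach it.

    Patients presenting with baseline dFLC below the measurable-disease
    cutoff (5 mg/dL) are assessed by complete-response criteria only; for
    them ``category`` can only be CR or NR, and the composite score treats
    a non-CR differently from a standard-pathway NR.
    """

    category: HematologicResponse
    low_dflc_pathway: bool = False

    def __post_init__(self):
        if self.low_dflc_pathway and self.category in (
            HematologicResponse.VGPR,
            HematologicResponse.PR,
        ):
            raise ValueError(
                "low-dFLC pathway admits only CR or NR, got "
                f"{self.category.value}"
            )


# biomarker fields that must be non-negative when present
_NONNEGATIVE_FIELDS = (
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
)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's baseline + landmark biomarkers and follow-up."""

    patient_id: str

    # organ involvement (diagnosis-time; an input, never inferred here)
    heart_involved: bool = False
    kidney_involved: bool = False
    liver_involved: bool = False
    on_dialysis_at_baseline: bool = False

    # hematologic markers
    baseline_dflc: Optional[float] = None  # mg/dL
    landmark_dflc: Optional[float] = None
    baseline_ifix_negative: Optional[bool] = None  # serum AND urine
    baseline_flc_ratio_normal: Optional[bool] = None
    landmark_ifix_negative: Optional[bool] = None
    landmark_flc_ratio_normal: Optional[bool] = None

    # organ markers
    baseline_ntprobnp: Optional[float] = None  # pg/mL
    landmark_ntprobnp: Optional[float] = None
    baseline_proteinuria: Optional[float] = None  # mg/24h
    landmark_proteinuria: Optional[float] = None
    baseline_egfr: Optional[float] = None  # mL/min/1.73m2
    landmark_egfr: Optional[float] = None
    baseline_alp: Optional[float] = None  # U/L
    landmark_alp: Optional[float] = None

    # follow-up
    os_time: Optional[float] = None  # months from treatment start
    os_event: Optional[bool] = None  # death
    dialysis_time: Optional[float] = None
    dialysis_event: Optional[bool] = None
    landmark_months: float = 6.0

    def validate(self) -> list[str]:
        """Return a list of validation messages (empty when clean)."""
        problems: list[str] = []
        for name in _NONNEGATIVE_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                problems.append(f"{name} is negative ({v})")
        if not (self.heart_involved or self.kidney_involved or self.liver_involved):
            problems.append("no major organ (heart/kidney/liver) involved")
        if self.os_time is not None and self.os_time < 0:
            problems.append(f"os_time is negative ({self.os_time})")
        if self.landmark_months <= 0:
            problems.append(f"landmark_months must be positive ({self.landmark_months})")
        return problems

    @property
    def involved_organs(self) -> tuple[str, ...]:
        out = []
        if self.heart_involved:
            out.append("heart")
        if self.kidney_involved:
            out.append("kidney")
        if self.liver_involved:
            out.append("liver")
        return tuple(out)


@dataclass(frozen=True)
class ResponseAssessment:
    """Bundle of hematologic + per-organ statuses at one landmark."""

    patient_id: str
    hematologic: HematologicCategory
    cardiac: OrganStatus
    renal: OrganStatus
    liver: OrganStatus
    landmark_months: float = 6.0

    @property
    def organ_statuses(self) -> tuple[OrganStatus, OrganStatus, OrganStatus]:
        return (self.cardiac, self.renal, self.liver)
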