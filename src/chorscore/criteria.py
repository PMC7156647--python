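"""Hematologic and per-organ response classifiers.

The classifiers implement the consensus response criteria used in AL
amyloidosis trials, applied at a fixed landmark (6 or 12 months) after the
start of first-line therapy:

* hematologic: CR (negative serum + urine immunofixation and normal free
  light-chain ratio), VGPR (landmark dFLC < 4 mg/dL), PR (>= 50% dFLC
  reduction), otherwise NR.  Patients with baseline dFLC < 5 mg/dL lack
  measurable disease for the graded criteria and are assessed for CR only.
* cardiac: NT-proBNP decrease > 30% AND > 300 pg/mL, evaluable only when
  baseline NT-proBNP >= 650 pg/mL.
* renal: proteinuria decrease >= 30% (or landmark proteinuria < 500 mg/24h)
  without a >= 25% decline in eGFR; patients on dialysis at baseline are
  not evaluable.
* liver: alkaline phosphatase decrease >= 50%.

Every threshold lives in :class:`ResponseThresholds` so the criteria can be
audited or overridden in one place.  Relative ("%") thresholds named ``>=``
are inclusive; the cardiac ``>`` thresholds are strict, matching the wording
of the criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ClassificationError, CohortValidationError
from .records import (
    HematologicCategory,
    HematologicResponse,
    OrganStatus,
    PatientRecord,
    ResponseAssessment,
)

__all__ = [
    "ResponseThresholds",
    "DEFAULT_THRESHOLDS",
    "classify_hematologic",
    "classify_cardiac",
    "classify_renal",
    "classify_liver",
    "assess_patient",
]


@dataclass(frozen=True)
class ResponseThresholds:
    """All response-criteria cutoffs, in the units of the source markers."""

    low_dflc_cutoff: float = 5.0  # mg/dL; below => CR-only assessment
    vgpr_dflc: float = 4.0  # mg/dL landmark dFLC
    pr_fraction: float = 0.5  # >= 50% dFLC reduction
    cardiac_rel_drop: float = 0.30  # strict >
    cardiac_abs_drop: float = 300.0  # pg/mL, strict >
    cardiac_eval_floor: float = 650.0  # baseline NT-proBNP evaluability
    renal_proteinuria_drop: float = 0.30  # inclusive >=
    renal_proteinuria_floor: float = 500.0  # mg/24h, strict <
    renal_egfr_decline: float = 0.25  # inclusive >= disqualifies
    liver_alp_fraction: float = 0.5  # landmark <= 0.5 x baseline


DEFAULT_THRESHOLDS = ResponseThresholds()


def _require_nonnegative(rec: PatientRecord, *names: str) -> None:
    bad = [
        f"{n}={getattr(rec, n)}"
        for n in names
        if getattr(rec, n) is not None and getattr(rec, n) < 0
    ]
    if bad:
        raise CohortValidationError(
            f"patient {rec.patient_id}: negative biomarker value(s)", bad
        )


def classify_hematologic(
    rec: PatientRecord, thresholds: ResponseThresholds = DEFAULT_THRESHOLDS
) -> HematologicCategory:
    """Classify depth of hematologic response at the landmark.

    Patients with baseline dFLC below ``thresholds.low_dflc_cutoff`` are
    assessed by CR criteria only (``low_dflc_pathway=True``): non-CR is
    recorded as NR but is scored separately by the composite model.
    """
    _require_nonnegative(rec, "baseline_dflc", "landmark_dflc")
    if rec.baseline_dflc is None:
        raise ClassificationError(
            f"patient {rec.patient_id}: baseline dFLC is required for "
            "hematologic classification"
        )

    is_cr = bool(rec.landmark_ifix_negative) and bool(rec.landmark_flc_ratio_normal)

    if rec.baseline_dflc < thresholds.low_dflc_cutoff:
        if rec.landmark_ifix_negative is None or rec.landmark_flc_ratio_normal is None:
            raise ClassificationError(
                f"patient {rec.patient_id}: landmark immunofixation and FLC "
                "ratio are required for the low-dFLC (CR-only) pathway"
            )
        cat = HematologicResponse.CR if is_cr else HematologicResponse.NR
        return HematologicCategory(cat, low_dflc_pathway=True)

    if is_cr:
        return HematologicCategory(HematologicResponse.CR, low_dflc_pathway=False)
    if rec.landmark_dflc is None:
        raise ClassificationError(
            f"patient {rec.patient_id}: landmark dFLC is required for "
            "graded (VGPR/PR) hematologic classification"
        )
    if rec.landmark_dflc < thresholds.vgpr_dflc:
        cat = HematologicResponse.VGPR
    elif rec.landmark_dflc <= thresholds.pr_fraction * rec.baseline_dflc:
        cat = HematologicResponse.PR
    else:
        cat = HematologicResponse.NR
    return HematologicCategory(cat, low_dflc_pathway=False)


def classify_cardiac(
    rec: PatientRecord, thresholds: ResponseThresholds = DEFAULT_THRESHOLDS
) -> OrganStatus:
    """NT-proBNP-based cardiac response (strict >30% AND >300 pg/mL drop)."""
    if not rec.heart_involved:
        return OrganStatus.NOT_EVALUABLE
    _require_nonnegative(rec, "baseline_ntprobnp", "landmark_ntprobnp")
    if rec.baseline_ntprobnp is None or rec.landmark_ntprobnp is None:
        return OrganStatus.NOT_EVALUABLE
    if rec.baseline_ntprobnp < thresholds.cardiac_eval_floor:
        return OrganStatus.NOT_EVALUABLE
    drop = rec.baseline_ntprobnp - rec.landmark_ntprobnp
    if (
        drop > thresholds.cardiac_abs_drop
        and drop > thresholds.cardiac_rel_drop * rec.baseline_ntprobnp
    ):
        return OrganStatus.RESPONSE
    return OrganStatus.NO_RESPONSE


def classify_renal(
    rec: PatientRecord, thresholds: ResponseThresholds = DEFAULT_THRESHOLDS
) -> OrganStatus:
    """Proteinuria/eGFR-based renal response; dialysis at baseline excludes."""
    if not rec.kidney_involved:
        return OrganStatus.NOT_EVALUABLE
    if rec.on_dialysis_at_baseline:
        return OrganStatus.NOT_EVALUABLE
    _require_nonnegative(
        rec,
        "baseline_proteinuria",
        "landmark_proteinuria",
        "baseline_egfr",
        "landmark_egfr",
    )
    if (
        rec.baseline_proteinuria is None
        or rec.landmark_proteinuria is None
        or rec.baseline_egfr is None
        or rec.landmark_egfr is None
    ):
        return OrganStatus.NOT_EVALUABLE

    if rec.baseline_proteinuria > 0:
        prot_drop = (
            rec.baseline_proteinuria - rec.landmark_proteinuria
        ) / rec.baseline_proteinuria
        prot_ok = prot_drop >= thresholds.renal_proteinuria_drop
    else:
        prot_ok = False
    prot_ok = prot_ok or rec.landmark_proteinuria < thresholds.renal_proteinuria_floor

    if rec.baseline_egfr > 0:
        egfr_decline = (rec.baseline_egfr - rec.landmark_egfr) / rec.baseline_egfr
    else:
        egfr_decline = 0.0
    egfr_ok = egfr_decline < thresholds.renal_egfr_decline

    return OrganStatus.RESPONSE if (prot_ok and egfr_ok) else OrganStatus.NO_RESPONSE


def classify_liver(
    rec: PatientRecord, thresholds: ResponseThresholds = DEFAULT_THRESHOLDS
) -> OrganStatus:
    """Alkaline-phosphatase-based liver response (>= 50% drop, inclusive)."""
    if not rec.liver_involved:
        return OrganStatus.NOT_EVALUABLE
    _require_nonnegative(rec, "baseline_alp", "landmark_alp")
    if rec.baseline_alp is None or rec.landmark_alp is None:
        return OrganStatus.NOT_EVALUABLE
    if rec.landmark_alp <= thresholds.liver_alp_fraction * rec.baseline_alp:
        return OrganStatus.RESPONSE
    return OrganStatus.NO_RESPONSE


def assess_patient(
    rec: PatientRecord, thresholds: ResponseThresholds = DEFAULT_THRESHOLDS
) -> ResponseAssessment:
    """Run all four classifiers on one record.

    Uninvolved organs come back NOT_EVALUABLE.  Classifier errors are
    re-raised with the patient id attached.
    """
    try:
        hematologic = classify_hematologic(rec, thresholds)
        cardiac = classify_cardiac(rec, thresholds)
        renal = classify_renal(rec, thresholds)
        liver = classify_liver(rec, thresholds)
    except (ClassificationError, CohortValidationError):
        raise
    except Exception as exc:  # pragma: no cover - defensive context wrapper
        raise ClassificationError(f"patient {rec.patient_id}: {exc}") from exc
    return ResponseAssessment(
        patient_id=rec.patient_id,
        hematologic=hematologic,
        cardiac=cardiac,
        renal=renal,
        liver=liver,
        landmark_months=rec.landmark_months,
    )
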