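"""End-to-end analysis: classify, score, analyze, report.

`run_analysis` applies the response classifiers and composite score to a
validated cohort, mirrors the consort flow (every input patient is either
scored or excluded with a reason code), and produces the landmark survival
analyses that validate the composite model: overall survival by combined
organ response (all patients, >1 major organ, heart-involved subsets),
overall survival by composite group with a Cox hazard ratio, paired
concordance comparisons of the composite against hematologic-CR and
all-organ-response classifications, and dialysis-free survival by renal
response.  Percentages are rendered as round-half-away-from-zero integers
with explicit numerator/denominator.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .composite import (
    CHORGroup,
    CHORResult,
    CombinedOR,
    CombinedORCategory,
    chor_score,
    combine_organ_responses,
)
from .criteria import DEFAULT_THRESHOLDS, ResponseThresholds, assess_patient
from .errors import ClassificationError, CohortValidationError, EstimationError, ScoringError
from .records import HematologicResponse, OrganStatus, PatientRecord, ResponseAssessment
from .survival import (
    SurvivalSummary,
    compare_c,
    cox_binary,
    dialysis_free_survival,
    km_estimate,
    logrank_test,
)

__all__ = ["run_analysis", "write_report", "score_cohort", "percent", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"

log = logging.getLogger("chorscore")


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounding half away from zero (45/119 -> 38)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _pct_block(numerator: int, denominator: int) -> dict:
    return {
        "percent": percent(numerator, denominator),
        "numerator": int(numerator),
        "denominator": int(denominator),
    }


def _summary_to_dict(s: SurvivalSummary) -> dict:
    return {
        "n": s.n,
        "n_events": s.n_events,
        "median_os": s.median,  # null == not reached
        "median_not_reached": s.median is None,
        "median_ci": list(s.median_ci),
    }


def _survival_block(times, events, labels, label_order) -> dict:
    """KM per group + pairwise/overall log-rank + Cox HRs vs the first label."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    block: dict = {"groups": {}, "n_per_group": {}}
    present = [g for g in label_order if (labels == g).any()]
    for g in present:
        m = labels == g
        block["n_per_group"][g] = int(m.sum())
        block["groups"][g] = _summary_to_dict(km_estimate(times[m], events[m]))
    if len(present) < 2:
        block["logrank_p"] = None
        block["non_separating"] = True
        return block
    lr = logrank_test(times, events, labels)
    block["logrank_p"] = lr.p
    block["logrank_statistic"] = lr.statistic
    block["non_separating"] = False
    ref = present[0]
    block["hazard_ratios_vs_" + str(ref)] = {}
    for g in present[1:]:
        m = (labels == ref) | (labels == g)
        try:
            cox = cox_binary(times[m], events[m], (labels[m] == g).astype(int))
            block["hazard_ratios_vs_" + str(ref)][g] = {
                "hazard_ratio": None if not cox.finite else cox.hazard_ratio,
                "ci": list(cox.ci),
                "p": None if not cox.finite else cox.p,
                "finite": cox.finite,
            }
        except (EstimationError, ValueError) as exc:
            block["hazard_ratios_vs_" + str(ref)][g] = {"error": str(exc)}
    return block


def score_cohort(
    records: Sequence[PatientRecord],
    thresholds: ResponseThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Classify and score every record; one row per input patient.

    Patients that cannot be scored keep a row with an ``exclusion_reason``
    so that consort accounting (n input = n scored + n excluded) holds.
    """
    rows = []
    for rec in records:
        row: dict = {"patient_id": rec.patient_id, "exclusion_reason": None}
        try:
            a = assess_patient(rec, thresholds)
        except (ClassificationError, CohortValidationError) as exc:
            row["exclusion_reason"] = f"hematologic_not_evaluable: {exc}"
            rows.append(row)
            continue
        combined = combine_organ_responses(a)
        row.update(
            hematologic_category=a.hematologic.category.value,
            low_dflc=a.hematologic.low_dflc_pathway,
            cardiac_status=a.cardiac.value,
            renal_status=a.renal.value,
            liver_status=a.liver.value,
            combined_or=combined.category.value,
        )
        if combined.category is CombinedORCategory.NOT_EVALUABLE:
            row["exclusion_reason"] = "no_evaluable_organ"
            rows.append(row)
            continue
        result = chor_score(a)
        row.update(
            hr_points=result.hr_points,
            or_points=result.or_points,
            chor_total=result.total,
            chor_group=result.group.value,
        )
        log.debug(
            "patient %s: HR %s (low_dflc=%s) + OR %s -> score %d (%s)",
            rec.patient_id, a.hematologic.category.value,
            a.hematologic.low_dflc_pathway, combined.category.value,
            result.total, result.group.value,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(
    records: Sequence[PatientRecord],
    thresholds: ResponseThresholds = DEFAULT_THRESHOLDS,
    config_fingerprint: Optional[dict] = None,
) -> dict:
    """Produce the full analysis report for a validated cohort."""
    if not records:
        raise CohortValidationError("empty cohort")
    scored = score_cohort(records, thresholds)
    ok = scored["exclusion_reason"].isna()
    if not ok.any():
        raise CohortValidationError(
            "zero scoreable patients",
            [
                f"{pid}: {reason}"
                for pid, reason in zip(scored["patient_id"], scored["exclusion_reason"])
            ],
        )

    by_id = {r.patient_id: r for r in records}
    n_input = len(records)
    excl = scored.loc[~ok, "exclusion_reason"].str.split(":").str[0]
    exclusions = excl.value_counts().to_dict()

    sd = scored[ok].reset_index(drop=True)
    recs = [by_id[p] for p in sd["patient_id"]]
    times = np.array([r.os_time for r in recs], dtype=float)
    events = np.array([bool(r.os_event) for r in recs])
    n = len(sd)

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "consort": {
            "n_input": n_input,
            "n_scored": int(n),
            "n_excluded": int(n_input - n),
            "exclusion_reasons": {k: int(v) for k, v in exclusions.items()},
        },
    }

    # --- cohort summary + response rates --------------------------------
    heart = np.array([r.heart_involved for r in recs])
    kidney = np.array([r.kidney_involved for r in recs])
    liver = np.array([r.liver_involved for r in recs])
    n_major = heart.astype(int) + kidney.astype(int) + liver.astype(int)
    report["cohort_summary"] = {
        "n": int(n),
        "heart_involved": _pct_block(int(heart.sum()), n),
        "kidney_involved": _pct_block(int(kidney.sum()), n),
        "liver_involved": _pct_block(int(liver.sum()), n),
        "more_than_one_major_organ": _pct_block(int((n_major > 1).sum()), n),
        "low_dflc": _pct_block(int(sd["low_dflc"].sum()), n),
    }

    std = ~sd["low_dflc"]
    n_std = int(std.sum())
    hr_rates = {}
    for cat in ("CR", "VGPR", "PR", "NR"):
        m = std & (sd["hematologic_category"] == cat)
        hr_rates[cat] = _pct_block(int(m.sum()), n_std) if n_std else None
    low_cr = int((sd["low_dflc"] & (sd["hematologic_category"] == "CR")).sum())
    n_low = int(sd["low_dflc"].sum())
    or_rates = {
        cat: _pct_block(int((sd["combined_or"] == cat).sum()), n)
        for cat in ("AOR", "MOR", "NOR")
    }
    cr_depth = (sd["hematologic_category"] == "CR")  # includes low-dFLC CR
    or_by_cr = {
        cat: _pct_block(int((cr_depth & (sd["combined_or"] == cat)).sum()), int(cr_depth.sum()))
        for cat in ("AOR", "MOR", "NOR")
    } if cr_depth.any() else None
    report["response_rates"] = {
        "hematologic_standard_pathway": hr_rates,
        "n_standard_pathway": n_std,
        "low_dflc_cr": _pct_block(low_cr, n_low) if n_low else None,
        "combined_or": or_rates,
        "combined_or_given_cr": or_by_cr,
    }

    # --- composite distribution -----------------------------------------
    report["chor_distribution"] = {
        "per_score": {
            int(s): int((sd["chor_total"] == s).sum()) for s in range(6)
        },
        "per_group": {
            g: int((sd["chor_group"] == g).sum()) for g in ("GROUP1", "GROUP2")
        },
    }

    # --- survival contrasts ----------------------------------------------
    or_labels = sd["combined_or"].to_numpy()
    order = ("AOR", "MOR", "NOR")
    survival_blocks = {
        "os_by_combined_or_overall": _survival_block(times, events, or_labels, order),
    }
    m = n_major > 1
    if m.any():
        survival_blocks["os_by_combined_or_multiorgan"] = _survival_block(
            times[m], events[m], or_labels[m], order
        )
    if heart.any():
        survival_blocks["os_by_combined_or_heart_involved"] = _survival_block(
            times[heart], events[heart], or_labels[heart], order
        )
    survival_blocks["os_by_chor_group"] = _survival_block(
        times, events, sd["chor_group"].to_numpy(), ("GROUP1", "GROUP2")
    )
    report["survival_blocks"] = survival_blocks

    # --- concordance comparisons ------------------------------------------
    group2 = (sd["chor_group"] == "GROUP2").astype(float).to_numpy()
    not_cr = (sd["hematologic_category"] != "CR").astype(float).to_numpy()
    not_aor = (sd["combined_or"] != "AOR").astype(float).to_numpy()
    concordance = {}
    for name, other in (("chor_vs_hr_cr", not_cr), ("chor_vs_aor", not_aor)):
        try:
            cc = compare_c(group2, other, times, events)
            concordance[name] = {
                "c_chor": cc.c_a,
                "c_other": cc.c_b,
                "delta": cc.delta,
                "delta_ci": list(cc.delta_ci),
                "p": cc.p,
            }
        except EstimationError as exc:
            concordance[name] = {"error": str(exc)}
    report["concordance_blocks"] = concordance

    # --- dialysis-free survival -------------------------------------------
    renal_eval = sd["renal_status"].isin(["RESPONSE", "NO_RESPONSE"]).to_numpy()
    if renal_eval.any():
        flags = (sd["renal_status"] == "RESPONSE").to_numpy()
        try:
            dfree = dialysis_free_survival(recs, flags)
            report["dialysis_free"] = {
                "s60_responders": dfree.s60_responders,
                "s60_nonresponders": dfree.s60_nonresponders,
                "logrank_p": dfree.logrank_p,
                "no_dialysis_events": dfree.no_events,
                "n_responders": dfree.responders.n,
                "n_nonresponders": dfree.nonresponders.n,
            }
        except EstimationError as exc:
            report["dialysis_free"] = {"error": str(exc)}

    # --- provenance --------------------------------------------------------
    fingerprint = config_fingerprint or {}
    digest = hashlib.sha256(
        json.dumps(fingerprint, sort_keys=True, default=str).encode()
    ).hexdigest()
    report["provenance"] = {
        "software_version": __version__,
        "config": fingerprint,
        "config_hash": digest,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    log.info(
        "analysis complete: %d scored, %d excluded", n, n_input - n
    )
    return report


def write_report(report: dict, outdir: Union[str, Path], scored: Optional[pd.DataFrame] = None) -> Path:
    """Write report.json and per-table CSVs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    tables = outdir / "tables"
    tables.mkdir(exist_ok=True)

    rows = []
    for cat, blk in report["response_rates"]["combined_or"].items():
        rows.append({"category": cat, **blk})
    pd.DataFrame(rows).to_csv(tables / "combined_or_rates.csv", index=False)

    dist = report["chor_distribution"]["per_score"]
    pd.DataFrame(
        {"score": list(dist), "n": list(dist.values())}
    ).to_csv(tables / "chor_score_distribution.csv", index=False)

    if scored is not None:
        scored.to_csv(tables / "scored_cohort.csv", index=False)
    return report_path
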