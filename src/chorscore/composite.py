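"""The composite hematologic + organ response (CHOR) score.

Per-organ statuses are first collapsed into a combined organ-response
category — AOR (response in all involved, evaluable major organs), MOR
(response in some), NOR (response in none) — and the combined category is
added to the hematologic depth on a single 0-5 point scale:

====================  ======  ====================  ======
hematologic           points  combined organ resp.  points
====================  ======  ====================  ======
CR                    0       AOR                   0
VGPR                  1       MOR                   1
PR                    2       NOR                   2
NR / progression      3
====================  ======  ====================  ======

Patients assessed on the low-dFLC (CR-only) pathway score 0 for CR and 1
for any other outcome, because their survival resembles that of VGPR.
The published two-group partition is scores 0-3 (group 1) versus 4-5
(group 2); :func:`build_grouping` reproduces the construction of that
partition from score-specific hazards on any scored cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError, ScoringError
from .records import HematologicCategory, HematologicResponse, OrganStatus, ResponseAssessment

__all__ = [
    "CombinedORCategory",
    "CombinedOR",
    "CHORGroup",
    "CHORResult",
    "GroupingRule",
    "combine_organ_responses",
    "hematologic_points",
    "organ_points",
    "chor_score",
    "build_grouping",
    "mayo2012_stage",
    "PUBLISHED_GROUP1_MAX",
]

#: maximum score in group 1 under the published partition (0-3 | 4-5)
PUBLISHED_GROUP1_MAX = 3


class CombinedORCategory(str, Enum):
    AOR = "AOR"
    MOR = "MOR"
    NOR = "NOR"
    NOT_EVALUABLE = "NOT_EVALUABLE"


@dataclass(frozen=True)
class CombinedOR:
    category: CombinedORCategory
    n_evaluable: int
    n_responding: int


class CHORGroup(str, Enum):
    GROUP1 = "GROUP1"
    GROUP2 = "GROUP2"


@dataclass(frozen=True)
class CHORResult:
    hr_points: int
    or_points: int
    total: int
    group: CHORGroup


_HR_POINTS_STANDARD = {
    HematologicResponse.CR: 0,
    HematologicResponse.VGPR: 1,
    HematologicResponse.PR: 2,
    HematologicResponse.NR: 3,
}

_OR_POINTS = {
    CombinedORCategory.AOR: 0,
    CombinedORCategory.MOR: 1,
    CombinedORCategory.NOR: 2,
}


def combine_organ_responses(assessment: ResponseAssessment) -> CombinedOR:
    """Collapse heart/kidney/liver statuses into AOR / MOR / NOR.

    Only involved-and-evaluable major organs enter the counts; a patient
    with no evaluable organ gets NOT_EVALUABLE (a value, not an error) and
    is excluded from composite scoring upstream.
    """
    evaluable = [
        s for s in assessment.organ_statuses if s is not OrganStatus.NOT_EVALUABLE
    ]
    n_eval = len(evaluable)
    n_resp = sum(1 for s in evaluable if s is OrganStatus.RESPONSE)
    if n_eval == 0:
        cat = CombinedORCategory.NOT_EVALUABLE
    elif n_resp == n_eval:
        cat = CombinedORCategory.AOR
    elif n_resp == 0:
        cat = CombinedORCategory.NOR
    else:
        cat = CombinedORCategory.MOR
    return CombinedOR(category=cat, n_evaluable=n_eval, n_responding=n_resp)


def hematologic_points(cat: HematologicCategory) -> int:
    """Map hematologic category to 0-3 points (low-dFLC pathway: 0 or 1)."""
    if cat.low_dflc_pathway:
        return 0 if cat.category is HematologicResponse.CR else 1
    return _HR_POINTS_STANDARD[cat.category]


def organ_points(combined: CombinedOR) -> int:
    """Map combined organ response to 0-2 points."""
    if combined.category is CombinedORCategory.NOT_EVALUABLE:
        raise ScoringError(
            "combined organ response is not evaluable; patient must be "
            "excluded from composite scoring"
        )
    return _OR_POINTS[combined.category]


def chor_score(
    assessment: ResponseAssessment, group1_max: int = PUBLISHED_GROUP1_MAX
) -> CHORResult:
    """Compute the 0-5 composite score and its two-group assignment."""
    combined = combine_organ_responses(assessment)
    hr_pts = hematologic_points(assessment.hematologic)
    or_pts = organ_points(combined)
    total = hr_pts + or_pts
    group = CHORGroup.GROUP1 if total <= group1_max else CHORGroup.GROUP2
    return CHORResult(hr_points=hr_pts, or_points=or_pts, total=total, group=group)


@dataclass(frozen=True)
class GroupingRule:
    """Result of the hazard-ratio-driven two-group construction.

    ``per_score_hr`` holds the Cox hazard ratio of each score relative to
    score 0 (NaN when that score had no events, listed in
    ``undefined_scores``).  ``cut_after`` is the largest score in the
    lower-hazard block; ``cut_statistics`` maps each candidate cut to its
    two-group log-rank chi-square so the choice is auditable against the
    published 3|4 partition.
    """

    per_score_hr: Mapping[int, float]
    cut_after: int
    cut_statistics: Mapping[int, float]
    best_logrank_p: float
    separating: bool
    undefined_scores: tuple[int, ...] = field(default=())

    @property
    def partition(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        low = tuple(s for s in range(6) if s <= self.cut_after)
        high = tuple(s for s in range(6) if s > self.cut_after)
        return low, high


def build_grouping(
    scores: Sequence[int],
    times: Sequence[float],
    events: Sequence[bool],
    alpha: float = 0.05,
) -> GroupingRule:
    """Reconstruct the two-group partition from score-specific hazards.

    Fits a Cox model with the score as a 6-level categorical (reference
    score 0) to expose per-score hazard ratios, then evaluates every
    contiguous cut of {0..5} and keeps the cut whose two blocks maximize
    the between-block log-rank statistic.  Ties break toward the lowest
    cut.  ``separating=False`` flags cohorts where even the best cut is
    not significant at ``alpha``.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    scores = np.asarray(scores, dtype=int)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not (len(scores) == len(times) == len(events)):
        raise ValueError("scores, times and events must have equal length")
    present = np.unique(scores)
    if present.size < 2:
        raise EstimationError("need at least two distinct scores to form groups")
    if present.min() < 0 or present.max() > 5:
        raise ValueError("scores must lie in {0..5}")

    # per-score HRs vs the best score present (reference = min score)
    ref = int(present.min())
    undefined = tuple(
        int(s) for s in present if not events[scores == s].any()
    )
    per_score_hr: dict[int, float] = {}
    fit_scores = [int(s) for s in present if s != ref and int(s) not in undefined]
    if fit_scores and ref not in undefined:
        df = pd.DataFrame({"T": times, "E": events.astype(int)})
        for s in fit_scores:
            df[f"s{s}"] = (scores == s).astype(float)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        for s in fit_scores:
            per_score_hr[s] = float(np.exp(cph.params_[f"s{s}"]))
    for s in present:
        if int(s) != ref and int(s) not in per_score_hr:
            per_score_hr[int(s)] = float("nan")

    # best contiguous cut by two-group log-rank statistic
    cut_statistics: dict[int, float] = {}
    cut_pvalues: dict[int, float] = {}
    for cut_after in range(0, 5):
        low = scores <= cut_after
        if not low.any() or low.all():
            continue
        res = logrank_test(times[low], times[~low], events[low], events[~low])
        cut_statistics[cut_after] = float(res.test_statistic)
        cut_pvalues[cut_after] = float(res.p_value)
    if not cut_statistics:
        raise EstimationError("no valid contiguous cut separates the scores")
    best_cut = max(
        sorted(cut_statistics), key=lambda c: (cut_statistics[c], -c)
    )
    best_p = cut_pvalues[best_cut]
    return GroupingRule(
        per_score_hr=per_score_hr,
        cut_after=int(best_cut),
        cut_statistics=cut_statistics,
        best_logrank_p=best_p,
        separating=bool(best_p < alpha),
        undefined_scores=undefined,
    )


def mayo2012_stage(
    ntprobnp: float,
    troponin_t: float,
    dflc: float,
    *,
    ntprobnp_cutoff: float = 1800.0,
    troponin_cutoff: float = 0.025,
    dflc_cutoff: float = 18.0,
) -> int:
    """Mayo 2012 stage (1-4): one point per biomarker at/above its cutoff.

    NT-proBNP in pg/mL, troponin-T in ng/mL, dFLC in mg/dL.  Used for the
    staging-subgroup robustness checks, not for response assessment.
    """
    markers = (ntprobnp, troponin_t, dflc)
    if any(m is None for m in markers):
        raise ScoringError("all three staging markers are required")
    return 1 + sum(
        (
            ntprobnp >= ntprobnp_cutoff,
            troponin_t >= troponin_cutoff,
            dflc >= dflc_cutoff,
        )
    )
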