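"""Landmark survival statistics used to validate the composite score.

Thin, typed wrappers around lifelines for the standard machinery
(Kaplan-Meier, log-rank, Cox with Efron ties), plus an in-package
implementation of Harrell's concordance and a paired leave-one-out
jackknife for comparing the concordance of two risk scores on the same
subjects.

Conventions: overall survival is measured from the start of treatment with
the cohort restricted to patients alive at the landmark; median survival is
the first time the survival curve drops to 0.5 or below ("not reached" is
``None``); confidence intervals for the median come from the log-log
(Brookmeyer-Crowley type) band; all tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import EstimationError
from .records import PatientRecord

__all__ = [
    "SurvivalSummary",
    "CoxResult",
    "LogrankResult",
    "ConcordanceComparison",
    "DialysisFreeResult",
    "km_estimate",
    "logrank_test",
    "cox_binary",
    "harrells_c",
    "compare_c",
    "lr_test",
    "dialysis_free_survival",
]


@dataclass(frozen=True)
class SurvivalSummary:
    """Kaplan-Meier curve plus median survival with 95% CI."""

    times: np.ndarray  # event/censor timeline (months)
    survival: np.ndarray  # S(t) at each timeline point
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: Optional[float]  # None == "not reached"
    median_ci: tuple[Optional[float], Optional[float]]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function lookup of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci: tuple[float, float]
    p: float
    coef: float
    se: float
    log_likelihood: float
    finite: bool = True  # False when the partial likelihood is monotone


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float
    df: int


@dataclass(frozen=True)
class ConcordanceComparison:
    c_a: float
    c_b: float
    delta: float
    delta_ci: tuple[float, float]
    p: float


def _as_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be equal-length 1-D sequences")
    if t.size == 0:
        raise EstimationError("empty survival input")
    if (t < 0).any():
        raise ValueError("survival times must be non-negative")
    return t, e


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalSummary:
    """Product-limit survival estimate with median and log-log 95% CI."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    med_ci_df = median_survival_times(ci)
    lo, hi = float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1])
    median_ci = (None if np.isinf(lo) else lo, None if np.isinf(hi) else hi)
    return SurvivalSummary(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        median=median,
        median_ci=median_ci,
        n=int(t.size),
        n_events=int(e.sum()),
    )


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> LogrankResult:
    """k-group log-rank test (chi-square, two-sided p)."""
    from lifelines.statistics import multivariate_logrank_test

    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise EstimationError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        df=int(labels.size - 1),
    )


def cox_binary(
    times: Sequence[float], events: Sequence[bool], indicator: Sequence
) -> CoxResult:
    """Cox hazard ratio for a binary indicator (Efron ties, Wald CI/p).

    When one arm carries no events the partial likelihood is monotone and
    the estimate is flagged non-finite rather than raised.
    """
    from lifelines import CoxPHFitter
    import pandas as pd

    t, e = _as_arrays(times, events)
    x = np.asarray(indicator, dtype=float)
    vals = np.unique(x)
    if vals.size != 2:
        raise ValueError("indicator must take exactly two values")
    x01 = (x == vals.max()).astype(float)

    if not e[x01 == 1].any() or not e[x01 == 0].any():
        arm_hr = np.inf if not e[x01 == 0].any() else 0.0
        return CoxResult(
            hazard_ratio=arm_hr,
            ci=(0.0, np.inf),
            p=float("nan"),
            coef=float("nan"),
            se=float("nan"),
            log_likelihood=float("nan"),
            finite=False,
        )

    df = pd.DataFrame({"T": t, "E": e.astype(int), "x": x01})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = stats.norm.ppf(0.975)
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        ci=(float(np.exp(coef - z * se)), float(np.exp(coef + z * se))),
        p=float(cph.summary.loc["x", "p"]),
        coef=coef,
        se=se,
        log_likelihood=float(cph.log_likelihood_),
    )


def _pair_matrices(risk, times, events):
    """Comparable-pair mask and per-pair concordance score.

    Ordered pair (i, j) is comparable when i's event is known to precede
    j's follow-up: t_i < t_j with an event in i, or t_i == t_j with an
    event in i and j censored.  Pairs of events tied in time are not
    comparable.  Score 1 when the earlier-failing subject has the higher
    risk, 0.5 on a risk tie.
    """
    r = np.asarray(risk, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    comparable = (ti < tj) & ei
    comparable |= (ti == tj) & ei & ~ej
    np.fill_diagonal(comparable, False)
    ri, rj = r[:, None], r[None, :]
    score = np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0))
    return comparable, score


def harrells_c(
    risk_scores: Sequence[float], times: Sequence[float], events: Sequence[bool]
) -> float:
    """Harrell's concordance: higher risk should mean earlier failure.

    Ties in risk count 0.5; pairs whose ordering censoring leaves unknown
    are skipped.
    """
    t, e = _as_arrays(times, events)
    r = np.asarray(risk_scores, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("risk scores must be finite")
    comparable, score = _pair_matrices(r, t, e)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise EstimationError("no comparable pairs (all censored or all tied)")
    return float(score[comparable].sum() / n_comp)


def compare_c(
    risk_a: Sequence[float],
    risk_b: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
) -> ConcordanceComparison:
    """Paired comparison of two risk scores' concordance on one cohort.

    delta = C_a - C_b, with standard error from a paired leave-one-out
    jackknife of the concordance difference and a two-sided normal p.
    """
    t, e = _as_arrays(times, events)
    ra = np.asarray(risk_a, dtype=float)
    rb = np.asarray(risk_b, dtype=float)
    if ra.shape != rb.shape or ra.shape != t.shape:
        raise ValueError("risk vectors and follow-up must have equal length")
    n = t.size

    comp, score_a = _pair_matrices(ra, t, e)
    _, score_b = _pair_matrices(rb, t, e)
    sa = np.where(comp, score_a, 0.0)
    sb = np.where(comp, score_b, 0.0)
    n_comp = comp.sum()
    if n_comp == 0:
        raise EstimationError("no comparable pairs")
    c_a = sa.sum() / n_comp
    c_b = sb.sum() / n_comp
    delta = c_a - c_b

    # leave-one-out via row/column sums of the pair matrices
    comp_k = comp.sum(axis=0) + comp.sum(axis=1)
    sa_k = sa.sum(axis=0) + sa.sum(axis=1)
    sb_k = sb.sum(axis=0) + sb.sum(axis=1)
    denom = n_comp - comp_k
    valid = denom > 0
    d_loo = np.full(n, delta)
    d_loo[valid] = (sa.sum() - sa_k[valid]) / denom[valid] - (
        sb.sum() - sb_k[valid]
    ) / denom[valid]
    se = float(np.sqrt((n - 1) / n * ((d_loo - d_loo.mean()) ** 2).sum()))

    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
        ci = (float(delta), float(delta))
    else:
        z = delta / se
        p = float(2 * stats.norm.sf(abs(z)))
        half = stats.norm.ppf(0.975) * se
        ci = (float(delta - half), float(delta + half))
    return ConcordanceComparison(
        c_a=float(c_a), c_b=float(c_b), delta=float(delta), delta_ci=ci, p=p
    )


def lr_test(loglik_full: float, loglik_reduced: float, df_diff: int, tol: float = 1e-8) -> float:
    """Likelihood-ratio p-value for nested models, chi-square(df_diff)."""
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    delta = loglik_full - loglik_reduced
    if delta < -tol:
        raise ValueError(
            "full model log-likelihood below reduced model: models are not nested"
        )
    return float(stats.chi2.sf(max(2.0 * delta, 0.0), df_diff))


@dataclass(frozen=True)
class DialysisFreeResult:
    responders: SurvivalSummary
    nonresponders: SurvivalSummary
    s60_responders: float
    s60_nonresponders: float
    logrank_p: Optional[float]
    no_events: bool  # True when no dialysis event occurred anywhere


def dialysis_free_survival(
    records: Sequence[PatientRecord],
    renal_response_flags: Sequence[bool],
    horizon_months: float = 60.0,
) -> DialysisFreeResult:
    """Dialysis-free survival by renal-response status.

    Restricted to renally involved patients not on dialysis at baseline;
    the event is dialysis initiation, with death treated as censoring.
    Reports the survival probability at ``horizon_months`` (5 years by
    default) in each response group with a log-rank p.
    """
    flags = np.asarray(renal_response_flags, dtype=bool)
    if len(records) != flags.size:
        raise ValueError("records and renal_response_flags must align")
    keep = [
        i
        for i, r in enumerate(records)
        if r.kidney_involved
        and not r.on_dialysis_at_baseline
        and r.dialysis_time is not None
    ]
    if not keep:
        raise EstimationError("no evaluable renally involved patients")
    t = np.array([records[i].dialysis_time for i in keep], dtype=float)
    e = np.array([bool(records[i].dialysis_event) for i in keep], dtype=bool)
    resp = flags[keep]
    if not resp.any() or resp.all():
        raise EstimationError("need both responders and non-responders")

    km_r = km_estimate(t[resp], e[resp])
    km_n = km_estimate(t[~resp], e[~resp])
    no_events = not e.any()
    lr_p = None
    if not no_events:
        lr_p = logrank_test(t, e, resp.astype(int)).p
    return DialysisFreeResult(
        responders=km_r,
        nonresponders=km_n,
        s60_responders=km_r.survival_at(horizon_months),
        s60_nonresponders=km_n.survival_at(horizon_months),
        logrank_p=lr_p,
        no_events=no_events,
    )
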