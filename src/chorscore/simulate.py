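"""Seeded synthetic cohorts with the structure the analysis assumes.

The generator emulates a landmark cohort of treated AL amyloidosis
patients: organ-involvement marginals, right-skewed baseline biomarkers
(log-normal, parameterized by median and IQR), hematologic response depth,
per-organ responses whose probability rises with hematologic depth, and
overall survival with a proportional-hazards contrast between the two
composite-score groups.  Two frozen configurations encode the marginals of
the published Mayo (testing) and Pavia (validation) cohorts.

Landmark biomarkers are synthesized *inside* the region implied by each
drawn response status, so running the response classifiers on a generated
cohort reproduces the generator's latent statuses exactly — the round-trip
is the main self-consistency oracle of the test suite.

Calibration notes
-----------------
* Involvement probabilities are specified as marginals conditional on at
  least one major organ involved (what a cohort table reports); the
  unconditional Bernoulli parameters are solved by fixed point.
* Per-organ response probabilities are solved per hematologic depth so
  that the expected all-organ-response (AOR) fraction among evaluable
  patients of that depth matches the configured target, accounting for
  the distribution of the number of evaluable organs (cardiac
  evaluability floor, dialysis exclusion).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .composite import (
    CHORGroup,
    CombinedOR,
    CombinedORCategory,
    combine_organ_responses,
    hematologic_points,
    organ_points,
)
from .criteria import DEFAULT_THRESHOLDS, ResponseThresholds
from .records import (
    HematologicCategory,
    HematologicResponse,
    OrganStatus,
)

__all__ = [
    "LogNormalSpec",
    "NormalSpec",
    "SurvivalModel",
    "DialysisModel",
    "SimulationConfig",
    "mayo_default_config",
    "pavia_default_config",
    "generate_baseline",
    "generate_responses",
    "generate_survival",
    "simulate_cohort",
]


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution parameterized by median and quartiles."""

    median: float
    q1: float
    q3: float

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    @property
    def sigma(self) -> float:
        # IQR of the underlying normal spans 2 * 0.67449 sigma
        return float((np.log(self.q3) - np.log(self.q1)) / (2 * stats.norm.ppf(0.75)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(self.mu, self.sigma, size=n))

    def sf(self, x: float) -> float:
        """P(X >= x)."""
        return float(stats.norm.sf((np.log(x) - self.mu) / self.sigma))


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float
    lo: float = 0.0
    hi: float = np.inf

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, size=n), self.lo, self.hi)


@dataclass(frozen=True)
class SurvivalModel:
    """Baseline time-to-death model with group hazard multipliers.

    ``baseline_rate`` is the exponential hazard (per month) of composite
    group 1; ``weibull_shape`` = 1 keeps the default exponential.  Times
    are left-truncated at the landmark by resampling, and administrative
    censoring is uniform over ``(censor_lo, censor_hi)`` months.
    """

    baseline_rate: float
    group_multipliers: dict[str, float] = field(
        default_factory=lambda: {"GROUP1": 1.0, "GROUP2": 3.4}
    )
    weibull_shape: float = 1.0
    censor_lo: float = 6.0
    censor_hi: float = 120.0


@dataclass(frozen=True)
class DialysisModel:
    """Exponential hazards (per month) of dialysis initiation."""

    responder_rate: float
    nonresponder_rate: float


@dataclass
class SimulationConfig:
    n_patients: int = 473
    seed: int = 0
    landmark_months: float = 6.0

    # involvement marginals, conditional on >= 1 major organ involved
    organ_involvement_probs: dict[str, float] = field(
        default_factory=lambda: {"heart": 0.70, "kidney": 0.70, "liver": 0.14}
    )
    dialysis_prob: float = 0.042  # among kidney-involved

    low_dflc_prob: float = 0.13
    hr_category_probs: dict[str, float] = field(
        default_factory=lambda: {"CR": 0.25, "VGPR": 0.35, "PR": 0.24, "NR": 0.16}
    )
    low_dflc_cr_prob: float = 0.29

    # per-organ response probability keyed by hematologic points (0..3)
    organ_response_given_hr: dict[int, float] = field(
        default_factory=lambda: {0: 0.55, 1: 0.45, 2: 0.25, 3: 0.05}
    )

    baseline_distributions: dict[str, object] = field(
        default_factory=lambda: {
            "dflc": LogNormalSpec(19.0, 8.0, 55.0),
            "ntprobnp": LogNormalSpec(1625.0, 327.0, 4296.0),
            "proteinuria": LogNormalSpec(2629.0, 375.0, 7008.0),
            "alp": LogNormalSpec(86.0, 69.0, 118.0),
            "egfr": NormalSpec(65.0, 25.2, lo=5.0, hi=150.0),
            "age": NormalSpec(63.0, 9.6, lo=18.0, hi=95.0),
        }
    )

    survival: SurvivalModel = field(
        default_factory=lambda: SurvivalModel(baseline_rate=np.log(2) / 34 / 3.4)
    )
    dialysis: DialysisModel = field(
        default_factory=lambda: DialysisModel(
            responder_rate=-np.log(0.88) / 60.0,
            nonresponder_rate=-np.log(0.65) / 60.0,
        )
    )

    thresholds: ResponseThresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)

    def validate(self) -> None:
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        for name, p in {
            **self.organ_involvement_probs,
            "low_dflc_prob": self.low_dflc_prob,
            "low_dflc_cr_prob": self.low_dflc_cr_prob,
            "dialysis_prob": self.dialysis_prob,
            **{f"organ_response_given_hr[{k}]": v for k, v in self.organ_response_given_hr.items()},
            **self.hr_category_probs,
        }.items():
            if not 0.0 <= p <= 1.0:
                problems.append(f"probability {name}={p} outside [0, 1]")
        if abs(sum(self.hr_category_probs.values()) - 1.0) > 1e-6:
            problems.append("hr_category_probs must sum to 1")
        if self.survival.baseline_rate <= 0:
            problems.append("baseline hazard must be positive")
        if self.survival.weibull_shape <= 0:
            problems.append("weibull shape must be positive")
        if self.dialysis.responder_rate <= 0 or self.dialysis.nonresponder_rate <= 0:
            problems.append("dialysis hazards must be positive")
        if self.survival.censor_lo < self.landmark_months:
            problems.append("censoring window must start at or after the landmark")
        if problems:
            raise ValueError("invalid SimulationConfig:\n  - " + "\n  - ".join(problems))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return plain(dataclasses.asdict(self))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        bd = {}
        for k, v in d.get("baseline_distributions", {}).items():
            if isinstance(v, dict):
                bd[k] = LogNormalSpec(**v) if "median" in v else NormalSpec(**v)
            else:
                bd[k] = v
        if bd:
            d["baseline_distributions"] = bd
        if isinstance(d.get("survival"), dict):
            d["survival"] = SurvivalModel(**d["survival"])
        if isinstance(d.get("dialysis"), dict):
            d["dialysis"] = DialysisModel(**d["dialysis"])
        if isinstance(d.get("thresholds"), dict):
            d["thresholds"] = ResponseThresholds(**d["thresholds"])
        if "organ_response_given_hr" in d:
            d["organ_response_given_hr"] = {
                int(k): float(v) for k, v in d["organ_response_given_hr"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------

_ORGANS = ("heart", "kidney", "liver")


def _unconditional_involvement(cond: dict[str, float]) -> dict[str, float]:
    """Solve unconditional Bernoulli marginals from conditional targets.

    Conditioning on >= 1 involved organ inflates every marginal by the
    same factor 1 / (1 - q), q the all-uninvolved probability; the fixed
    point p_o = t_o * (1 - q(p)) recovers the unconditional parameters.
    """
    p = {o: cond[o] for o in _ORGANS}
    for _ in range(200):
        q = np.prod([1.0 - p[o] for o in _ORGANS])
        new = {o: cond[o] * (1.0 - q) for o in _ORGANS}
        if max(abs(new[o] - p[o]) for o in _ORGANS) < 1e-12:
            p = new
            break
        p = new
    if any(not 0.0 < v < 1.0 for v in p.values()):
        raise ValueError("involvement targets are not jointly attainable")
    return p


def _evaluable_count_dist(config: SimulationConfig) -> np.ndarray:
    """P(K = k | >= 1 organ involved), K = number of evaluable organs."""
    p = _unconditional_involvement(config.organ_involvement_probs)
    ntp: LogNormalSpec = config.baseline_distributions["ntprobnp"]
    e = {
        "heart": ntp.sf(config.thresholds.cardiac_eval_floor),
        "kidney": 1.0 - config.dialysis_prob,
        "liver": 1.0,
    }
    dist = np.zeros(4)
    p_any = 0.0
    # per organ: 0 = uninvolved, 1 = involved not evaluable, 2 = involved evaluable
    for sh in range(3):
        for sk in range(3):
            for sl in range(3):
                prob = 1.0
                n_inv = n_eval = 0
                for organ, s in zip(_ORGANS, (sh, sk, sl)):
                    if s == 0:
                        prob *= 1.0 - p[organ]
                    elif s == 1:
                        prob *= p[organ] * (1.0 - e[organ])
                        n_inv += 1
                    else:
                        prob *= p[organ] * e[organ]
                        n_inv += 1
                        n_eval += 1
                if n_inv >= 1:
                    dist[n_eval] += prob
                    p_any += prob
    return dist / p_any


def _solve_organ_response_p(
    kdist: np.ndarray, target: float, kind: str = "aor"
) -> float:
    """Per-organ Bernoulli probability hitting an AOR (or any-response) target.

    ``kind='aor'`` solves E[p^K | K >= 1] = target; ``kind='any'`` solves
    1 - E[(1-p)^K | K >= 1] = target.
    """
    w = kdist[1:] / kdist[1:].sum()

    def f(p):
        if kind == "aor":
            return sum(w[k - 1] * p**k for k in (1, 2, 3)) - target
        return 1.0 - sum(w[k - 1] * (1.0 - p) ** k for k in (1, 2, 3)) - target

    return float(optimize.brentq(f, 1e-9, 1.0 - 1e-9))


def _calibrated_response_probs(
    config: SimulationConfig, aor_targets: dict[int, float], nr_any_target: float
) -> dict[int, float]:
    kdist = _evaluable_count_dist(config)
    out = {d: _solve_organ_response_p(kdist, t, "aor") for d, t in aor_targets.items()}
    out[3] = _solve_organ_response_p(kdist, nr_any_target, "any")
    return out


def mayo_default_config(n_patients: int = 473, seed: int = 0) -> SimulationConfig:
    """Frozen configuration matching the Mayo (testing) cohort marginals."""
    cfg = SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        organ_involvement_probs={"heart": 0.70, "kidney": 0.70, "liver": 0.14},
        dialysis_prob=14 / 330,
        low_dflc_prob=63 / 473,
        hr_category_probs={
            "CR": 101 / 410,
            "VGPR": 144 / 410,
            "PR": 99 / 410,
            "NR": 66 / 410,
        },
        low_dflc_cr_prob=18 / 63,
        baseline_distributions={
            "dflc": LogNormalSpec(19.0, 8.0, 55.0),
            "ntprobnp": LogNormalSpec(1625.0, 327.0, 4296.0),
            "proteinuria": LogNormalSpec(2629.0, 375.0, 7008.0),
            "alp": LogNormalSpec(86.0, 69.0, 118.0),
            "egfr": NormalSpec(65.0, (82 - 48) / 1.349, lo=5.0, hi=150.0),
            "age": NormalSpec(63.0, (69 - 56) / 1.349, lo=18.0, hi=95.0),
        },
        survival=SurvivalModel(
            baseline_rate=np.log(2) / 34 / 3.4,
            group_multipliers={"GROUP1": 1.0, "GROUP2": 3.4},
        ),
    )
    cfg.organ_response_given_hr = _calibrated_response_probs(
        cfg,
        aor_targets={0: 45 / 119, 1: 57 / 189, 2: 16 / 99},
        nr_any_target=9 / 66,
    )
    cfg.validate()
    return cfg


def pavia_default_config(n_patients: int = 575, seed: int = 0) -> SimulationConfig:
    """Frozen configuration matching the Pavia (validation) cohort marginals."""
    cfg = SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        organ_involvement_probs={"heart": 0.79, "kidney": 0.69, "liver": 0.11},
        dialysis_prob=9 / 399,
        low_dflc_prob=39 / 575,
        hr_category_probs={
            "CR": 74 / 536,
            "VGPR": 176 / 536,
            "PR": 105 / 536,
            "NR": 181 / 536,
        },
        low_dflc_cr_prob=1.0,
        baseline_distributions={
            "dflc": LogNormalSpec(19.0, 9.0, 52.0),
            "ntprobnp": LogNormalSpec(2215.0, 704.0, 5578.0),
            "proteinuria": LogNormalSpec(2561.0, 392.0, 6590.0),
            "alp": LogNormalSpec(149.0, 88.0, 217.0),
            "egfr": NormalSpec(69.0, (87 - 49) / 1.349, lo=5.0, hi=150.0),
            "age": NormalSpec(64.0, (70 - 56) / 1.349, lo=18.0, hi=95.0),
        },
        survival=SurvivalModel(
            baseline_rate=np.log(2) / 87,
            group_multipliers={"GROUP1": 1.0, "GROUP2": 2.8},
        ),
    )
    cfg.organ_response_given_hr = _calibrated_response_probs(
        cfg,
        aor_targets={0: 40 / 113, 1: 46 / 176, 2: 22 / 105},
        nr_any_target=31 / 181,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def generate_baseline(config: SimulationConfig) -> pd.DataFrame:
    """Sample baseline involvement, biomarkers and demographics.

    Involvement draws are independent Bernoulli with unconditional
    parameters solved so that, after rejecting all-uninvolved patients,
    the configured (conditional) marginals are matched.
    """
    config.validate()
    rng = _stage_rng(config, 1)
    n = config.n_patients
    p = _unconditional_involvement(config.organ_involvement_probs)

    inv = {o: rng.random(n) < p[o] for o in _ORGANS}
    bad = ~(inv["heart"] | inv["kidney"] | inv["liver"])
    while bad.any():
        for o in _ORGANS:
            redraw = rng.random(int(bad.sum())) < p[o]
            inv[o] = inv[o].copy()
            inv[o][bad] = redraw
        bad = ~(inv["heart"] | inv["kidney"] | inv["liver"])

    dialysis = np.zeros(n, dtype=bool)
    dialysis[inv["kidney"]] = rng.random(int(inv["kidney"].sum())) < config.dialysis_prob

    bd = config.baseline_distributions
    low = rng.random(n) < config.low_dflc_prob
    cutoff = config.thresholds.low_dflc_cutoff
    dflc = bd["dflc"].sample(rng, n)
    # truncate by pathway: low-dFLC patients below the cutoff, others above
    need = low & (dflc >= cutoff) | (~low & (dflc < cutoff))
    while need.any():
        dflc[need] = bd["dflc"].sample(rng, int(need.sum()))
        need = low & (dflc >= cutoff) | (~low & (dflc < cutoff))

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": np.round(bd["age"].sample(rng, n), 0),
            "heart_involved": inv["heart"],
            "kidney_involved": inv["kidney"],
            "liver_involved": inv["liver"],
            "on_dialysis_at_baseline": dialysis,
            "baseline_dflc": np.round(dflc, 2),
            "baseline_ifix_negative": np.zeros(n, dtype=bool),
            "baseline_flc_ratio_normal": np.zeros(n, dtype=bool),
            "baseline_ntprobnp": np.round(bd["ntprobnp"].sample(rng, n), 1),
            "baseline_proteinuria": np.round(bd["proteinuria"].sample(rng, n), 0),
            "baseline_egfr": np.round(bd["egfr"].sample(rng, n), 1),
            "baseline_alp": np.round(bd["alp"].sample(rng, n), 0),
            "landmark_months": np.full(n, config.landmark_months),
        }
    )
    return df


def _draw_categories(
    rng: np.random.Generator, baseline: pd.DataFrame, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Draw hematologic categories; return (category codes, low-path mask).

    Codes use hematologic points (0=CR, 1=VGPR, 2=PR, 3=NR); on the
    low-dFLC pathway only 0 (CR) and 1 (non-CR) occur.  Because a PR
    classification requires baseline dFLC >= twice the VGPR cutoff (a
    landmark value that is both >= 4 mg/dL and a >= 50% reduction must
    exist), PR draws landing on low-baseline patients are swapped with
    non-PR draws of feasible patients — the category histogram is exactly
    preserved.
    """
    n = len(baseline)
    thr = config.thresholds
    low = baseline["baseline_dflc"].to_numpy() < thr.low_dflc_cutoff

    codes = np.full(n, -1, dtype=int)
    codes[low] = np.where(
        rng.random(int(low.sum())) < config.low_dflc_cr_prob, 0, 1
    )
    std_idx = np.flatnonzero(~low)
    probs = [config.hr_category_probs[c] for c in ("CR", "VGPR", "PR", "NR")]
    codes[std_idx] = rng.choice(4, size=std_idx.size, p=np.asarray(probs) / sum(probs))

    dflc = baseline["baseline_dflc"].to_numpy()
    pr_floor = 2 * thr.vgpr_dflc
    infeasible = np.flatnonzero(~low & (codes == 2) & (dflc < pr_floor))
    candidates = np.flatnonzero(~low & (codes != 2) & (dflc >= pr_floor))
    if infeasible.size > candidates.size:
        raise ValueError("cannot place PR draws on feasible baselines")
    if infeasible.size:
        chosen = rng.choice(candidates, size=infeasible.size, replace=False)
        codes[infeasible], codes[chosen] = codes[chosen], codes[infeasible].copy()
    return codes, low


def generate_responses(
    baseline: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw latent responses and synthesize consistent landmark biomarkers.

    Returns ``(cohort, truth)``: the cohort table extended with landmark
    columns, and a latent-truth table (hematologic category, per-organ
    status, combined category, composite points and group) that the
    response classifiers must reproduce exactly.
    """
    config.validate()
    rng = _stage_rng(config, 2)
    n = len(baseline)
    thr = config.thresholds
    out = baseline.copy()

    codes, low = _draw_categories(rng, baseline, config)
    dflc = baseline["baseline_dflc"].to_numpy()

    # --- hematologic landmark values ------------------------------------
    is_cr = codes == 0
    ifix_neg = is_cr.copy()
    ratio_norm = np.where(is_cr, True, rng.random(n) < 0.3)
    lm_dflc = np.empty(n)
    lm_dflc[is_cr] = rng.uniform(0.0, 2.0, int(is_cr.sum()))
    m = low & ~is_cr  # low-dFLC non-CR: flags break CR, dFLC stays low
    lm_dflc[m] = rng.uniform(0.0, dflc[m])
    m = ~low & (codes == 1)  # VGPR: landmark dFLC < 4
    lm_dflc[m] = rng.uniform(0.5, thr.vgpr_dflc - 0.1, int(m.sum()))
    m = ~low & (codes == 2)  # PR: in [4, 0.5 x baseline]
    lm_dflc[m] = rng.uniform(thr.vgpr_dflc, thr.pr_fraction * dflc[m])
    m = ~low & (codes == 3)  # NR: > 0.5 x baseline and >= 4
    lm_dflc[m] = np.maximum(dflc[m] * rng.uniform(0.55, 1.2, int(m.sum())), thr.vgpr_dflc)

    out["landmark_dflc"] = np.round(lm_dflc, 3)
    out["landmark_ifix_negative"] = ifix_neg
    out["landmark_flc_ratio_normal"] = ratio_norm

    # --- organ evaluability and latent statuses -------------------------
    heart = baseline["heart_involved"].to_numpy()
    kidney = baseline["kidney_involved"].to_numpy()
    liver = baseline["liver_involved"].to_numpy()
    dialysis = baseline["on_dialysis_at_baseline"].to_numpy()
    bnp0 = baseline["baseline_ntprobnp"].to_numpy()
    prot0 = baseline["baseline_proteinuria"].to_numpy()
    egfr0 = baseline["baseline_egfr"].to_numpy()
    alp0 = baseline["baseline_alp"].to_numpy()

    eval_heart = heart & (bnp0 >= thr.cardiac_eval_floor)
    eval_kidney = kidney & ~dialysis
    eval_liver = liver

    p_resp = np.array([config.organ_response_given_hr[d] for d in range(4)])[codes]
    resp_heart = eval_heart & (rng.random(n) < p_resp)
    resp_kidney = eval_kidney & (rng.random(n) < p_resp)
    resp_liver = eval_liver & (rng.random(n) < p_resp)

    # --- cardiac landmark NT-proBNP -------------------------------------
    lm_bnp = bnp0 * rng.uniform(0.75, 1.15, n)  # uninvolved / not evaluable
    m = resp_heart
    # 0.005 margin keeps the strict >30% / >300 pg/mL clauses satisfied
    # even after landmark values are rounded for the CSV
    lo_frac = np.minimum(
        np.maximum(thr.cardiac_rel_drop, thr.cardiac_abs_drop / np.maximum(bnp0, 1e-9))
        + 0.005,
        0.79,
    )
    frac = rng.uniform(lo_frac, 0.8)
    lm_bnp[m] = bnp0[m] * (1.0 - frac[m])
    m = eval_heart & ~resp_heart  # fails the strict >30% clause
    lm_bnp[m] = bnp0[m] * (1.0 - rng.uniform(-0.2, 0.295, n)[m])

    # --- renal landmark proteinuria / eGFR ------------------------------
    lm_prot = prot0 * rng.uniform(0.8, 1.2, n)
    lm_egfr = egfr0 * rng.uniform(0.9, 1.1, n)
    m = resp_kidney  # >= 30% proteinuria drop, eGFR decline < 25%
    lm_prot[m] = prot0[m] * (1.0 - rng.uniform(0.32, 0.8, n)[m])
    lm_egfr[m] = egfr0[m] * (1.0 - rng.uniform(-0.15, 0.20, n)[m])
    m = eval_kidney & ~resp_kidney  # drop < 30% and landmark kept >= 500
    lm_prot[m] = np.maximum(
        thr.renal_proteinuria_floor, prot0[m] * (1.0 - rng.uniform(-0.2, 0.25, n)[m])
    )
    lm_egfr[m] = egfr0[m] * (1.0 - rng.uniform(-0.15, 0.15, n)[m])

    # --- liver landmark ALP ---------------------------------------------
    lm_alp = alp0 * rng.uniform(0.8, 1.2, n)
    m = resp_liver
    lm_alp[m] = alp0[m] * rng.uniform(0.3, 0.5, n)[m]
    m = eval_liver & ~resp_liver
    lm_alp[m] = alp0[m] * rng.uniform(0.55, 1.15, n)[m]

    out["landmark_ntprobnp"] = np.round(lm_bnp, 1)
    out["landmark_proteinuria"] = np.round(lm_prot, 1)
    out["landmark_egfr"] = np.round(lm_egfr, 2)
    out["landmark_alp"] = np.round(lm_alp, 1)

    # --- latent truth ----------------------------------------------------
    def organ_status(inv, ev, resp):
        s = np.where(resp, "RESPONSE", "NO_RESPONSE")
        return np.where(inv & ev, s, "NOT_EVALUABLE")

    cat_names = np.array(["CR", "VGPR", "PR", "NR"])
    truth_cat = cat_names[codes].copy()
    truth_cat[low & (codes == 1)] = "NR"  # low-dFLC non-CR carries NR label

    truth = pd.DataFrame(
        {
            "patient_id": baseline["patient_id"],
            "hr_category": truth_cat,
            "low_dflc_pathway": low,
            "cardiac_status": organ_status(heart, eval_heart, resp_heart),
            "renal_status": organ_status(kidney, eval_kidney, resp_kidney),
            "liver_status": organ_status(liver, eval_liver, resp_liver),
        }
    )

    n_eval = (
        (truth["cardiac_status"] != "NOT_EVALUABLE").astype(int)
        + (truth["renal_status"] != "NOT_EVALUABLE").astype(int)
        + (truth["liver_status"] != "NOT_EVALUABLE").astype(int)
    )
    n_resp = (
        (truth["cardiac_status"] == "RESPONSE").astype(int)
        + (truth["renal_status"] == "RESPONSE").astype(int)
        + (truth["liver_status"] == "RESPONSE").astype(int)
    )
    combined = np.where(
        n_eval == 0,
        "NOT_EVALUABLE",
        np.where(n_resp == 0, "NOR", np.where(n_resp == n_eval, "AOR", "MOR")),
    )
    truth["combined_or"] = combined
    truth["hr_points"] = codes
    or_pts = pd.Series(combined).map({"AOR": 0, "MOR": 1, "NOR": 2})
    truth["or_points"] = or_pts
    truth["chor_total"] = truth["hr_points"] + truth["or_points"]
    truth["chor_group"] = np.where(
        truth["chor_total"].isna(),
        None,
        np.where(truth["chor_total"] <= 3, "GROUP1", "GROUP2"),
    )
    return out, truth


def generate_survival(
    cohort: pd.DataFrame, truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Attach survival and dialysis follow-up driven by the composite group.

    Death times follow the baseline hazard scaled by the group multiplier
    (patients excluded from scoring keep the baseline hazard), resampled
    until past the landmark, with uniform administrative censoring.
    Dialysis times (renally involved, not on dialysis at baseline) follow
    the response-specific hazards, censored by death and end of follow-up.
    """
    config.validate()
    rng = _stage_rng(config, 3)
    n = len(cohort)
    sv = config.survival

    mult = np.ones(n)
    grp = truth["chor_group"].to_numpy()
    for name, m in sv.group_multipliers.items():
        mult[grp == name] = m

    shape = sv.weibull_shape
    scale = (1.0 / (sv.baseline_rate * mult)) if shape == 1.0 else (
        1.0 / (sv.baseline_rate * mult) ** (1.0 / shape)
    )
    death = scale * rng.weibull(shape, n)
    # left truncation: cohort members were alive at the landmark
    need = death <= config.landmark_months
    while need.any():
        death[need] = scale[need] * rng.weibull(shape, int(need.sum()))
        need = death <= config.landmark_months

    censor = rng.uniform(sv.censor_lo, sv.censor_hi, n)
    os_time = np.minimum(death, censor)
    os_event = death <= censor

    out = cohort.copy()
    out["os_time"] = np.round(os_time, 3)
    out["os_event"] = os_event

    renal_eval = (
        cohort["kidney_involved"].to_numpy()
        & ~cohort["on_dialysis_at_baseline"].to_numpy()
    )
    renal_resp = truth["renal_status"].to_numpy() == "RESPONSE"
    rate = np.where(renal_resp, config.dialysis.responder_rate, config.dialysis.nonresponder_rate)
    dial = rng.exponential(1.0 / rate, n)
    dialysis_time = np.where(renal_eval, np.minimum(dial, os_time), os_time)
    dialysis_event = renal_eval & (dial <= os_time)
    out["dialysis_time"] = np.round(dialysis_time, 3)
    out["dialysis_event"] = dialysis_event
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all three stages and return ``(cohort, truth)`` tables.

    The cohort table uses exactly the CSV dialect the reader consumes; the
    truth table holds the generator's latent statuses and scores.
    """
    baseline = generate_baseline(config)
    cohort, truth = generate_responses(baseline, config)
    cohort = generate_survival(cohort, truth, config)
    return cohort, truth
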