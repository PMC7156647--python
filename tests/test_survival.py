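"""Unit tests for the survival statistics, each against an independent oracle."""

import numpy as np
import pytest
from scipy import stats

from chorscore import (
    compare_c,
    cox_binary,
    dialysis_free_survival,
    harrells_c,
    km_estimate,
    logrank_test,
    lr_test,
)
from chorscore.errors import EstimationError

from conftest import make_record
from tests_support_oracles import brute_force_c


class TestKaplanMeier:
    def test_hand_product_limit(self):
        s = km_estimate([1, 2, 3], [True, True, True])
        assert np.allclose(s.survival, [1.0, 2 / 3, 1 / 3, 0.0])  # S(0) = 1
        assert s.median == 2.0

    def test_all_censored(self):
        s = km_estimate([5, 6, 7], [False, False, False])
        assert np.allclose(s.survival, 1.0)
        assert s.median is None  # not reached

    def test_single_subject(self):
        s = km_estimate([5.0], [True])
        assert s.median == 5.0

    def test_censoring_between_events(self):
        # risk set shrinks after the censoring at t=2
        s = km_estimate([1, 2, 3], [True, False, True])
        assert np.allclose(s.survival, [1.0, 2 / 3, 2 / 3, 0.0])

    def test_matches_empirical_sf_without_censoring(self, rng):
        t = rng.exponential(10, 40)
        s = km_estimate(t, np.ones(40, dtype=bool))
        emp = [(t > u).mean() for u in s.times]
        assert np.allclose(s.survival, emp)

    def test_step_lookup(self):
        s = km_estimate([1, 2, 3], [True, True, True])
        assert s.survival_at(0.5) == 1.0
        assert s.survival_at(2.5) == pytest.approx(1 / 3)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [3.0, 5.0, 8.0, 10.0]
        e = [True, True, False, True]
        res = logrank_test(t + t, e + e, [0] * 4 + [1] * 4)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_worked_example(self):
        # brute-force observed-minus-expected over risk sets
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 1, 0, 1], dtype=bool)
        groups = np.array([0, 1, 0, 1, 0, 1])
        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(times[events]):
            at_risk = times >= t
            d = float((events & (times == t)).sum())
            n = float(at_risk.sum())
            n1 = float((at_risk & (groups == 1)).sum())
            d1 = float((events & (times == t) & (groups == 1)).sum())
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected = o_minus_e**2 / var
        res = logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(expected, rel=1e-9)

    def test_separated_hazards_significant(self, rng):
        n = 500
        t = np.concatenate([rng.exponential(30, n), rng.exponential(10, n)])
        g = np.repeat([0, 1], n)
        res = logrank_test(t, np.ones(2 * n, dtype=bool), g)
        assert res.p < 0.001

    def test_label_permutation_invariance(self, rng):
        t = rng.exponential(10, 60)
        e = rng.random(60) < 0.7
        g = rng.integers(0, 2, 60)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.p == pytest.approx(b.p)

    def test_single_group_errors(self):
        with pytest.raises(EstimationError):
            logrank_test([1, 2], [True, True], [0, 0])


class TestCox:
    def test_grid_search_oracle_four_subjects(self):
        # no ties: Efron == Breslow partial likelihood, maximized on a grid
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([True, True, True, True])
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_pl(beta):
            ll = 0.0
            for i in range(4):
                risk = times >= times[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        grid = np.linspace(-3, 3, 20001)
        beta_star = grid[np.argmin([neg_pl(b) for b in grid])]
        res = cox_binary(times, events, x)
        assert res.coef == pytest.approx(beta_star, abs=1e-3)

    def test_label_swap_gives_reciprocal_hr(self, rng):
        t = rng.exponential(10, 200)
        e = rng.random(200) < 0.6
        x = rng.integers(0, 2, 200)
        a = cox_binary(t, e, x)
        b = cox_binary(t, e, 1 - x)
        assert a.hazard_ratio == pytest.approx(1.0 / b.hazard_ratio, rel=1e-6)

    def test_null_covariate_ci_covers_one(self, rng):
        t = rng.exponential(10, 300)
        x = rng.integers(0, 2, 300)
        res = cox_binary(t, np.ones(300, dtype=bool), x)
        assert res.ci[0] < 1.0 < res.ci[1]

    def test_monotone_likelihood_flagged(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, False]
        x = [1, 1, 0, 0]  # all events in one arm
        res = cox_binary(t, e, x)
        assert not res.finite


class TestHarrellsC:
    def test_perfect_ordering(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert harrells_c([5, 4, 3, 2, 1], t, [True] * 5) == 1.0

    def test_constant_risk_is_half(self):
        assert harrells_c([1] * 5, [1, 2, 3, 4, 5], [True] * 5) == 0.5

    def test_censored_six_subject_oracle(self):
        t = np.array([2.0, 4.0, 4.0, 6.0, 8.0, 9.0])
        e = np.array([1, 1, 0, 1, 0, 1], dtype=bool)
        r = np.array([3.0, 2.0, 5.0, 2.0, 1.0, 0.0])
        assert harrells_c(r, t, e) == pytest.approx(brute_force_c(r, t, e))

    def test_matches_lifelines_convention(self, rng):
        from lifelines.utils import concordance_index

        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.6
        r = rng.normal(size=80)
        # lifelines scores predicted *survival* times: negate the risk
        assert harrells_c(r, t, e) == pytest.approx(concordance_index(t, -r, e))

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(EstimationError):
            harrells_c([1, 2], [1.0, 2.0], [False, False])


class TestCompareC:
    def test_identical_scores_delta_zero(self, rng):
        t = rng.exponential(10, 50)
        e = rng.random(50) < 0.7
        r = rng.normal(size=50)
        res = compare_c(r, r, t, e)
        assert res.delta == 0.0
        assert res.p == 1.0

    def test_jackknife_matches_direct_leave_one_out(self, rng):
        n = 30
        t = rng.exponential(10, n)
        e = rng.random(n) < 0.7
        ra = -t + rng.normal(0, 2, n)
        rb = rng.normal(size=n)
        res = compare_c(ra, rb, t, e)
        # direct recomputation-per-leave-one-out oracle
        deltas = []
        for k in range(n):
            keep = np.arange(n) != k
            deltas.append(
                brute_force_c(ra[keep], t[keep], e[keep])
                - brute_force_c(rb[keep], t[keep], e[keep])
            )
        deltas = np.array(deltas)
        se = np.sqrt((n - 1) / n * ((deltas - deltas.mean()) ** 2).sum())
        width = res.delta_ci[1] - res.delta_ci[0]
        assert width == pytest.approx(2 * stats.norm.ppf(0.975) * se, rel=1e-9)

    def test_informative_score_beats_noise(self, rng):
        n = 200
        t = rng.exponential(10, n)
        e = rng.random(n) < 0.7
        res = compare_c(-t, rng.normal(size=n), t, e)
        assert res.delta > 0
        assert res.delta_ci[0] > 0


class TestLrTest:
    def test_zero_delta(self):
        assert lr_test(-100.0, -100.0, 1) == pytest.approx(1.0)

    def test_chi_square_quantile_identity(self):
        assert lr_test(-100.0, -100.0 - 3.841 / 2, 1) == pytest.approx(0.05, abs=1e-3)

    def test_against_chi2_sf(self):
        assert lr_test(-50.0, -55.0, 2) == pytest.approx(stats.chi2.sf(10.0, 2), abs=1e-10)

    def test_non_nested_raises(self):
        with pytest.raises(ValueError):
            lr_test(-105.0, -100.0, 1)


class TestDialysisFree:
    def _records(self, n, responder_frac, rng, rate_r=0.002, rate_n=0.008):
        recs, flags = [], []
        for i in range(n):
            resp = i < int(n * responder_frac)
            d = rng.exponential(1.0 / (rate_r if resp else rate_n))
            death = rng.exponential(120.0)
            c = rng.uniform(6, 120)
            t = min(d, death, c)
            recs.append(
                make_record(
                    patient_id=f"R{i}", kidney_involved=True,
                    dialysis_time=t, dialysis_event=d <= min(death, c),
                )
            )
            flags.append(resp)
        return recs, flags

    def test_group_separation(self, rng):
        recs, flags = self._records(400, 0.5, rng)
        res = dialysis_free_survival(recs, flags)
        assert res.s60_responders > res.s60_nonresponders
        assert res.logrank_p < 0.05

    def test_no_renal_patients_errors(self):
        recs = [make_record(kidney_involved=False)]
        with pytest.raises(EstimationError):
            dialysis_free_survival(recs, [True])

    def test_no_events_flagged(self):
        recs = [
            make_record(patient_id=f"R{i}", kidney_involved=True,
                        dialysis_time=60.0, dialysis_event=False)
            for i in range(6)
        ]
        res = dialysis_free_survival(recs, [True, True, True, False, False, False])
        assert res.no_events
        assert res.s60_responders == 1.0
        assert res.logrank_p is None
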