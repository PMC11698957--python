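"""Exact trial statistics: design search, exact tests, trend, survival."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from smmkit import trial


def brute_force_design(p0, p1, alpha, beta, n_max):
    """Independent oracle: exhaustive enumeration over all (n, r)."""
    for n in range(1, n_max + 1):
        for r in range(0, n + 1):
            a = sum(stats.binom.pmf(k, n, p0) for k in range(r, n + 1))
            power = sum(stats.binom.pmf(k, n, p1) for k in range(r, n + 1))
            if a <= alpha and power >= 1 - beta:
                return n, r
    return None


class TestDesign:
    def test_published_design_50_vs_70(self):
        res = trial.design_single_stage(trial.DesignSpec(0.50, 0.70, 0.05, 0.10))
        assert (res.n, res.r) == (53, 33)
        assert res.attained_alpha <= 0.05
        assert res.attained_power >= 0.90

    def test_vacuous_constraints(self):
        res = trial.design_single_stage(trial.DesignSpec(0.1, 0.9, 1.0, 1.0))
        assert (res.n, res.r) == (1, 0)

    def test_matches_brute_force_enumeration(self):
        spec = trial.DesignSpec(0.50, 0.90, 0.05, 0.20)
        res = trial.design_single_stage(spec)
        assert (res.n, res.r) == brute_force_design(0.50, 0.90, 0.05, 0.20, 50)

    @pytest.mark.parametrize("p0,p1,alpha,beta", [
        (0.50, 0.70, 0.05, 0.10),
        (0.20, 0.40, 0.05, 0.20),
        (0.30, 0.50, 0.10, 0.10),
    ])
    def test_minimality_and_error_constraints(self, p0, p1, alpha, beta):
        """The returned n satisfies both exact constraints and n-1 admits no r."""
        spec = trial.DesignSpec(p0, p1, alpha, beta)
        res = trial.design_single_stage(spec)
        assert stats.binom.sf(res.r - 1, res.n, p0) <= alpha
        assert stats.binom.sf(res.r - 1, res.n, p1) >= 1 - beta
        for n in range(1, res.n):
            feasible = any(
                stats.binom.sf(r - 1, n, p0) <= alpha
                and stats.binom.sf(r - 1, n, p1) >= 1 - beta
                for r in range(0, n + 1)
            )
            assert not feasible

    def test_search_failure_raises(self):
        with pytest.raises(trial.DesignSearchError):
            trial.design_single_stage(trial.DesignSpec(0.50, 0.51, 0.05, 0.10), n_max=30)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            trial.DesignSpec(0.7, 0.5, 0.05, 0.10)


class TestCriticalValue:
    def test_published_value(self):
        assert trial.critical_value(53, 0.5, 0.05) == 33

    def test_alpha_one_gives_zero(self):
        assert trial.critical_value(10, 0.5, 1.0) == 0

    def test_matches_direct_pmf_summation(self):
        # enumerate all 11 upper tails for n = 10
        tails = {r: sum(stats.binom.pmf(k, 10, 0.5) for k in range(r, 11))
                 for r in range(0, 12)}
        expected = min(r for r, t in tails.items() if t <= 0.05)
        assert trial.critical_value(10, 0.5, 0.05) == expected

    def test_never_reject_sentinel(self):
        # even r = n has tail p0^n above alpha
        assert trial.critical_value(3, 0.9, 0.001) == 4


class TestExactBinomial:
    def test_primary_endpoint_significance(self):
        assert trial.exact_binomial_test(50, 55, 0.5, "greater") < 0.001

    def test_zero_successes_greater(self):
        assert trial.exact_binomial_test(0, 20, 0.3, "greater") == 1.0

    def test_hand_summation(self):
        expected = sum(stats.binom.pmf(k, 10, 0.5) for k in range(7, 11))
        assert trial.exact_binomial_test(7, 10, 0.5, "greater") == pytest.approx(expected)

    def test_invalid_x(self):
        with pytest.raises(ValueError):
            trial.exact_binomial_test(11, 10, 0.5)


class TestClopperPearson:
    @pytest.mark.parametrize("x,n,lo,hi", [(50, 55, 80, 97), (25, 55, 32, 59)])
    def test_published_intervals_integer_percent(self, x, n, lo, hi):
        low, high = trial.clopper_pearson_ci(x, n, 0.95)
        assert round(low * 100) == lo
        assert round(high * 100) == hi

    def test_boundaries(self):
        assert trial.clopper_pearson_ci(0, 20)[0] == 0.0
        assert trial.clopper_pearson_ci(20, 20)[1] == 1.0

    def test_coverage_at_least_nominal(self):
        """Simulated coverage of the 95% interval at (n=55, p=0.6)."""
        rng = np.random.default_rng(0)
        xs = rng.binomial(55, 0.6, size=10_000)
        # vectorized beta-tail inversion equals clopper_pearson_ci
        lo = np.where(xs > 0, stats.beta.ppf(0.025, xs, 55 - xs + 1), 0.0)
        hi = np.where(xs < 55, stats.beta.ppf(0.975, xs + 1, 55 - xs), 1.0)
        spot = rng.integers(0, len(xs), 20)
        for i in spot:
            l, h = trial.clopper_pearson_ci(int(xs[i]), 55)
            assert (l, h) == pytest.approx((lo[i], hi[i]), abs=1e-9)
        assert np.mean((lo <= 0.6) & (0.6 <= hi)) >= 0.95


def fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration with the probability-mass rule."""
    row1, col1, n = a + b, a + c, a + b + c + d
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = {k: stats.hypergeom.pmf(k, n, col1, row1) for k in support}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_evolving_vs_response_table(self):
        _, p = trial.fisher_exact_test(9, 20, 16, 10)
        assert round(p, 3) == 0.032

    def test_exchangeable_table(self):
        _, p = trial.fisher_exact_test(5, 5, 5, 5)
        assert p == pytest.approx(1.0)

    def test_tiny_enumeration(self):
        _, p = trial.fisher_exact_test(2, 0, 0, 2)
        assert p == pytest.approx(1 / 3)

    def test_odds_ratio_and_infinity(self):
        odds, _ = trial.fisher_exact_test(9, 20, 16, 10)
        assert odds == pytest.approx(9 * 10 / (20 * 16))
        assert trial.fisher_exact_test(2, 0, 0, 2)[0] == np.inf

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            trial.fisher_exact_test(0, 0, 0, 0)

    @given(st.tuples(*[st.integers(0, 8)] * 4).filter(lambda t: sum(t) > 0))
    def test_invariant_under_row_and_column_swaps(self, cells):
        a, b, c, d = cells
        p = trial.fisher_exact_test(a, b, c, d)[1]
        assert 0 < p <= 1 + 1e-12
        assert trial.fisher_exact_test(c, d, a, b)[1] == pytest.approx(p, rel=1e-9)
        assert trial.fisher_exact_test(b, a, d, c)[1] == pytest.approx(p, rel=1e-9)


class TestCochranArmitage:
    def test_response_by_risk_trend(self):
        res = trial.cochran_armitage_trend([9, 19, 23], [9, 21, 25])
        assert round(res.p_value, 2) == 0.55

    def test_identical_proportions_zero_statistic(self):
        res = trial.cochran_armitage_trend([5, 5, 5], [10, 10, 10])
        assert res.z == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_all_successes(self):
        res = trial.cochran_armitage_trend([10, 10], [10, 10])
        assert res.degenerate and res.p_value == 1.0

    def test_two_groups_equals_score_chi_square(self):
        """z^2 for 2 groups equals the 2x2 score-test chi-square (direct oracle)."""
        s, t = np.array([12, 20]), np.array([30, 30])
        res = trial.cochran_armitage_trend(s, t)
        # unconditional score (Pearson) chi-square on the 2x2 table
        table = np.array([[s[0], t[0] - s[0]], [s[1], t[1] - s[1]]])
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        assert res.z**2 == pytest.approx(chi2, rel=1e-9)


def hand_km(times, events):
    """Hand product-limit computation at event times (independent oracle)."""
    surv = {}
    s = 1.0
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    for t in np.unique(times[events == 1]):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / at_risk
        surv[t] = s
    return surv


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survivor(self):
        times = np.array([1.0, 2, 3, 4, 5])
        sample = trial.SurvivalSample(times, np.ones(5))
        res = trial.km_curve(sample)
        for t in times:
            assert res.at(t) == pytest.approx(np.mean(times > t))

    def test_all_censored_median_not_reached(self):
        sample = trial.SurvivalSample([5.0, 6, 7], [0, 0, 0])
        assert trial.km_curve(sample).median is None

    def test_mixed_fixture_matches_hand_table(self):
        times = [1.0, 2, 3, 4, 5, 6]
        events = [1, 0, 1, 1, 0, 1]
        res = trial.km_curve(trial.SurvivalSample(times, events))
        for t, s in hand_km(times, events).items():
            assert res.at(t) == pytest.approx(s)

    def test_curve_monotone_right_continuous(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        res = trial.km_curve(trial.SurvivalSample(times, events))
        assert np.all(np.diff(res.survival) <= 1e-12)
        assert res.at(-0.001) == 1.0

    def test_median_definition(self):
        # 4 events: S drops to 0.5 at the second event time
        res = trial.km_curve(trial.SurvivalSample([1.0, 2, 3, 4], [1, 1, 1, 1]))
        assert res.median == pytest.approx(2.0)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2, 3, 4] * 2)
        e = np.array([1, 1, 0, 1] * 2)
        g = np.array([0] * 4 + [1] * 4)
        res = trial.logrank_test(trial.SurvivalSample(t, e, g))
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_no_events_degenerate(self):
        res = trial.logrank_test(
            trial.SurvivalSample([1.0, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        )
        assert res.degenerate and res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            trial.logrank_test(trial.SurvivalSample([1.0, 2], [1, 1], [0, 0]))

    def test_small_fixture_matches_hand_computation(self):
        """Observed-minus-expected table computed by hand for 8 subjects."""
        times = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        groups = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            n, n0 = at_risk.sum(), (at_risk & (groups == 0)).sum()
            d = ((times == t) & (events == 1)).sum()
            d0 = ((times == t) & (events == 1) & (groups == 0)).sum()
            o_minus_e += d0 - d * n0 / n
            if n > 1:
                var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        res = trial.logrank_test(trial.SurvivalSample(times, events, groups))
        assert res.chi2 == pytest.approx(expected_chi2, rel=1e-9)


class TestReverseKM:
    def test_all_censored_equals_km_of_censoring_times(self):
        sample = trial.SurvivalSample([3.0, 5, 7, 9], [0, 0, 0, 0])
        assert trial.reverse_km_median(sample) == pytest.approx(5.0)

    def test_all_events_not_reached(self):
        sample = trial.SurvivalSample([3.0, 5, 7], [1, 1, 1])
        assert trial.reverse_km_median(sample) is None

    def test_consistency_with_flipped_km(self):
        rng = np.random.default_rng(11)
        sample = trial.SurvivalSample(rng.exponential(10, 30),
                                      rng.integers(0, 2, 30))
        flipped = trial.SurvivalSample(sample.time, 1 - sample.event)
        assert trial.reverse_km_median(sample) == trial.km_curve(flipped).median
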