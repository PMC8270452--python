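"""Multinomial and variance day-level tests, against brute-force oracles."""

import itertools
import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from disorient import (
    DailyPolaritySeries,
    MultinomialNull,
    basic_daily_test,
    exact_multinomial_pvalue,
    mc_multinomial_pvalue,
    rejection_summary,
    running_daily_test,
    running_variance_test,
    window_sensitivity,
)
from disorient.daily_tests import variance_test_from_proportions


def brute_force_pvalue(counts, probs):
    """Exact multinomial p-value by plain itertools enumeration (oracle)."""
    n = sum(counts)

    def pmf(x):
        coef = math.factorial(n) / math.prod(math.factorial(c) for c in x)
        p = coef
        for c, pi in zip(x, probs):
            if pi == 0:
                if c > 0:
                    return 0.0
            else:
                p *= pi ** c
        return p

    p_obs = pmf(counts)
    if p_obs == 0:
        return 0.0
    total = 0.0
    for x1 in range(n + 1):
        for x2 in range(n + 1 - x1):
            x = (x1, x2, n - x1 - x2)
            px = pmf(x)
            if px <= p_obs * (1 + 1e-9):
                total += px
    return min(total, 1.0)


class TestExactPvalue:
    def test_modal_observation_gives_one(self):
        # the mode has no outcome more probable than itself excluded
        null = MultinomialNull((0.5, 0.3, 0.2))
        mode = (10, 6, 4)
        assert exact_multinomial_pvalue(mode, null) == pytest.approx(1.0)

    def test_degenerate_null_single_outcome(self):
        null = MultinomialNull((1.0, 0.0, 0.0))
        assert exact_multinomial_pvalue((7, 0, 0), null) == 1.0

    def test_impossible_observation_has_p_zero(self):
        null = MultinomialNull((1.0, 0.0, 0.0))
        assert exact_multinomial_pvalue((6, 1, 0), null) == 0.0

    def test_small_case_full_enumeration(self):
        # n = 3 under (0.5, 0.3, 0.2): P(3,0,0) = 0.125; outcomes with
        # probability <= 0.125 are (3,0,0), (0,3,0), (0,0,3), (1,0,2),
        # (0,2,1), (0,1,2): total 0.310
        null = MultinomialNull((0.5, 0.3, 0.2))
        p = exact_multinomial_pvalue((3, 0, 0), null)
        assert p == pytest.approx(0.310, abs=1e-12)
        assert p == pytest.approx(brute_force_pvalue((3, 0, 0), (0.5, 0.3, 0.2)))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_on_random_cases(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(3))
        n = int(rng.integers(1, 16))
        counts = rng.multinomial(n, probs)
        got = exact_multinomial_pvalue(tuple(counts), MultinomialNull(tuple(probs)))
        want = brute_force_pvalue(tuple(counts), tuple(probs))
        assert got == pytest.approx(want, rel=1e-9)

    def test_enumeration_cap(self):
        null = MultinomialNull((0.5, 0.3, 0.2))
        with pytest.raises(ValueError, match="mc_multinomial"):
            exact_multinomial_pvalue((3000, 0, 0), null, max_n=2000)

    def test_validity_by_enumeration(self):
        # P(p <= alpha) <= alpha + max outcome probability, for every alpha
        null = MultinomialNull((0.6, 0.25, 0.15))
        for n in (5, 12, 20):
            comps = [(a, b, n - a - b) for a in range(n + 1)
                     for b in range(n + 1 - a)]
            pvals = np.array([exact_multinomial_pvalue(c, null) for c in comps])
            probs = np.array([math.factorial(n)
                              / math.prod(math.factorial(v) for v in c)
                              * 0.6 ** c[0] * 0.25 ** c[1] * 0.15 ** c[2]
                              for c in comps])
            slack = probs.max()
            for alpha in (0.01, 0.05, 0.10):
                assert probs[pvals <= alpha].sum() <= alpha + slack + 1e-12


class TestMonteCarloPvalue:
    def test_modal_observation_near_one(self):
        null = MultinomialNull((0.5, 0.3, 0.2))
        p = mc_multinomial_pvalue((10, 6, 4), null, n_sim=2000, seed=0)
        assert p > 0.99

    def test_deterministic_given_seed(self):
        null = MultinomialNull((0.4, 0.35, 0.25))
        p1 = mc_multinomial_pvalue((20, 5, 5), null, n_sim=2000, seed=123)
        p2 = mc_multinomial_pvalue((20, 5, 5), null, n_sim=2000, seed=123)
        assert p1 == p2

    def test_agrees_with_exact_within_mc_error(self):
        rng = np.random.default_rng(2)
        n_sim = 4000
        for _ in range(15):
            probs = rng.dirichlet(np.ones(3) * 2)
            n = int(rng.integers(5, 60))
            counts = rng.multinomial(n, probs)
            null = MultinomialNull(tuple(probs))
            p_ex = exact_multinomial_pvalue(tuple(counts), null)
            p_mc = mc_multinomial_pvalue(tuple(counts), null, n_sim=n_sim,
                                         seed=int(rng.integers(2 ** 31)))
            band = 3 * math.sqrt(max(p_ex * (1 - p_ex), 1e-12) / n_sim) \
                + 2 / n_sim
            assert abs(p_ex - p_mc) <= band

    def test_rejects_tiny_n_sim(self):
        with pytest.raises(ValueError):
            mc_multinomial_pvalue((5, 3, 2), MultinomialNull((0.5, 0.3, 0.2)),
                                  n_sim=10)


class TestBasicDailyTest:
    def test_single_day_series_is_its_own_null(self):
        counts = np.array([[12, 5, 3]])
        series = DailyPolaritySeries.from_arrays(date(2018, 1, 1), counts)
        res = basic_daily_test(series)
        # the observed vector is a mode of Multinomial(n, x/n): p = 1
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_zero_volume_day_skipped(self, small_series):
        res = basic_daily_test(small_series)
        assert bool(res["skipped"].iloc[1])
        assert res["skipped"].sum() == 1
        assert rejection_summary(res).tested_days == 4

    def test_null_is_pooled_yearly_proportions(self, small_series):
        res = basic_daily_test(small_series)
        pooled = small_series.pooled_counts()
        expected = pooled / pooled.sum()
        tested = res[~res["skipped"]]
        assert np.allclose(tested[["null_F", "null_C", "null_U"]], expected)


class TestRunningDailyTest:
    def test_first_window_days_skipped(self, constant_series):
        res = running_daily_test(constant_series, window=15)
        assert res["skipped"].iloc[:15].all()
        assert not res["skipped"].iloc[15:].any()

    def test_window_equal_to_length_skips_all(self, constant_series):
        res = running_daily_test(constant_series, window=len(constant_series.dates))
        assert res["skipped"].all()

    def test_null_is_mean_of_preceding_proportions(self, small_series):
        res = running_daily_test(small_series, window=3, min_history=2)
        # day 4 (index 3): preceding non-empty days are 1 and 3 (0-based 0, 2)
        props = small_series.proportions().to_numpy()
        want = np.nanmean(props[[0, 2]], axis=0)
        got = res.loc[3, ["null_F", "null_C", "null_U"]].to_numpy(dtype=float)
        assert np.allclose(got, want)

    def test_abrupt_shift_detected(self):
        # 20 calm days then one day whose favourable share jumps by +0.15
        rng = np.random.default_rng(42)
        base = np.array([0.70, 0.164, 0.136])
        shifted = base + np.array([0.15, -0.15 * 0.164 / 0.3, -0.15 * 0.136 / 0.3])
        counts = np.array([rng.multinomial(500, base) for _ in range(20)]
                          + [rng.multinomial(500, shifted)])
        series = DailyPolaritySeries.from_arrays(date(2018, 1, 1), counts)
        res = running_daily_test(series, window=15, seed=0)
        assert res["p_value"].iloc[-1] < 0.01

    def test_pooled_null_variant(self, small_series):
        res = running_daily_test(small_series, window=3, min_history=2,
                                 pooled_null=True)
        pooled = small_series.counts[[0, 2]].sum(axis=0)
        want = pooled / pooled.sum()
        got = res.loc[3, ["null_F", "null_C", "null_U"]].to_numpy(dtype=float)
        assert np.allclose(got, want)


class TestRunningVarianceTest:
    def test_constant_window_is_low_direction_small_p(self):
        rng = np.random.default_rng(3)
        p_f = np.concatenate([rng.uniform(0.4, 0.9, size=30),
                              np.full(15, 0.7)])
        res = variance_test_from_proportions(p_f, window=15)
        last = res.iloc[-1]
        assert last["statistic"] == pytest.approx(0.0, abs=1e-20)
        assert last["direction"] == "low"
        assert last["p_value"] < 1e-6

    def test_statistic_at_yearly_variance(self):
        # if s_w^2 == sigma0^2 then T = w - 1 and the two-sided p follows
        # straight from the chi-square CDF with w-1 df
        w = 15
        t_stat = float(w - 1)
        cdf = stats.chi2.cdf(t_stat, df=w - 1)
        expected_p = 2 * min(cdf, 1 - cdf)
        rng = np.random.default_rng(8)
        p_f = rng.normal(0.7, 0.05, size=200)
        res = variance_test_from_proportions(p_f, window=w)
        ok = res[~res["skipped"]]
        # locate the day whose statistic is closest to w-1 and check the
        # p-value is computed by the same chi-square formula
        i = (ok["statistic"] - t_stat).abs().idxmin()
        row = ok.loc[i]
        c = stats.chi2.cdf(row["statistic"], df=w - 1)
        assert row["p_value"] == pytest.approx(2 * min(c, 1 - c))
        assert expected_p == pytest.approx(2 * min(cdf, 1 - cdf))

    def test_shift_invariance(self):
        rng = np.random.default_rng(9)
        p_f = rng.uniform(0.3, 0.8, size=60)
        r1 = variance_test_from_proportions(p_f, window=10)
        r2 = variance_test_from_proportions(p_f + 0.1, window=10)
        assert np.allclose(r1["statistic"].astype(float),
                           r2["statistic"].astype(float), equal_nan=True)

    def test_zero_yearly_variance_errors(self):
        with pytest.raises(ValueError):
            variance_test_from_proportions(np.full(30, 0.5), window=5)

    def test_series_wrapper_skips_empty_days(self, small_series):
        res = running_variance_test(small_series, window=3)
        assert bool(res["skipped"].iloc[1])
        assert res.loc[1, "skip_reason"] == "no observation"


class TestRejectionSummary:
    def test_expected_days_is_alpha_times_tested(self, constant_series):
        res = basic_daily_test(constant_series)
        summ = rejection_summary(res, alphas=(0.05,))
        assert summ.tested_days == 30
        assert summ.expected_days[0] == pytest.approx(1.5)

    def test_365_day_expectation_is_about_18(self):
        counts = np.tile(np.array([[140, 33, 27]]), (365, 1))
        series = DailyPolaritySeries.from_arrays(date(2018, 1, 1), counts)
        summ = rejection_summary(basic_daily_test(series), alphas=(0.05,))
        assert summ.expected_days[0] == pytest.approx(18.25)

    def test_empty_results(self):
        import pandas as pd
        summ = rejection_summary(pd.DataFrame())
        assert summ.rejected_days == (0, 0, 0)
        assert summ.tested_days == 0

    def test_all_p_one_no_rejections(self, constant_series):
        res = basic_daily_test(constant_series)
        res["p_value"] = 1.0
        summ = rejection_summary(res)
        assert summ.rejected_days == (0, 0, 0)

    def test_rejections_monotone_in_alpha(self):
        rng = np.random.default_rng(17)
        counts = rng.multinomial(80, [0.6, 0.25, 0.15], size=60)
        series = DailyPolaritySeries.from_arrays(date(2018, 1, 1), counts)
        res = basic_daily_test(series, seed=0)
        summ = rejection_summary(res, alphas=(0.01, 0.05, 0.10, 0.20))
        assert list(summ.rejected_days) == sorted(summ.rejected_days)


class TestWindowSensitivity:
    def test_single_window_matches_direct_calls(self, noisy_series):
        table = window_sensitivity(noisy_series, [15], alphas=(0.05,), seed=0)
        direct = rejection_summary(
            running_daily_test(noisy_series, window=15, seed=0), (0.05,))
        row = table[(table["test"] == "running_multinomial")].iloc[0]
        assert row["rejected_days"] == direct.rejected_days[0]
        assert row["tested_days"] == direct.tested_days

    def test_empty_window_list(self, noisy_series):
        table = window_sensitivity(noisy_series, [])
        assert len(table) == 0

    def test_reports_both_tests_per_window(self, noisy_series):
        table = window_sensitivity(noisy_series, [7, 15], alphas=(0.1, 0.05))
        assert set(table["test"]) == {"running_multinomial", "running_variance"}
        assert len(table) == 2 * 2 * 2
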