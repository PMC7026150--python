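import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from facedim.stats import (
    AnovaResult,
    DegenerateVarianceError,
    GroupSummary,
    InsufficientDataError,
    PowerSpec,
    anova_from_summaries,
    anova_raw,
    as_mean_sd,
    choose_test,
    cohens_d,
    d_confidence_interval,
    holm_adjust,
    iqr_to_sd,
    min_n_for_power,
    rank_sum_test,
    summarize,
    tukey_hsd,
    welch_from_summaries,
    welch_t,
)

summary_strategy = st.builds(
    GroupSummary,
    n=st.integers(2, 500),
    location=st.floats(-100, 100),
    spread=st.floats(0.01, 50),
)


class TestGroupSummary:
    def test_rejects_small_n(self):
        with pytest.raises(InsufficientDataError):
            GroupSummary(n=1, location=0.0, spread=1.0)

    def test_rejects_zero_spread(self):
        with pytest.raises(DegenerateVarianceError):
            GroupSummary(n=5, location=0.0, spread=0.0)

    def test_median_iqr_conversion(self):
        s = GroupSummary(n=10, location=5.0, spread=1.349, kind="median_iqr")
        converted = as_mean_sd(s)
        assert converted.kind == "mean_sd"
        assert converted.spread == pytest.approx(iqr_to_sd(1.349))
        # IQR of a standard normal maps back to SD 1
        assert iqr_to_sd(2 * sps.norm.ppf(0.75)) == pytest.approx(1.0)


class TestWelch:
    @pytest.mark.parametrize(
        "s1, n1, s2, n2, printed_df",
        [
            (2.81, 30, 3.19, 69, 62.3),
            (2.41, 40, 2.35, 40, 78.0),
            (8.07, 40, 7.11, 40, 76.8),
            (4.68, 30, 5.78, 69, 67.6),
            (3.21, 30, 3.28, 69, 56.3),
            (1.75, 25, 1.57, 60, 40.8),
            (6.71, 40, 5.39, 40, 74.5),
        ],
    )
    def test_satterthwaite_df_matches_printed(self, s1, n1, s2, n2, printed_df):
        res = welch_from_summaries(
            GroupSummary(n1, 10.0, s1), GroupSummary(n2, 9.0, s2)
        )
        assert res.df == pytest.approx(printed_df, abs=0.15)

    def test_t_from_printed_upper_lip_summaries(self):
        # direct formula evaluation on rounded summaries (printed t is 4.37
        # from unrounded raw data)
        res = welch_from_summaries(
            GroupSummary(40, 22.8, 2.41), GroupSummary(40, 20.4, 2.35)
        )
        assert res.statistic == pytest.approx(4.509, abs=0.001)
        assert res.df == pytest.approx(77.95, abs=0.01)

    def test_equal_means_give_zero_t(self):
        res = welch_from_summaries(
            GroupSummary(10, 5.0, 1.0), GroupSummary(20, 5.0, 3.0)
        )
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_median_iqr_requires_flag(self):
        s1 = GroupSummary(10, 5.0, 1.0, kind="median_iqr")
        s2 = GroupSummary(10, 6.0, 1.0)
        with pytest.raises(ValueError, match="median_approx"):
            welch_from_summaries(s1, s2)
        res = welch_from_summaries(s1, s2, median_approx=True)
        assert res.approximated_from_median_iqr

    def test_copied_sample_gives_zero_t(self):
        x = np.array([1.0, 2.0, 3.5, 4.0])
        res = welch_t(x, x.copy())
        assert res.statistic == 0.0

    def test_raw_equals_summary_route(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 13), rng.normal(0.4, 2, 29)
        raw = welch_t(x, y)
        summ = welch_from_summaries(summarize(x), summarize(y))
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.df == pytest.approx(summ.df, abs=1e-12)
        assert raw.p == pytest.approx(summ.p, abs=1e-12)

    def test_against_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(5, 40))
            y = rng.normal(0.3, 1.7, rng.integers(5, 40))
            res = welch_t(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)
            assert res.df == pytest.approx(ref.df, rel=1e-12)

    def test_constant_samples_error(self):
        with pytest.raises(DegenerateVarianceError):
            welch_t([3.0, 3.0, 3.0], [4.0, 4.0])

    @given(summary_strategy, summary_strategy)
    @settings(max_examples=200, deadline=None)
    def test_df_bounds_property(self, s1, s2):
        res = welch_from_summaries(s1, s2)
        assert min(s1.n, s2.n) - 1 <= res.df + 1e-9
        assert res.df <= s1.n + s2.n - 2 + 1e-9

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(42)
        n_sim = 10_000
        x = rng.normal(0.0, 1.0, size=(n_sim, 30))
        y = rng.normal(0.0, 1.0, size=(n_sim, 69))
        rejections = sum(welch_t(x[i], y[i]).p < 0.05 for i in range(n_sim))
        assert rejections / n_sim == pytest.approx(0.05, abs=0.01)


class TestCohensD:
    def test_equal_means_symmetric_ci(self):
        d, (lo, hi) = cohens_d(GroupSummary(20, 5.0, 1.0), GroupSummary(30, 5.0, 2.0))
        assert d == 0.0
        assert lo == pytest.approx(-hi)

    def test_printed_ci_reproduction(self):
        # published d = 0.81 with n = 30/69 printed CI [0.36, 1.26]
        lo, hi = d_confidence_interval(0.81, 30, 69)
        assert lo == pytest.approx(0.36, abs=0.01)
        assert hi == pytest.approx(1.26, abs=0.01)

    def test_forehead_height_effect_size(self):
        d, _ = cohens_d(GroupSummary(40, 57.6, 5.39), GroupSummary(40, 50.4, 6.71))
        assert d == pytest.approx(1.18, abs=0.005)  # printed 1.17 from unrounded data
        assert d == pytest.approx(1.17, abs=0.02)

    @given(summary_strategy, summary_strategy)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, s1, s2):
        d12, ci12 = cohens_d(s1, s2)
        d21, ci21 = cohens_d(s2, s1)
        assert d12 == pytest.approx(-d21, rel=1e-9, abs=1e-12)
        assert ci12[0] == pytest.approx(-ci21[1], rel=1e-9, abs=1e-12)
        assert ci12[1] == pytest.approx(-ci21[0], rel=1e-9, abs=1e-12)

    @given(summary_strategy, summary_strategy)
    @settings(max_examples=100, deadline=None)
    def test_ci_contains_d(self, s1, s2):
        d, (lo, hi) = cohens_d(s1, s2)
        assert lo <= d <= hi


def exact_rank_sum_p(x, y):
    """Full-enumeration two-sided Mann-Whitney p (no ties)."""
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    u_obs = sum(xi > yj for xi in x for yj in y)
    dev_obs = abs(u_obs - n1 * n2 / 2)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(xi > yj for xi in xs for yj in ys)
        total += 1
        count += abs(u - n1 * n2 / 2) >= dev_obs - 1e-12
    return count / total


class TestRankSum:
    def test_fully_separated_three_vs_three(self):
        res = rank_sum_test([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == 9
        assert res.p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = rank_sum_test(x, list(x))
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("n1, n2, seed", [(2, 3, 0), (3, 3, 1), (4, 5, 2), (5, 5, 3), (5, 2, 4)])
    def test_exact_p_matches_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n1)
        y = rng.normal(0.8, 1, n2)
        res = rank_sum_test(x, y)
        assert res.p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_u_convention(self):
        x, y = [10.0, 20.0], [1.0, 2.0, 3.0]
        res = rank_sum_test(x, y)
        assert res.statistic == 6  # all 2*3 pairs have x > y

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientDataError):
            rank_sum_test([], [1.0])


class TestChooseTest:
    def test_gaussian_samples_mostly_parametric(self):
        parametric = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            decision = choose_test(rng.normal(0, 1, 40), rng.normal(0, 1, 40))
            parametric += decision["choice"] == "parametric"
        assert parametric >= 17

    def test_lognormal_triggers_nonparametric(self):
        rng = np.random.default_rng(5)
        decision = choose_test(rng.lognormal(0, 1, 40), rng.normal(0, 1, 40))
        assert decision["choice"] == "nonparametric"

    def test_small_group_raises(self):
        with pytest.raises(InsufficientDataError):
            choose_test([1.0, 2.0], [1.0, 2.0, 3.0])


def moment_matched_sample(n, mean, sd, seed):
    """Raw data whose sample mean/SD equal the targets exactly."""
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1, n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestAnova:
    def test_equal_means_zero_f(self):
        groups = [GroupSummary(10, 5.0, s) for s in (1.0, 2.0, 3.0)]
        assert anova_from_summaries(groups).F == 0.0

    def test_three_group_male_scores(self):
        groups = [
            GroupSummary(54, 14.5, 2.69),
            GroupSummary(30, 14.0, 2.81),
            GroupSummary(69, 11.6, 3.19),
        ]
        res = anova_from_summaries(groups)
        assert (res.df_between, res.df_within) == (2, 150)
        assert res.F == pytest.approx(16.4, abs=0.05)  # printed 16.8 from raw data
        assert res.p < 0.001

    def test_two_groups_rejected_by_default(self):
        groups = [GroupSummary(10, 5.0, 1.0), GroupSummary(10, 6.0, 1.0)]
        with pytest.raises(ValueError, match="welch"):
            anova_from_summaries(groups)

    def test_summary_equals_raw_on_moment_matched_data(self):
        targets = [(12, 3.0, 1.2), (15, 4.5, 0.8), (20, 3.8, 2.0)]
        samples = [moment_matched_sample(n, m, s, seed=i) for i, (n, m, s) in enumerate(targets)]
        raw = anova_raw(samples)
        summ = anova_from_summaries([GroupSummary(n, m, s) for n, m, s in targets])
        assert raw.F == pytest.approx(summ.F, rel=1e-9)
        assert raw.p == pytest.approx(summ.p, rel=1e-9)

    def test_k2_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(0, 1, rng.integers(5, 30))
            y = rng.normal(0.5, 1, rng.integers(5, 30))
            res = anova_raw([x, y], allow_two_groups=True)
            t_pooled = sps.ttest_ind(x, y, equal_var=True).statistic
            assert res.F == pytest.approx(t_pooled**2, rel=1e-9)

    def test_against_scipy_f_oneway(self):
        rng = np.random.default_rng(9)
        samples = [rng.normal(m, 1.0, 25) for m in (0.0, 0.3, 0.9)]
        res = anova_raw(samples)
        ref = sps.f_oneway(*samples)
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-8)


class TestTukey:
    def test_identical_groups_p_near_one(self):
        g = np.arange(10.0)
        res = tukey_hsd([g, g.copy(), g.copy()])
        assert all(p > 0.999 for _, _, p in res.tukey_pairs)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        c = rng.normal(5, 1, 30)  # 5 pooled SDs away
        res = tukey_hsd([a, b, c], labels=["a", "b", "c"])
        pmap = {pair: p for pair, _, p in res.tukey_pairs}
        assert pmap[("a", "b")] > 0.5
        assert pmap[("a", "c")] < 0.001
        assert pmap[("b", "c")] < 0.001

    def test_adjusted_p_not_below_pairwise(self):
        rng = np.random.default_rng(33)
        samples = [rng.normal(m, 1.0, 15) for m in (0.0, 0.4, 0.8)]
        res = tukey_hsd(samples)
        for (i, j), (_, _, p_adj) in zip(itertools.combinations(range(3), 2), res.tukey_pairs):
            p_unadj = sps.ttest_ind(samples[i], samples[j], equal_var=True).pvalue
            assert p_adj >= p_unadj - 1e-12

    def test_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(17)
        samples = [rng.normal(m, 1.0, 20) for m in (0.0, 0.5, 1.1)]
        res = tukey_hsd(samples, labels=["g0", "g1", "g2"])
        values = np.concatenate(samples)
        labels = np.repeat(["g0", "g1", "g2"], 20)
        ref = sm.pairwise_tukeyhsd(values, labels)
        for (_, diff, p), ref_diff, ref_p in zip(res.tukey_pairs, ref.meandiffs, ref.pvalues):
            assert diff == pytest.approx(-ref_diff, rel=1e-9)
            assert p == pytest.approx(ref_p, abs=1e-4)


class TestPower:
    def test_published_minimum_sample_sizes(self):
        assert min_n_for_power(PowerSpec(effect_f=0.42)) == 62
        assert min_n_for_power(PowerSpec(effect_f=0.82)) == 18

    def test_trivial_power_target_floor(self):
        assert min_n_for_power(PowerSpec(effect_f=0.5, power=0.0001)) == 4
        assert min_n_for_power(PowerSpec(effect_f=0.5, power=0.0001, k=3)) == 6

    def test_monotone_in_effect_size(self):
        ns = [min_n_for_power(PowerSpec(effect_f=f)) for f in (0.2, 0.4, 0.6, 0.8)]
        assert ns == sorted(ns, reverse=True)

    def test_monotone_in_alpha(self):
        n_strict = min_n_for_power(PowerSpec(effect_f=0.4, alpha=0.01))
        n_loose = min_n_for_power(PowerSpec(effect_f=0.4, alpha=0.10))
        assert n_strict >= n_loose

    def test_monotone_in_power(self):
        n_lo = min_n_for_power(PowerSpec(effect_f=0.4, power=0.80))
        n_hi = min_n_for_power(PowerSpec(effect_f=0.4, power=0.95))
        assert n_hi >= n_lo

    def test_unreachable_power_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            min_n_for_power(PowerSpec(effect_f=0.001, power=0.99), max_n=200)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PowerSpec(effect_f=-1.0)
        with pytest.raises(ValueError):
            PowerSpec(effect_f=0.5, alpha=1.5)
        with pytest.raises(ValueError):
            PowerSpec(effect_f=0.5, k=1)


class TestHolm:
    def test_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        p = [0.001, 0.04, 0.03, 0.2, 0.8]
        ref = mt.multipletests(p, method="holm")[1]
        np.testing.assert_allclose(holm_adjust(p), ref)
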