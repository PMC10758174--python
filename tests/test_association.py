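import numpy as np
import pandas as pd
import pytest
from scipy import stats

from culturedist.association import (
    GroupSummary,
    influential_item_count,
    polynomial_trend_regression,
    posthoc_distal,
    quartile_trend_anova,
    summary_stat_anova,
    variance_heterogeneity,
)
from culturedist.ratings import RatingsMatrix


def _balanced(y_by_group):
    y, q = [], []
    for g, vals in enumerate(y_by_group, start=1):
        y += list(vals)
        q += [g] * len(vals)
    return pd.Series(y, dtype=float), pd.Series(q)


class TestPolynomialTrend:
    def test_pure_linear_relation(self):
        x = np.linspace(-2, 3, 40)
        out = polynomial_trend_regression(x, 2 * x + 1)
        assert out.loc[1, "r_squared"] == pytest.approx(1.0)
        assert out.loc[2, "delta_r_squared"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[3, "delta_r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_cubic_component_detected(self):
        # closed form: x^3 - x on a symmetric grid projects onto the odd
        # orthogonal polynomials; the cubic increment is exact, so its
        # F-change p-value vanishes
        x = np.linspace(-3, 3, 25)
        out = polynomial_trend_regression(x, x**3 - x)
        assert out.loc[3, "p_change"] < 0.01
        assert out.loc[3, "r_squared"] == pytest.approx(1.0)

    def test_constant_outcome_gives_zero_correlations(self):
        x = np.linspace(0, 1, 20)
        out = polynomial_trend_regression(x, np.full(20, 3.3))
        assert (out["r"].fillna(0) == 0).all()
        assert (out["delta_r_squared"] == 0).all()

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            polynomial_trend_regression(np.ones(20), np.arange(20.0))


class TestQuartileTrendANOVA:
    def test_equal_means_give_null_statistics(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        y, q = _balanced([base, base, base, base])
        res = quartile_trend_anova(y, q)
        assert res.f_overall == pytest.approx(0.0, abs=1e-20)
        assert res.eta == pytest.approx(0.0, abs=1e-10)

    def test_pure_linear_trend_loads_on_linear_contrast(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(loc=g, scale=1.0, size=33) for g in range(4)]
        res = quartile_trend_anova(*_balanced(groups))
        assert res.f_linear / max(res.f_nonlinear, 1e-12) >= 10

    def test_sum_of_squares_decomposition_identity(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc=m, size=25) for m in (0, 2, 1, 3)]
        res = quartile_trend_anova(*_balanced(groups))
        assert res.ss_linear + res.ss_nonlinear == pytest.approx(
            res.ss_between, abs=1e-9)

    def test_eta_squared_identity_at_study_dfs(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc=m, size=n)
                  for m, n in zip((0, 1, 0.5, 2), (34, 33, 33, 33))]
        res = quartile_trend_anova(*_balanced(groups))
        assert res.df_within == 129
        implied = 3 * res.f_overall / (3 * res.f_overall + 129)
        assert res.eta_squared == pytest.approx(implied, rel=1e-9)

    def test_undersized_group_rejected(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        q = pd.Series([1, 1, 2, 2, 3, 3, 4])  # quartile 4 has one member
        with pytest.raises(ValueError, match="fewer than 2"):
            quartile_trend_anova(y, q)


class TestSummaryStatANOVA:
    def test_matches_raw_anova_exactly_on_balanced_data(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(loc=m, scale=s, size=20)
                  for m, s in zip((0, 1, 3, 2), (1, 2, 1.5, 3))]
        y, q = _balanced(groups)
        raw = quartile_trend_anova(y, q)
        summaries = [GroupSummary(g + 1, v.mean(), v.std(ddof=1), len(v))
                     for g, v in enumerate(groups)]
        reco = summary_stat_anova(summaries)
        for attr in ("f_overall", "f_linear", "f_nonlinear", "eta",
                     "ss_between", "ss_within"):
            assert getattr(reco, attr) == pytest.approx(
                getattr(raw, attr), abs=1e-9, rel=1e-9)

    def test_equal_groups_give_zero_f(self):
        groups = [GroupSummary(i, 10.0, 2.0, 30) for i in range(1, 5)]
        res = summary_stat_anova(groups)
        assert res.f_overall == pytest.approx(0.0, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            GroupSummary(1, 0.0, 1.0, 1)


class TestPosthocDistal:
    def test_distal_deficit_detected_reliably(self):
        # distal group one pooled s.d. below the rest, n=33 per group.
        # Tukey-adjusted per-contrast power at these conditions is ~0.93
        # (noncentral t with the studentized-range critical value), so the
        # joint all-three rate is bounded below by ~0.93^3 ~ 0.79.
        joint = 0
        single = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(loc=0, size=33) for _ in range(3)]
            groups.append(rng.normal(loc=-1, size=33))
            out = posthoc_distal(*_balanced(groups))
            joint += out["distal_lower"].all()
            single += out["distal_lower"].mean()
        assert joint / reps >= 0.75
        assert single / reps >= 0.85

    def test_identical_groups_show_no_contrasts(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=33)
        out = posthoc_distal(*_balanced([base, base, base, base]))
        assert not out["distal_lower"].any()
        assert (out["p_value"] > 0.99).all()

    def test_two_group_reduction_agrees_with_t_test(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=30)
        b = rng.normal(loc=0.7, size=30)
        out = posthoc_distal(*_balanced([a, b]))
        t_p = stats.ttest_ind(b, a).pvalue
        assert out["p_value"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_scheffe_option(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(loc=m, size=20) for m in (0, 0, 0, -2)]
        out = posthoc_distal(*_balanced(groups), method="scheffe")
        assert out["distal_lower"].all()


class TestVarianceHeterogeneity:
    def test_type_one_error_rate_near_nominal(self):
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(size=33) for _ in range(4)]
            _, p, _ = variance_heterogeneity(*_balanced(groups))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_inflated_distal_variance_detected(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(size=33) for _ in range(3)]
            groups.append(rng.normal(scale=3.0, size=33))
            _, p, variances = variance_heterogeneity(*_balanced(groups))
            hits += (p <= 0.001) and (variances.idxmax() == 4)
        assert hits / reps >= 0.9

    def test_scale_invariance_of_p_value(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(scale=s, size=20) for s in (1, 1, 2, 3)]
        y, q = _balanced(groups)
        _, p1, _ = variance_heterogeneity(y, q)
        _, p2, _ = variance_heterogeneity(10 * y, q)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestInfluentialItemCount:
    def test_all_influential(self):
        m = RatingsMatrix.from_arrays(4 * np.ones((2, 29)), "TG")
        assert (influential_item_count(m) == 29).all()

    def test_dichotomisation_boundary(self):
        m = RatingsMatrix.from_arrays(np.array([[1, 2, 3, 4]], float), "TG",
                                      items=list("ABCD"))
        assert influential_item_count(m).iloc[0] == 2

    def test_quartile_means(self):
        vals = np.array([[4] * 4, [4] * 4, [1] * 4, [1, 1, 1, 4]], float)
        m = RatingsMatrix.from_arrays(vals, "TG", items=list("ABCD"))
        quart = pd.Series([1, 1, 2, 2], index=m.values.index)
        counts, means = influential_item_count(m, quart)
        assert means.loc[1] == 4.0
        assert means.loc[2] == 0.5
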