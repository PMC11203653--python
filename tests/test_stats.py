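"""Tests of the statistics layer against independent references."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from calfmolli.stats import (InsufficientDataError, categorical_test,
                             compare_groups, icc_two_way_average,
                             univariate_regression)

# fixed fixtures for oracle comparisons
A_FIX = [12.1, 14.3, 11.8, 13.2, 15.0, 12.7, 13.9, 14.6, 12.4, 13.1]
B_FIX = [10.2, 11.7, 12.9, 10.8, 11.3, 12.2, 10.5, 11.9, 12.6, 11.1]
SKEWED = [1.0, 1.1, 1.2, 1.3, 1.6, 2.4, 5.9, 11.2, 30.0, 80.0]


class TestCompareGroups:
    def test_identical_groups_give_large_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 30)
        c = compare_groups(a, a.copy())
        assert c.p_value > 0.9

    def test_separated_groups_give_tiny_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, 10)
        c = compare_groups(a + 1000.0, a)
        assert c.p_value < 0.001

    def test_normal_branch_matches_scipy_ttest(self):
        c = compare_groups(A_FIX, B_FIX)
        assert c.test_used == "t"
        ref = sps.ttest_ind(A_FIX, B_FIX, equal_var=True)
        assert c.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert c.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert "±" in c.summary_a  # normal branch formats mean ± sd

    def test_nonnormal_branch_matches_scipy_mannwhitney(self):
        c = compare_groups(SKEWED, B_FIX)
        assert c.test_used == "mann_whitney"
        ref = sps.mannwhitneyu(SKEWED, B_FIX, alternative="two-sided",
                               method="asymptotic")
        assert c.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert "(" in c.summary_a  # median (IQR) format

    def test_symmetry_in_group_order(self):
        c1 = compare_groups(A_FIX, B_FIX)
        c2 = compare_groups(B_FIX, A_FIX)
        assert c1.p_value == pytest.approx(c2.p_value, abs=1e-12)
        assert c1.statistic == pytest.approx(-c2.statistic, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCategorical:
    def test_smoking_history_reproduces_printed_p(self):
        # 16/18 vs 8/19 with a history of smoking
        p, test = categorical_test([[16, 2], [8, 11]])
        assert test == "fisher"
        assert abs(p - 0.006) < 1e-3  # agreement at the printed precision

    def test_balanced_table_p_is_one(self):
        p, _ = categorical_test([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_fisher_equals_hypergeometric_tail_sum(self):
        """Two-sided Fisher p for a diagonal table equals the enumerated
        sum of hypergeometric probabilities no larger than the observed."""
        table = [[10, 0], [0, 10]]
        p, test = categorical_test(table)
        assert test == "fisher"
        n, K, N = 20, 10, 10  # total, row-1 margin, col-1 margin
        probs = [sps.hypergeom.pmf(k, n, K, N) for k in range(11)]
        p_obs = sps.hypergeom.pmf(10, n, K, N)
        ref = sum(q for q in probs if q <= p_obs * (1 + 1e-12))
        assert p == pytest.approx(ref, rel=1e-10)

    def test_large_cell_2x2_uses_pearson_chi2(self):
        p, test = categorical_test([[11, 7], [11, 8]])
        assert test == "chi2"
        ref = sps.chi2_contingency([[11, 7], [11, 8]], correction=False).pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            categorical_test([[0, 0], [0, 0]])


class TestRegression:
    def test_perfect_fit(self):
        x = np.arange(10, dtype=float)
        r = univariate_regression(2 * x, x)
        assert r.beta_std == pytest.approx(1.0, abs=1e-12)
        assert r.r2 == pytest.approx(1.0, abs=1e-12)
        assert r.p_value < 1e-12

    def test_matches_closed_form_ols_on_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 2.9, 4.2, 3.8, 5.4])
        r = univariate_regression(y, x)
        n = 5
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        se = np.sqrt(np.sum(resid**2) / (n - 2) / sxx)
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        assert r.slope_raw == pytest.approx(slope, abs=1e-10)
        assert r.slope_se == pytest.approx(se, abs=1e-10)
        assert r.r2 == pytest.approx(r2, abs=1e-10)
        t = slope / se
        assert r.p_value == pytest.approx(2 * sps.t.sf(abs(t), n - 2), abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = 0.7 * x + rng.normal(size=25)
        r = univariate_regression(y, x)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert r.slope_raw == pytest.approx(fit.params[1], abs=1e-10)
        assert r.slope_se == pytest.approx(fit.bse[1], abs=1e-10)
        assert r.r2 == pytest.approx(fit.rsquared, abs=1e-10)
        assert r.p_value == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_identities_and_negative_adjusted_r2(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        y = rng.normal(size=30)  # independent noise
        r = univariate_regression(y, x)
        # standardized beta equals Pearson r; r2 equals its square
        pearson = sps.pearsonr(x, y).statistic
        assert r.beta_std == pytest.approx(pearson, abs=1e-12)
        assert r.r2 == pytest.approx(r.beta_std**2, abs=1e-12)
        assert r.adj_r2 <= r.r2
        assert abs(r.beta_std) < 0.3
        # weak association can legitimately yield a negative adjusted r2
        if r.r2 < 1 / 29:
            assert r.adj_r2 < 0

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            univariate_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestIcc:
    def test_identical_raters_give_exactly_one(self):
        X = np.column_stack([np.arange(6.0), np.arange(6.0)])
        r = icc_two_way_average(X)
        assert r.icc == 1.0
        assert r.ci_low == r.ci_high == 1.0
        assert r.excellent

    def test_offset_raters_approach_one_as_target_variance_grows(self):
        """Absolute agreement penalizes a fixed offset by a vanishing
        fraction as between-target variance grows; oracle is the direct
        ANOVA mean-squares arithmetic on a 6x2 matrix."""
        base = np.arange(6.0)
        iccs = []
        for scale in (1.0, 10.0, 100.0):
            X = np.column_stack([scale * base, scale * base + 3.0])
            n, k = X.shape
            grand = X.mean()
            msr = k * np.sum((X.mean(1) - grand) ** 2) / (n - 1)
            msc = n * np.sum((X.mean(0) - grand) ** 2) / (k - 1)
            mse = (np.sum((X - grand) ** 2)
                   - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
            oracle = (msr - mse) / (msr + (msc - mse) / n)
            r = icc_two_way_average(X)
            assert r.icc == pytest.approx(oracle, abs=1e-12)
            iccs.append(r.icc)
        assert iccs[0] < iccs[1] < iccs[2]
        assert iccs[2] > 0.999

    def test_independent_raters_near_zero_with_ci_covering_zero(self):
        rng = np.random.default_rng(123)
        X = rng.normal(size=(20, 2))
        r = icc_two_way_average(X)
        assert abs(r.icc) < 0.5
        assert r.ci_low < 0.0 < r.ci_high

    def test_matches_pingouin_icc2k(self):
        import pingouin as pg
        rng = np.random.default_rng(1)
        X = rng.normal(10, 2, (12, 2)) + rng.normal(0, 0.5, (12, 1))
        r = icc_two_way_average(X)
        df = pd.DataFrame({"t": np.repeat(np.arange(12), 2),
                           "r": np.tile([0, 1], 12), "s": X.ravel()})
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="s")
        row = ref[ref["Type"] == "ICC(A,k)"]
        if row.empty:
            row = ref[ref["Type"] == "ICC2k"]
        row = row.iloc[0]
        assert r.icc == pytest.approx(row["ICC"], abs=1e-10)
        lo, hi = row["CI95"] if "CI95" in row else row["CI95%"]
        assert r.ci_low == pytest.approx(lo, abs=5e-3)  # pingouin rounds CI
        assert r.ci_high == pytest.approx(hi, abs=5e-3)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(50, 5, (10, 3))
        r = icc_two_way_average(X)
        r2 = icc_two_way_average(3.7 * X + 100.0)
        assert r2.icc == pytest.approx(r.icc, abs=1e-12)
        assert r2.ci_low == pytest.approx(r.ci_low, abs=1e-9)

    def test_incomplete_matrix_rejected(self):
        X = np.ones((4, 2))
        X[1, 1] = np.nan
        with pytest.raises(ValueError):
            icc_two_way_average(X)
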