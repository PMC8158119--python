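"""Rank-sum, chi-square, correlation, regression and sample-size machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acunet import (SampleSizeInputs, ValidationError, chi_square_2x2,
                    group_summary, linear_regression, pearson_correlation,
                    sample_size, wilcoxon_rank_sum)
from acunet.stats import exact_rank_sum_p_by_enumeration


class TestWilcoxonExamples:
    def test_two_vs_two(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert res.p_value == pytest.approx(1 / 3)
        assert res.exact

    def test_three_vs_three(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], mode="exact")
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1, 2])

    def test_auto_switches_to_normal(self):
        x = list(range(15))
        y = list(range(5, 20))
        res = wilcoxon_rank_sum(x, y, mode="auto")
        assert not res.exact and "normal" in res.method


small_samples = st.lists(st.integers(min_value=0, max_value=5),
                         min_size=1, max_size=5)


class TestWilcoxonProperties:
    @given(small_samples, small_samples)
    @settings(max_examples=150, deadline=None)
    def test_exact_matches_enumeration_oracle(self, x, y):
        p_fast = wilcoxon_rank_sum(x, y, mode="exact").p_value
        p_slow = exact_rank_sum_p_by_enumeration(x, y)
        assert p_fast == pytest.approx(p_slow, abs=1e-12)

    @given(small_samples, small_samples)
    @settings(max_examples=60, deadline=None)
    def test_symmetry(self, x, y):
        assert wilcoxon_rank_sum(x, y, mode="exact").p_value == pytest.approx(
            wilcoxon_rank_sum(y, x, mode="exact").p_value)

    @given(small_samples, small_samples)
    @settings(max_examples=60, deadline=None)
    def test_monotone_transform_invariance(self, x, y):
        f = lambda v: [math.exp(t) + 3 * t for t in v]  # strictly increasing
        p1 = wilcoxon_rank_sum(x, y, mode="exact").p_value
        p2 = wilcoxon_rank_sum(f(x), f(y), mode="exact").p_value
        assert p1 == pytest.approx(p2)

    def test_scipy_cross_check_no_ties(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(0.5, size=7)
            mine = wilcoxon_rank_sum(x, y, mode="exact").p_value
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)


class TestChiSquare:
    @pytest.mark.parametrize("table,expected_p", [
        ((11, 2, 18, 4), 0.8320),   # fertilization, all participants
        ((9, 1, 16, 4), 0.4884),    # fertilization, age > 37
        ((8, 1, 18, 4), 0.6271),    # fertilization, > 1 prior cycle
    ])
    def test_published_fertilization_tables(self, table, expected_p):
        assert chi_square_2x2(*table).p_value == pytest.approx(expected_p, abs=5e-5)

    def test_proportional_rows_give_zero(self):
        res = chi_square_2x2(10, 10, 20, 20)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_invariance_under_table_symmetries(self):
        base = chi_square_2x2(11, 2, 18, 4).statistic
        assert chi_square_2x2(11, 18, 2, 4).statistic == pytest.approx(base)  # transpose
        assert chi_square_2x2(18, 4, 11, 2).statistic == pytest.approx(base)  # row swap
        assert chi_square_2x2(2, 11, 4, 18).statistic == pytest.approx(base)  # col swap

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2(0, 0, 5, 5)

    def test_scipy_cross_check(self):
        from scipy.stats import chi2_contingency
        stat, p, _, _ = chi2_contingency([[11, 2], [18, 4]], correction=False)
        res = chi_square_2x2(11, 2, 18, 4)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_yates_shrinks_statistic(self):
        assert chi_square_2x2(11, 2, 18, 4, yates=True).statistic <= \
               chi_square_2x2(11, 2, 18, 4).statistic


class TestCorrelation:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pearson_correlation(x, [2 * v for v in x])
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_correlation(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1, 2, 3], [5, 5, 5])

    def test_recovers_population_correlation(self):
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=1000)
        res = pearson_correlation(z[:, 0], z[:, 1])
        assert res.statistic == pytest.approx(0.5, abs=0.1)

    def test_scipy_cross_check(self):
        from scipy.stats import pearsonr
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = pearson_correlation(x, y)
        ref = pearsonr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestRegression:
    def test_noiseless_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = linear_regression(3 + 2 * x, x, names=["x"])
        assert fit.coef == pytest.approx([3.0, 2.0])
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        y = 1.0 + 0.5 * X[:, 0] - 1.2 * X[:, 1] + rng.normal(size=40)
        fit = linear_regression(y, X, names=["a", "b"])
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.coef == pytest.approx(ref.params, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse, abs=1e-6)
        assert fit.p == pytest.approx(ref.pvalues, abs=1e-6)
        assert fit.r_squared == pytest.approx(ref.rsquared, abs=1e-9)

    def test_five_point_numeric_oracle(self):
        # brute-force numeric minimisation of the sum of squares
        from scipy.optimize import minimize
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 2.9, 5.2, 6.8, 9.1])
        fit = linear_regression(y, x, names=["x"])
        obj = lambda b: ((y - b[0] - b[1] * x) ** 2).sum()
        ref = minimize(obj, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12}).x
        assert fit.coef == pytest.approx(ref, abs=1e-6)

    def test_rank_deficiency_names_column(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValidationError, match="dup"):
            linear_regression(x, X, names=["orig", "dup"])

    def test_coverage_of_confidence_intervals(self):
        # 95% CI for the slope should cover the truth ~95% of the time
        rng = np.random.default_rng(31)
        from scipy import stats as sps
        hits = 0
        n_rep, n = 400, 30
        for _ in range(n_rep):
            x = rng.normal(size=n)
            y = 1.0 + 0.8 * x + rng.normal(size=n)
            fit = linear_regression(y, x, names=["x"])
            tcrit = sps.t.ppf(0.975, n - 2)
            lo = fit.coef[1] - tcrit * fit.se[1]
            hi = fit.coef[1] + tcrit * fit.se[1]
            hits += lo <= 0.8 <= hi
        assert 0.92 <= hits / n_rep <= 0.98


class TestGroupSummary:
    def test_formatting(self):
        df = pd.DataFrame({"arm": ["A"] * 3 + ["B"] * 3,
                           "v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        tab = group_summary(df, ["v"], by="arm")
        assert tab.loc["v", "A"] == "2.00 ± 1.00"
        assert tab.loc["v", "p_value"] == 1.0

    def test_unknown_variable_rejected(self):
        df = pd.DataFrame({"arm": ["A", "B"], "v": [1, 2]})
        with pytest.raises(ValidationError):
            group_summary(df, ["w"], by="arm")


class TestSampleSize:
    def test_planned_followup_trial_inputs(self):
        inputs = SampleSizeInputs(z_alpha_half=1.96, z_beta=0.8416,
                                  sigma=1.18, delta=1.15, dropout=0.0)
        unadj, infl = sample_size(inputs)
        assert unadj == 17
        assert infl == 17  # no dropout: inflation is the identity

    def test_huge_effect_floor(self):
        unadj, _ = sample_size(SampleSizeInputs(sigma=1.0, delta=1e6))
        assert unadj == 1

    def test_dropout_inflation(self):
        unadj, infl = sample_size(SampleSizeInputs(sigma=1.18, delta=1.15,
                                                   dropout=0.2))
        assert unadj == 17 and infl == math.ceil(17 / 0.8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            SampleSizeInputs(sigma=0.0)
        with pytest.raises(ValidationError):
            SampleSizeInputs(delta=0.0)
        with pytest.raises(ValidationError):
            SampleSizeInputs(dropout=1.0)
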