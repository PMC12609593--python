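import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rdnacn import (descriptive_summary, mann_whitney_u, minimum_cn_analysis,
                    normality_tests, pregnancy_regression, spearman_rho)

MINIMA_ALL = [43, 47, 50, 55, 56]
MINIMA_PREG = [61, 65, 67, 69, 69]


def brute_force_exact_p(a, b):
    """Exhaustive permutation two-sided p for the rank-sum statistic."""
    from scipy.stats import rankdata

    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    n_a = len(a)
    s_obs = ranks[:n_a].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n_a)]
    sums = np.array(sums)
    lower = (sums <= s_obs + 1e-9).mean()
    upper = (sums >= s_obs - 1e-9).mean()
    return min(1.0, 2 * min(lower, upper))


class TestDescriptiveSummary:
    def test_printed_minima_row(self):
        s = descriptive_summary(MINIMA_ALL)
        assert s.mean == pytest.approx(50.2)
        assert s.median == 50
        assert (s.min, s.max) == (43, 56)

    def test_single_value(self):
        s = descriptive_summary([7.0])
        assert s.mean == s.median == s.min == s.max == 7.0
        assert s.sd == 0.0 and not s.sd_defined

    def test_even_n_median_midpoint(self):
        assert descriptive_summary([1, 2, 3, 4]).median == 2.5

    def test_sample_sd_uses_n_minus_1(self):
        s = descriptive_summary([1.0, 3.0])
        assert s.sd == pytest.approx(math.sqrt(2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            descriptive_summary([])


class TestMannWhitney:
    def test_minima_lists_u_zero(self):
        res = mann_whitney_u(MINIMA_ALL, MINIMA_PREG, method="asymptotic")
        assert res.statistic == 0.0
        assert round(res.p_value, 3) == 0.009

    def test_minima_lists_exact(self):
        res = mann_whitney_u(MINIMA_ALL, MINIMA_PREG, method="exact")
        assert res.p_value == pytest.approx(2 / 252)

    def test_identical_groups_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3], method="exact")
        assert res.p_value == 1.0

    def test_degenerate_constant_data(self):
        res = mann_whitney_u([5, 5, 5], [5, 5])
        assert res.degenerate and res.p_value == 1.0

    def test_exact_matches_brute_force_4v4(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            a = rng.integers(0, 8, 4)
            b = rng.integers(0, 8, 4)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            res = mann_whitney_u(a, b, method="exact")
            assert res.p_value == pytest.approx(brute_force_exact_p(a, b), abs=1e-12)

    @given(st.lists(st.integers(0, 10), min_size=2, max_size=6),
           st.lists(st.integers(0, 10), min_size=2, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_equals_enumeration_property(self, a, b):
        if len(set(a) | set(b)) == 1:
            return
        res = mann_whitney_u(a, b, method="exact")
        assert res.p_value == pytest.approx(brute_force_exact_p(a, b), abs=1e-12)

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8),
           st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_u_complement_identity(self, a, b):
        u_ab = mann_whitney_u(a, b).statistic
        u_ba = mann_whitney_u(b, a).statistic
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_asymptotic_matches_scipy_no_ties(self):
        from scipy.stats import mannwhitneyu as scipy_mwu

        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 35)
        res = mann_whitney_u(a, b, method="asymptotic")
        ref = scipy_mwu(a, b, alternative="two-sided", method="asymptotic",
                        use_continuity=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


class TestSpearman:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_rho(x, x).statistic == pytest.approx(1.0)
        assert spearman_rho(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        # rho = 1 - 6*sum(d^2)/(n^3 - n); d = (-1, 1, -1, 1, 0) -> sum 4
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        expected = 1 - 6 * 4 / (5**3 - 5)
        assert spearman_rho(x, y).statistic == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        base = spearman_rho(x, y).statistic
        assert spearman_rho(np.exp(x), y).statistic == pytest.approx(base)
        assert spearman_rho(x, 3 * y + 7).statistic == pytest.approx(base)

    def test_pairwise_complete(self):
        x = [1, 2, np.nan, 4, 5]
        y = [1, 2, 3, 4, np.nan]
        res = spearman_rho(x, y)
        assert res.n == (3,)

    def test_zero_variance_flagged(self):
        res = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.degenerate

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])


class TestNormality:
    def test_uniform_rejected_normal_accepted(self):
        rng = np.random.default_rng(13)
        uniform = rng.uniform(0, 1, 500)
        ks_u, sw_u = normality_tests(uniform)
        assert sw_u.p_value < 0.05
        normal = rng.normal(0, 1, 500)
        _, sw_n = normality_tests(normal)
        assert sw_n.p_value > 0.001  # typically accepted

    def test_shapiro_type1_error_near_nominal(self):
        rng = np.random.default_rng(21)
        rejections = sum(
            normality_tests(rng.normal(size=80))[1].p_value < 0.05 for _ in range(400))
        assert 0.02 <= rejections / 400 <= 0.09

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            normality_tests([1.0, 2.0])

    def test_constant_flagged(self):
        ks, sw = normality_tests([2.0, 2.0, 2.0, 2.0])
        assert ks.degenerate and sw.degenerate


def _cohort_frame(n=300, beta=1.0, seed=0):
    rng = np.random.default_rng(seed)
    active = rng.normal(110, 30, n)
    conc = rng.normal(57, 20, n)
    mot = rng.normal(47, 15, n)
    morph = rng.normal(7, 3, n)
    age = rng.normal(39, 7, n)
    bmi = rng.normal(26, 4, n)
    z = beta * (active - 110) / 30
    p = 1 / (1 + np.exp(-z))
    preg = np.where(rng.random(n) < p, "yes", "no")
    return pd.DataFrame({
        "active_cn": active, "conc_mio_per_ml": conc, "motility_pct": mot,
        "morphology_pct": morph, "age": age, "bmi": bmi, "pregnancy": preg,
    })


class TestPregnancyRegression:
    def test_recovers_generating_slope(self):
        # true per-SD log-odds on active CN = 1; covariates are null
        fits = [pregnancy_regression(_cohort_frame(2000, beta=1.0, seed=s))
                for s in range(5)]
        est = np.median([f.coefficient("active_cn") for f in fits])
        assert est == pytest.approx(1.0, abs=0.12)

    def test_null_covariate_near_zero(self):
        fit = pregnancy_regression(_cohort_frame(2000, beta=1.0, seed=3))
        assert abs(fit.coefficient("bmi")) < 0.15
        assert fit.converged

    def test_single_class_outcome_rejected(self):
        df = _cohort_frame(100, beta=0.0, seed=1)
        df["pregnancy"] = "yes"
        with pytest.raises(ValueError, match="single class"):
            pregnancy_regression(df)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            pregnancy_regression(_cohort_frame(10))

    def test_perfect_separation_flagged(self):
        df = _cohort_frame(100, beta=0.0, seed=2)
        df["pregnancy"] = np.where(df["active_cn"] > 110, "yes", "no")
        fit = pregnancy_regression(df)
        assert fit.separation
        assert fit.table["p"].isna().all()

    def test_unknown_outcomes_dropped(self):
        df = _cohort_frame(200, beta=0.5, seed=4)
        df.loc[:20, "pregnancy"] = "unknown"
        fit = pregnancy_regression(df)
        assert fit.n == len(df) - 21


class TestMinimumCn:
    def _records(self):
        # 5 smallest overall are the worked-example minima; pregnancy stratum higher
        rng = np.random.default_rng(5)
        rest = rng.uniform(80, 200, 90)
        active = np.concatenate([MINIMA_ALL, MINIMA_PREG, rest])
        preg = np.array(["no"] * 5 + ["yes"] * 5 + ["yes"] * 45 + ["no"] * 45)
        return pd.DataFrame({"active_cn": active, "pregnancy": preg})

    def test_floor_and_comparison(self):
        res = minimum_cn_analysis(self._records(), k=5)
        assert res.overall_minima == tuple(float(v) for v in MINIMA_ALL)
        assert res.pregnancy_minima == tuple(float(v) for v in MINIMA_PREG)
        assert res.floor == 61.0
        assert res.comparison.p_value == pytest.approx(2 / 252)

    def test_identical_strata_p_one(self):
        df = pd.DataFrame({"active_cn": [50, 60, 70, 80, 90] * 2,
                           "pregnancy": ["yes"] * 10})
        res = minimum_cn_analysis(df, k=5)
        assert res.comparison.p_value == 1.0

    def test_k1_no_test(self):
        res = minimum_cn_analysis(self._records(), k=1)
        assert res.comparison is None
        assert res.floor == 61.0

    def test_small_stratum_rejected(self):
        df = pd.DataFrame({"active_cn": [1, 2, 3], "pregnancy": ["yes", "no", "no"]})
        with pytest.raises(ValueError):
            minimum_cn_analysis(df, k=5)
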