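"""Regression/test machinery against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from hipfatigue.stats import (
    first_last_ttest,
    interval_regression,
    multivariate_r2,
    slope_anova,
    stepwise_fit,
)


def ols_normal_equations(t, v):
    """Independent OLS oracle via the normal equations + closed-form t test."""
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ v)
    resid = v - X @ beta
    n = len(v)
    s2 = resid @ resid / (n - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    tstat = beta[1] / np.sqrt(cov[1, 1])
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(tstat), n - 2)
    ss_tot = np.sum((v - v.mean()) ** 2)
    r2 = 1 - resid @ resid / ss_tot
    return beta[1], beta[0], p, r2


class TestIntervalRegression:
    def test_exact_line(self):
        values = np.arange(1.0, 0.05, -0.1)  # 1.0, 0.9, ..., 0.1
        reg = interval_regression(values, np.arange(1, 11))
        assert reg.slope == pytest.approx(-0.1)
        assert reg.r2 == pytest.approx(1.0)
        assert reg.p_slope < 1e-6

    def test_constant_values(self):
        reg = interval_regression(np.full(10, 0.4), np.arange(10))
        assert reg.slope == 0.0 and reg.r2 == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        t = np.arange(1.0, 11.0)
        v = 0.8 - 0.05 * t + 0.02 * rng.standard_normal(10)
        reg = interval_regression(v, t)
        slope, intercept, p, r2 = ols_normal_equations(t, v)
        assert reg.slope == pytest.approx(slope, abs=1e-10)
        assert reg.intercept == pytest.approx(intercept, abs=1e-10)
        assert reg.p_slope == pytest.approx(p, abs=1e-10)
        assert reg.r2 == pytest.approx(r2, abs=1e-10)

    def test_constant_time_raises(self):
        with pytest.raises(ValueError, match="singular"):
            interval_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            interval_regression([1.0, 2.0], [1.0, 2.0])

    @given(scale=st.floats(0.01, 50.0), shift=st.floats(-10.0, 10.0))
    def test_slope_sign_and_p_invariance(self, scale, shift):
        """Positive scaling preserves slope sign; affine transforms preserve p."""
        t = np.arange(1.0, 11.0)
        v = np.array([0.9, 0.85, 0.88, 0.7, 0.75, 0.6, 0.55, 0.58, 0.4, 0.45])
        base = interval_regression(v, t)
        other = interval_regression(scale * v + shift, t)
        assert np.sign(other.slope) == np.sign(base.slope)
        assert other.p_slope == pytest.approx(base.p_slope, rel=1e-9)


class TestPairedT:
    def test_identical_vectors_convention(self):
        res = first_last_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_closed_form(self, rng):
        first = rng.standard_normal(12)
        d = 0.3 + 0.5 * rng.standard_normal(12)
        res = first_last_ttest(first, first + d)
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        assert res.statistic == pytest.approx(expected_t, abs=1e-10)

    def test_matches_textbook_oracle(self, rng):
        a = rng.standard_normal(20)
        b = a - 0.2 + 0.3 * rng.standard_normal(20)
        res = first_last_ttest(a, b)
        d = b - a
        from scipy.stats import t as tdist

        t_o = d.mean() / (d.std(ddof=1) / np.sqrt(20))
        p_o = 2 * tdist.sf(abs(t_o), 19)
        assert res.statistic == pytest.approx(t_o, abs=1e-10)
        assert res.p == pytest.approx(p_o, abs=1e-10)

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            first_last_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestSlopeAnova:
    def test_all_identical_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            slope_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    def test_equal_means_agree_with_permutation_oracle(self, rng):
        """Two groups with identical sample means: F ~ 0, permutation p ~ 1."""
        g1 = np.array([-0.1, 0.0, 0.1, -0.05, 0.05])
        g2 = np.array([-0.2, 0.2, -0.1, 0.1, 0.0])  # both means exactly 0
        res, _ = slope_anova({"a": g1, "b": g2})
        pooled = np.concatenate([g1, g2])
        rng_p = np.random.default_rng(0)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng_p.shuffle(pooled)
            f = _f_oracle([pooled[:5], pooled[5:]])
            count += f >= res.statistic
        assert res.p > 0.9
        assert count / n_perm > 0.9

    def test_matches_sum_of_squares_oracle(self, rng):
        groups = {
            "a": -0.3 + 0.1 * rng.standard_normal(8),
            "b": -0.1 + 0.1 * rng.standard_normal(10),
            "c": 0.05 + 0.1 * rng.standard_normal(9),
        }
        res, _ = slope_anova(groups)
        f_o = _f_oracle(list(groups.values()))
        assert res.statistic == pytest.approx(f_o, abs=1e-10)

    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.standard_normal(10)
        b = 0.5 + rng.standard_normal(12)
        res, pw = slope_anova({"a": a, "b": b})
        assert res.statistic == pytest.approx(pw["t"].iloc[0] ** 2, rel=1e-9)
        assert res.p == pytest.approx(pw["p"].iloc[0], rel=1e-9)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            slope_anova({"a": [1.0, 2.0], "b": [3.0]})


def _f_oracle(arrays):
    """Between/within sum-of-squares one-way F statistic."""
    grand = np.concatenate(arrays).mean()
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestMultivariate:
    def test_exact_linear_response(self, rng):
        X = rng.standard_normal((10, 4))
        y = 2.0 + 3.0 * X[:, 1]
        res = multivariate_r2(X, y)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_matrix_ols_oracle(self, rng):
        X = rng.standard_normal((10, 4))
        y = 1.0 + X @ np.array([0.5, -0.2, 0.0, 0.3]) + 0.2 * rng.standard_normal(10)
        res = multivariate_r2(X, y)
        design = np.column_stack([np.ones(10), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        resid = y - design @ beta
        r2_o = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert res.r2 == pytest.approx(r2_o, abs=1e-10)

    def test_noise_only_r2_matches_monte_carlo_expectation(self):
        """4 spurious predictors on 10 points: median R² over 100 seeds ~ 4/9."""
        r2s = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            r2s.append(multivariate_r2(rng.standard_normal((10, 4)),
                                       rng.standard_normal(10)).r2)
        assert np.median(r2s) == pytest.approx(4 / 9, abs=0.08)

    def test_rank_deficient_raises(self, rng):
        X = rng.standard_normal((10, 4))
        X[:, 3] = 2 * X[:, 0]
        with pytest.raises(ValueError, match="singular|rank"):
            multivariate_r2(X, rng.standard_normal(10))


def stepwise_stable_subsets(X, y, p_enter=0.05, p_remove=0.10):
    """Exhaustive 2^p oracle: subsets where no term would leave and none would enter."""
    cols = list(X.columns)
    stable = []
    for r in range(len(cols) + 1):
        for subset in itertools.combinations(cols, r):
            subset = list(subset)
            if subset:
                fit = sm.OLS(y, sm.add_constant(X[subset])).fit()
                pvals = fit.pvalues[1:]
                if (pvals > p_remove).any():
                    continue
            ok = True
            for c in cols:
                if c in subset:
                    continue
                fit = sm.OLS(y, sm.add_constant(X[subset + [c]])).fit()
                if fit.pvalues[c] < p_enter:
                    ok = False
                    break
            if ok:
                stable.append(frozenset(subset))
    return stable


class TestStepwise:
    def test_dominant_predictor_retained_alone(self, rng):
        t = np.arange(1.0, 11.0)
        X = pd.DataFrame(
            {
                "acc_max": t + 0.001 * rng.standard_normal(10),
                "acc_auc": rng.standard_normal(10),
                "acc_ss": rng.standard_normal(10),
                "acc_zcr": rng.standard_normal(10),
            }
        )
        res = stepwise_fit(X, t)
        assert res.retained_terms == ("acc_max",)
        assert res.term_pvalues["acc_max"] < 1e-6

    def test_pure_noise_rarely_retains(self):
        """Type-I behavior: selection takes the minimum of 4 term p-values, so the
        chance of an empty model is ~0.95^4 ~ 0.81 per run (independent oracle)."""
        empty = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((10, 4)),
                             columns=["m", "auc", "ss", "zcr"])
            res = stepwise_fit(X, rng.standard_normal(10))
            empty += not res.retained_terms
        assert empty / 100 == pytest.approx(0.95**4, abs=0.10)

    def test_matches_exhaustive_stable_subset_oracle(self, rng):
        t = np.arange(1.0, 16.0)
        X = pd.DataFrame(
            {
                "a": t + 0.5 * rng.standard_normal(15),
                "b": rng.standard_normal(15),
                "c": 0.5 * t + rng.standard_normal(15),
                "d": rng.standard_normal(15),
            }
        )
        res = stepwise_fit(X, t)
        stable = stepwise_stable_subsets(X, t)
        assert frozenset(res.retained_terms) in stable

    def test_too_few_rows_raises(self, rng):
        X = pd.DataFrame(rng.standard_normal((4, 4)))
        with pytest.raises(ValueError):
            stepwise_fit(X, rng.standard_normal(4))
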