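"""Regression and hypothesis-testing machinery.

Muscle motor fatigue is operationalized as a negative ordinary-least-squares
slope of (normalized) MNF against time with a significant two-sided slope
test; wobble growth analogously for the acceleration measures.  First-vs-last
interval comparisons use paired two-tailed t-tests; slopes are compared
across muscles and activities with one-way ANOVA followed by unadjusted
pairwise t-tests; per-trial multivariate fits regress the summed MNF on the
four wobble measures; and a forward/backward stepwise regression (p-to-enter
0.05, p-to-remove 0.10) selects which wobble measures carry a time trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "TestResult",
    "MultivariateResult",
    "StepwiseResult",
    "interval_regression",
    "first_last_ttest",
    "slope_anova",
    "multivariate_r2",
    "stepwise_fit",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of one measure against time."""

    slope: float
    intercept: float
    p_slope: float
    r2: float
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: float
    kind: str  # paired_t | anova_F | kruskal_H


@dataclass(frozen=True)
class MultivariateResult:
    """Multi-predictor OLS summary (per-trial wobble-vs-fatigue regression)."""

    r2: float
    p_overall: float
    n: int
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class StepwiseResult:
    retained_terms: tuple[str, ...]
    term_pvalues: dict
    overall_p: float


def _finite_pairs(values, times) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.shape != t.shape:
        raise ValueError("values and times must have the same length")
    mask = np.isfinite(v) & np.isfinite(t)
    return v[mask], t[mask]


def interval_regression(values, times) -> RegressionResult:
    """OLS of value on time; two-sided slope p via the t distribution (n-2 df)."""
    v, t = _finite_pairs(values, times)
    if v.size < 3:
        raise ValueError(f"need >= 3 finite (time, value) pairs, got {v.size}")
    if np.ptp(t) == 0:
        raise ValueError("singular design: time vector is constant")
    if np.ptp(v) == 0:
        # flat response: slope 0 carries no evidence against the null
        return RegressionResult(slope=0.0, intercept=float(v[0]), p_slope=1.0, r2=0.0, n=v.size)
    res = sps.linregress(t, v)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_slope=float(res.pvalue),
        r2=float(res.rvalue**2),
        n=v.size,
    )


def first_last_ttest(first_values, last_values) -> TestResult:
    """Paired two-tailed t-test of last vs first interval across trials."""
    a, b = _finite_pairs(first_values, last_values)
    if a.size < 2:
        raise ValueError(f"need >= 2 pairs, got {a.size}")
    diff = b - a
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            # identical vectors: t = 0, no evidence of change
            return TestResult(statistic=0.0, p=1.0, df=a.size - 1, kind="paired_t")
        raise ValueError("degenerate paired test: differences have zero variance")
    t, p = sps.ttest_rel(b, a)
    return TestResult(statistic=float(t), p=float(p), df=a.size - 1, kind="paired_t")


def slope_anova(
    groups: Mapping[str, Sequence[float]], pairwise: bool = True, tukey: bool = False
) -> tuple[TestResult, pd.DataFrame | None]:
    """One-way ANOVA on regression slopes grouped by muscle or activity.

    Follow-up pairwise comparisons are unadjusted two-sample t-tests by
    default (bare pairwise p-values); pass ``tukey=True`` for Tukey HSD.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        empty = [n for n, a in zip(names, arrays) if a.size < 2]
        raise ValueError(f"groups too small (need n >= 2): {empty}")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate ANOVA: all values identical")
    f, p = sps.f_oneway(*arrays)
    k, n = len(arrays), pooled.size
    # guard against tiny negative F (and p = nan) from catastrophic cancellation
    # when group means are numerically identical
    if f < 0 and f > -1e-12:
        f = 0.0
    if not np.isfinite(p) and np.isfinite(f):
        p = float(sps.f.sf(f, k - 1, n - k))
    result = TestResult(statistic=float(f), p=float(p), df=float(k - 1), kind="anova_F")

    table = None
    if pairwise:
        rows = []
        if tukey:
            labels = np.concatenate([[g] * a.size for g, a in zip(names, arrays)])
            hsd = sm.stats.multicomp.pairwise_tukeyhsd(pooled, labels)
            summ = pd.DataFrame(
                hsd.summary().data[1:], columns=hsd.summary().data[0]
            )
            table = summ.rename(columns={"p-adj": "p"})[["group1", "group2", "p"]]
        else:
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    t, pv = sps.ttest_ind(arrays[i], arrays[j])
                    rows.append(
                        {"group1": names[i], "group2": names[j], "t": float(t), "p": float(pv)}
                    )
            table = pd.DataFrame(rows)
    return result, table


def multivariate_r2(acc_features: pd.DataFrame | np.ndarray, response) -> MultivariateResult:
    """OLS of the summed MNF on the four wobble measures (plus intercept)."""
    X = pd.DataFrame(acc_features)
    y = np.asarray(response, dtype=float)
    if len(X) != y.size:
        raise ValueError("predictor rows and response length differ")
    mask = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    X, y = X.loc[mask], y[mask]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more observations ({n}) than predictors + intercept ({p + 1})")
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design: predictors are rank-deficient")
    fit = sm.OLS(y, design).fit()
    params = dict(zip(["const", *map(str, X.columns)], map(float, fit.params)))
    return MultivariateResult(
        r2=float(fit.rsquared), p_overall=float(fit.f_pvalue), n=int(n), params=params
    )


def _ols_pvalues(X: pd.DataFrame, y: np.ndarray, terms: list[str]) -> tuple[pd.Series, float]:
    design = sm.add_constant(X[terms].to_numpy(dtype=float), has_constant="add")
    fit = sm.OLS(y, design).fit()
    pvals = pd.Series(fit.pvalues[1:], index=terms)
    return pvals, float(fit.f_pvalue)


def stepwise_fit(
    predictors: pd.DataFrame,
    response,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward selection with backward pruning on OLS term p-values.

    At each step the candidate with the smallest p-value below ``p_enter`` is
    added, then any retained term whose p-value exceeds ``p_remove`` is
    dropped (worst first).  Terminates when no move is possible.
    """
    X = pd.DataFrame(predictors).copy()
    X.columns = [str(c) for c in X.columns]
    y = np.asarray(response, dtype=float)
    mask = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    X, y = X.loc[mask].reset_index(drop=True), y[mask]
    if len(X) <= X.shape[1] + 1:
        raise ValueError(
            f"need more observations ({len(X)}) than predictors + intercept ({X.shape[1] + 1})"
        )

    selected: list[str] = []
    for _ in range(2 * X.shape[1] + 2):  # guard against enter/remove cycling
        changed = False
        candidates = [c for c in X.columns if c not in selected]
        if candidates:
            best, best_p = None, np.inf
            for c in candidates:
                try:
                    pvals, _ = _ols_pvalues(X, y, selected + [c])
                except np.linalg.LinAlgError:
                    continue
                if np.isfinite(pvals[c]) and pvals[c] < best_p:
                    best, best_p = c, float(pvals[c])
            if best is not None and best_p < p_enter:
                selected.append(best)
                changed = True
        while selected:
            pvals, _ = _ols_pvalues(X, y, selected)
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if selected:
        pvals, overall_p = _ols_pvalues(X, y, selected)
        term_pvalues = {t: float(pvals[t]) for t in selected}
    else:
        term_pvalues, overall_p = {}, float("nan")
    return StepwiseResult(
        retained_terms=tuple(selected), term_pvalues=term_pvalues, overall_p=overall_p
    )
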