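"""Cohort-level statistics: Welch's t, regression metrics, PCA.

These are the comparisons the surrounding modules report through — group
differences in delta-age, cell fractions and telomere deltas (Welch's
t-test), clock-validation metrics (R², MAE, regression p), and PCA for
dataset inspection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "WelchResult",
    "RegressionMetrics",
    "PcaResult",
    "welch_t",
    "regression_metrics",
    "pca",
    "bonferroni",
]


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    df: float
    p_value: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int


def welch_t(x, y) -> WelchResult:
    """Two-sided Welch's t-test (unequal variances, Satterthwaite df).

    The sign of t follows mean(x) - mean(y).  Requires n >= 2 per group;
    if both groups have zero variance and equal means, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            # degenerate: identical constants; no evidence of difference
            return WelchResult(0.0, float(len(x) + len(y) - 2), 1.0,
                               float(x.mean()), float(y.mean()), len(x), len(y))
        raise ValueError("welch_t undefined: zero variance in both groups with unequal means")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        n_x=len(x),
        n_y=len(y),
    )


@dataclass(frozen=True)
class RegressionMetrics:
    r_squared: float
    mae: float
    slope: float
    intercept: float
    regression_p: float
    n: int


def regression_metrics(predicted, chronological) -> RegressionMetrics:
    """OLS of predicted on chronological age, plus raw-pair MAE.

    R² and the regression p (F-test) come from the fitted line; the MAE is
    deliberately computed on the raw (predicted, chronological) pairs, not
    on fitted values — a clock with a constant offset keeps R² = 1 but pays
    for the offset in MAE.
    """
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if len(p) != len(c):
        raise ValueError("length mismatch")
    if len(p) < 3:
        raise ValueError("regression_metrics requires n >= 3")
    if np.var(c) == 0:
        raise ValueError("chronological age has zero variance")
    res = sm.OLS(p, sm.add_constant(c)).fit()
    return RegressionMetrics(
        r_squared=float(res.rsquared),
        mae=float(np.mean(np.abs(p - c))),
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        regression_p=float(res.f_pvalue),
        n=len(p),
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    variance_explained: np.ndarray  # fraction per component, non-increasing


def pca(betas: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """PCA of a beta matrix (CpG rows x sample columns) via SVD.

    Samples are observations; features (CpGs) are centered but not scaled —
    all share the percent unit.  ``variance_explained`` is the fraction of
    total variance per returned component.
    """
    X = betas.to_numpy(dtype=float).T  # samples x features
    n, m = X.shape
    if n < 2 or m < 1:
        raise ValueError("pca requires >= 2 samples and >= 1 feature")
    if n_components > min(n, m):
        raise ValueError(f"n_components={n_components} exceeds min(n_samples, n_features)")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    frac = (s**2) / total if total > 0 else np.zeros_like(s)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (U * s)[:, :n_components], index=betas.columns, columns=comps
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=betas.index, columns=comps)
    return PcaResult(scores=scores, loadings=loadings, variance_explained=frac[:n_components])


def bonferroni(p_values):
    """Bonferroni-adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * len(p), 1.0)
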