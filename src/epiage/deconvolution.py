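"""Reference-based leukocyte deconvolution by constrained projection.

Estimates the fractions of six leukocyte subsets (CD4 T, CD8 T, NK, B
cells, monocytes, granulocytes) in a blood methylation profile by
projecting it onto cell-type reference profiles at discriminating CpGs:

    minimise ||R f - b||^2   subject to  f >= 0,  sum(f) <= 1

This is the constrained-projection formulation behind the reference-based
blood deconvolution widely used on methylation arrays.  The sum constraint
is an inequality during optimisation (the unexplained remainder absorbs
profile noise); an optional post-hoc flag renormalises to sum(f) = 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from . import stats

__all__ = [
    "CELL_TYPES",
    "CellFractionEstimate",
    "estimate_cell_fractions",
    "deconvolve_matrix",
    "compare_composition",
]

CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")


@dataclass
class CellFractionEstimate:
    sample_id: str
    fractions: pd.Series  # indexed by cell type, >= 0, sum <= 1 (+eps)
    residual_norm: float


def _validate_reference(reference: pd.DataFrame):
    R = reference.to_numpy(dtype=float)
    if R.shape[0] < R.shape[1]:
        raise ValueError("reference needs at least as many CpG rows as cell types")
    if np.linalg.matrix_rank(R, tol=1e-8) < R.shape[1]:
        raise ValueError("reference matrix is rank deficient")


def _constrained_nnls(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Non-negative least squares with sum(f) <= 1.

    Plain NNLS first; if the sum constraint is violated it must be active
    at the optimum, so re-solve with sum(f) = 1 enforced through an
    augmented penalty row, escalating the penalty weight until the sum is
    within 1e-10.
    """
    f, _ = scipy.optimize.nnls(R, b)
    if f.sum() <= 1.0 + 1e-10:
        return f
    scale = max(np.abs(R).max(), 1.0)
    ones = np.ones((1, R.shape[1]))
    for lam in (1e4, 1e6, 1e8, 1e10):
        A = np.vstack([R, lam * scale * ones])
        y = np.concatenate([b, [lam * scale]])
        f, _ = scipy.optimize.nnls(A, y)
        if abs(f.sum() - 1.0) <= 1e-10:
            break
    return f


def estimate_cell_fractions(
    sample_betas: pd.Series,
    reference: pd.DataFrame,
    normalize: bool = False,
    sample_id: str = "",
) -> CellFractionEstimate:
    """Estimate cell-type fractions for one sample.

    ``sample_betas`` must provide a value for every CpG row of
    ``reference`` (both on the percent scale); extra CpGs are ignored.
    ``normalize=True`` rescales the solution to sum exactly 1.
    """
    _validate_reference(reference)
    missing = set(reference.index) - set(sample_betas.index)
    if missing:
        raise KeyError(f"sample is missing reference CpGs: {sorted(missing)}")
    b = sample_betas.reindex(reference.index).to_numpy(dtype=float)
    if np.isnan(b).any():
        bad = reference.index[np.isnan(b)]
        raise KeyError(f"sample has NaN at reference CpGs: {list(bad)}")
    R = reference.to_numpy(dtype=float)
    f = _constrained_nnls(R, b)
    resid = float(np.linalg.norm(R @ f - b))
    if normalize:
        s = f.sum()
        if s > 0:
            f = f / s
    return CellFractionEstimate(
        sample_id=str(sample_id or getattr(sample_betas, "name", "") or ""),
        fractions=pd.Series(f, index=reference.columns),
        residual_norm=resid,
    )


def deconvolve_matrix(
    betas: pd.DataFrame, reference: pd.DataFrame, normalize: bool = False
) -> pd.DataFrame:
    """Deconvolve every column of a beta matrix; returns samples x cell types."""
    est = [
        estimate_cell_fractions(betas[c], reference, normalize=normalize, sample_id=str(c))
        for c in betas.columns
    ]
    out = pd.DataFrame([e.fractions for e in est], index=[e.sample_id for e in est])
    out["residual_norm"] = [e.residual_norm for e in est]
    return out


def compare_composition(estimates: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-cell-type group comparison of estimated fractions.

    ``estimates`` is samples x cell types (the output of
    :func:`deconvolve_matrix`); ``groups`` maps sample id to group label.
    For exactly two groups with >= 2 samples each, a Welch t-test is run
    per cell type; otherwise the output is descriptive only (NaN test
    columns).
    """
    groups = groups.reindex(estimates.index)
    labels = [g for g in pd.unique(groups.dropna())]
    cell_cols = [c for c in estimates.columns if c != "residual_norm"]
    rows = []
    testable = (
        len(labels) == 2
        and all((groups == g).sum() >= 2 for g in labels)
    )
    for ct in cell_cols:
        row: dict = {"cell_type": ct}
        for g in labels:
            row[f"mean_{g}"] = float(estimates.loc[groups == g, ct].mean())
        if len(labels) == 2:
            g1, g2 = labels
            row["difference"] = row[f"mean_{g1}"] - row[f"mean_{g2}"]
            if testable:
                res = stats.welch_t(
                    estimates.loc[groups == g1, ct], estimates.loc[groups == g2, ct]
                )
                row["t_statistic"] = res.t_statistic
                row["p_value"] = res.p_value
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_type")
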