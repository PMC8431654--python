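"""Linear epigenetic clocks: representation, fitting, application, delta-age.

An epigenetic clock is a weighted linear combination of CpG methylation
levels (percent scale, 0-100) plus an intercept, optionally passed through
the piecewise log/linear age transform used by several published clocks.
The module ships the three-CpG bisulfite-amplicon blood clock
(CCDC102B, FHL2, PDE4C) and a generic engine for user-supplied coefficient
tables.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ClockDefinition",
    "ClockFit",
    "ba3_clock",
    "predict_age",
    "fit_clock",
    "delta_age",
    "age_transform",
    "age_transform_inverse",
]


class MissingCpGError(KeyError):
    """Raised when a clock's required CpGs are absent from a beta matrix."""

    def __init__(self, cpgs):
        self.cpgs = sorted(cpgs)
        super().__init__(f"beta matrix is missing required CpGs: {', '.join(self.cpgs)}")


class CollinearityError(ValueError):
    """Raised when the design matrix for a clock fit is rank deficient."""

    def __init__(self, cpgs):
        self.cpgs = list(cpgs)
        super().__init__(
            "design matrix is rank deficient; offending CpGs: " + ", ".join(self.cpgs)
        )


def age_transform(age, adult_age: float = 20.0):
    """Piecewise log/linear transform of chronological age.

    log((age+1)/(adult_age+1)) below ``adult_age``, linear (slope
    1/(adult_age+1)) above.  This is the transform several large published
    clocks train against; it is optional here and off by default.
    """
    age = np.asarray(age, dtype=float)
    return np.where(
        age < adult_age,
        np.log(age + 1.0) - np.log(adult_age + 1.0),
        (age - adult_age) / (adult_age + 1.0),
    )


def age_transform_inverse(raw, adult_age: float = 20.0):
    """Inverse of :func:`age_transform`."""
    raw = np.asarray(raw, dtype=float)
    return np.where(
        raw < 0,
        (adult_age + 1.0) * np.exp(raw) - 1.0,
        (adult_age + 1.0) * raw + adult_age,
    )


@dataclass(frozen=True)
class ClockDefinition:
    """A linear methylation clock.

    Parameters
    ----------
    name : str
        Identifier used in prediction output.
    terms : tuple of (cpg_id, weight)
        Weights in years per percentage point of methylation.
    intercept : float
        Intercept in years (on the transformed scale if ``transform`` is
        ``log_linear``).
    transform : {"identity", "log_linear"}
        Output transform; ``log_linear`` applies the piecewise
        log/linear inverse around ``adult_age``.
    adult_age : float
        Knot of the log_linear transform; ignored for identity.
    """

    name: str
    terms: tuple[tuple[str, float], ...]
    intercept: float
    transform: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self):
        ids = [c for c, _ in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cpg_id in clock terms")
        ws = np.array([w for _, w in self.terms], dtype=float)
        if ws.size and not np.all(np.isfinite(ws)):
            raise ValueError("clock weights must be finite")
        if not np.isfinite(self.intercept):
            raise ValueError("clock intercept must be finite")
        if self.transform not in ("identity", "log_linear"):
            raise ValueError(f"unknown transform: {self.transform!r}")
        object.__setattr__(self, "terms", tuple((str(c), float(w)) for c, w in self.terms))

    @property
    def required_cpgs(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.terms)

    def weights(self) -> pd.Series:
        return pd.Series({c: w for c, w in self.terms}, dtype=float)


def ba3_clock() -> ClockDefinition:
    """The published three-CpG bisulfite-amplicon blood-age clock.

    predicted age [years] = -0.34 * CCDC102B + 0.83 * FHL2 + 1.18 * PDE4C + 3.86

    with methylation on the percent scale and no output transform.  The
    signature combines one hypomethylating and two hypermethylating CpGs,
    which reduces sensitivity to global PCR amplification bias.
    """
    return ClockDefinition(
        name="BA3",
        terms=(("CCDC102B", -0.34), ("FHL2", 0.83), ("PDE4C", 1.18)),
        intercept=3.86,
        transform="identity",
    )


def _resolve_missing(betas: pd.DataFrame, clock: ClockDefinition, policy: str):
    """Return (betas restricted to clock CpGs, effective clock) per policy."""
    missing_rows = clock.required_cpgs - set(betas.index)
    sub = betas.reindex([c for c, _ in clock.terms])
    has_nan = sub.isna().to_numpy().any()
    if policy == "error":
        if missing_rows:
            raise MissingCpGError(missing_rows)
        if has_nan:
            bad = sub.index[sub.isna().any(axis=1)]
            raise MissingCpGError(bad)
        return sub, clock
    if policy == "drop_sample":
        if missing_rows:
            raise MissingCpGError(missing_rows)  # every sample would be dropped
        keep = ~sub.isna().any(axis=0)
        return sub.loc[:, keep], clock
    if policy == "mean_impute":
        eff = clock
        if missing_rows:
            warnings.warn(
                f"clock {clock.name}: CpGs {sorted(missing_rows)} absent from matrix; "
                "their terms are dropped (expect a moderate offset)",
                stacklevel=3,
            )
            eff = ClockDefinition(
                name=clock.name,
                terms=tuple(t for t in clock.terms if t[0] not in missing_rows),
                intercept=clock.intercept,
                transform=clock.transform,
                adult_age=clock.adult_age,
            )
            sub = betas.reindex([c for c, _ in eff.terms])
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
        if sub.isna().to_numpy().any():
            raise MissingCpGError(sub.index[sub.isna().any(axis=1)])
        return sub, eff
    raise ValueError(f"unknown missing_policy: {policy!r}")


def predict_age(
    betas: pd.DataFrame,
    clock: ClockDefinition,
    missing_policy: str = "error",
) -> pd.DataFrame:
    """Apply a clock to a beta matrix (CpG rows x sample columns, percent).

    Returns a DataFrame with columns ``sample_id``, ``clock``,
    ``predicted_age`` (years), one row per sample.

    ``missing_policy`` controls required CpGs absent/NaN in ``betas``:
    ``error`` (default) raises listing them, ``drop_sample`` drops samples
    with NaN values, ``mean_impute`` fills NaNs with the CpG's cross-sample
    mean (entirely absent CpGs are dropped from the clock with a warning).
    """
    sub, eff = _resolve_missing(betas, clock, missing_policy)
    w = np.array([t[1] for t in eff.terms], dtype=float)
    raw = w @ sub.to_numpy(dtype=float) + eff.intercept
    if eff.transform == "log_linear":
        pred = age_transform_inverse(raw, eff.adult_age)
    else:
        pred = raw
    return pd.DataFrame(
        {
            "sample_id": sub.columns.astype(str),
            "clock": eff.name,
            "predicted_age": np.atleast_1d(pred),
        }
    )


@dataclass
class ClockFit:
    """Result of an ordinary-least-squares clock fit."""

    clock: ClockDefinition
    r_squared: float
    mae: float
    stderr: pd.Series = field(repr=False)  # per-coefficient SEs incl. intercept


def _offending_columns(X: np.ndarray, names) -> list[str]:
    """Greedy scan for columns (CpGs) linearly dependent on earlier ones."""
    bad, basis = [], []
    for j, name in enumerate(names):
        cand = basis + [X[:, j]]
        if np.linalg.matrix_rank(np.column_stack(cand), tol=1e-8) < len(cand):
            bad.append(name)
        else:
            basis = cand
    return bad


def fit_clock(
    betas: pd.DataFrame,
    ages,
    cpg_ids=None,
    name: str = "fitted",
) -> ClockFit:
    """Fit a linear clock by unregularised OLS of age on selected betas.

    ``betas`` is CpG x sample (percent); ``ages`` aligns with the sample
    columns.  Requires more samples than CpGs + 1 and a full-rank design;
    a rank-deficient design raises :class:`CollinearityError` naming the
    offending CpGs.
    """
    if cpg_ids is None:
        cpg_ids = list(betas.index)
    missing = set(cpg_ids) - set(betas.index)
    if missing:
        raise MissingCpGError(missing)
    X = betas.loc[cpg_ids].to_numpy(dtype=float).T  # samples x CpGs
    y = np.asarray(ages, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("fit_clock requires complete data (no NaN)")
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} samples to fit {k} CpGs; got {n}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design, tol=1e-8) < design.shape[1]:
        raise CollinearityError(_offending_columns(X, cpg_ids) or list(cpg_ids))
    res = sm.OLS(y, design).fit()
    clock = ClockDefinition(
        name=name,
        terms=tuple(zip([str(c) for c in cpg_ids], res.params[1:])),
        intercept=float(res.params[0]),
    )
    mae = float(np.mean(np.abs(res.fittedvalues - y)))
    stderr = pd.Series(res.bse, index=["(Intercept)", *map(str, cpg_ids)])
    return ClockFit(clock=clock, r_squared=float(res.rsquared), mae=mae, stderr=stderr)


def delta_age(predictions: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Annotate predictions with chronological age and delta-age.

    ``sample_sheet`` needs columns ``sample_id`` and ``age`` (``group`` is
    carried through when present).  delta_age = predicted - chronological;
    positive values mean age acceleration.  Every predicted sample must
    appear in the sheet.
    """
    sheet = sample_sheet.set_index("sample_id")
    unmatched = set(predictions["sample_id"].astype(str)) - set(sheet.index.astype(str))
    if unmatched:
        raise KeyError(f"sample ids missing from sample sheet: {sorted(unmatched)}")
    out = predictions.copy()
    out["chronological_age"] = sheet["age"].reindex(out["sample_id"]).to_numpy(dtype=float)
    out["delta_age"] = out["predicted_age"] - out["chronological_age"]
    if "group" in sheet.columns:
        out["group"] = sheet["group"].reindex(out["sample_id"]).to_numpy()
    return out
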