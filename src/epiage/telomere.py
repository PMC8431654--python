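"""Age-adjusted telomere-length analysis.

Lymphocyte telomere length (Flow-FISH, kilobases) declines roughly
linearly with age in adulthood.  A reference cohort is summarised as
linear percentile curves (quantile regression of kb on age, one line per
requested percentile, non-crossing enforced over the fitted age range);
each patient measurement is then expressed as its difference from the
age-matched median curve, and banded by the percentile curves it falls
below — the clinically used flag being "below the 10th percentile".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.regression.quantile_regression import QuantReg

from . import stats

__all__ = [
    "TelomereMeasurement",
    "TelomereReference",
    "TelomereDelta",
    "fit_percentile_curves",
    "age_adjusted_delta",
    "compare_telomere_groups",
]


@dataclass(frozen=True)
class TelomereMeasurement:
    """One patient's telomere measurement (replicate kb values + age)."""

    sample_id: str
    replicate_values: tuple[float, ...]
    age: float
    group: str = ""

    def __post_init__(self):
        if not self.replicate_values:
            raise ValueError("at least one replicate value required")
        if any(v < 0 for v in self.replicate_values):
            raise ValueError("telomere lengths must be non-negative kb")

    @property
    def mean_kb(self) -> float:
        return float(np.mean(self.replicate_values))


@dataclass(frozen=True)
class TelomereReference:
    """Linear percentile curves fitted to a healthy reference cohort.

    ``curves`` maps percentile -> (intercept kb, slope kb/year); the fit is
    only trusted inside ``age_range`` (extrapolation beyond 5 years past
    either end attaches a warning to deltas).
    """

    curves: dict[int, tuple[float, float]]
    n_reference: int
    age_range: tuple[float, float]

    def evaluate(self, percentile: int, age: float) -> float:
        a, b = self.curves[percentile]
        return a + b * age

    @property
    def percentiles(self) -> tuple[int, ...]:
        return tuple(sorted(self.curves))


def fit_percentile_curves(
    ages,
    kb,
    percentiles=(1, 10, 50, 90, 99),
) -> TelomereReference:
    """Fit one linear quantile-regression curve per requested percentile.

    Requires >= 30 reference samples spanning >= 20 years.  Percentiles
    must lie strictly inside (0, 100).  If the data lie exactly on a line
    (zero residual OLS fit) every percentile curve is that line.
    Non-crossing across percentiles is enforced within the observed age
    range by rearranging curve values at the range endpoints (sorting
    across percentiles) and re-deriving each line through its two adjusted
    endpoint values.
    """
    ages = np.asarray(ages, dtype=float)
    kb = np.asarray(kb, dtype=float)
    percentiles = sorted(int(p) for p in percentiles)
    for p in percentiles:
        if not 0 < p < 100:
            raise ValueError(f"percentile must be strictly inside (0, 100); got {p}")
    n = len(ages)
    if n < 30:
        raise ValueError(f"need >= 30 reference samples; got {n}")
    lo, hi = float(ages.min()), float(ages.max())
    if hi - lo < 20:
        raise ValueError(f"reference ages must span >= 20 years; span {hi - lo:.1f}")

    X = sm.add_constant(ages)
    ols = sm.OLS(kb, X).fit()
    curves: dict[int, tuple[float, float]] = {}
    if float(np.max(np.abs(ols.resid))) < 1e-10:
        # degenerate: all mass on one line; every quantile is that line
        for p in percentiles:
            curves[p] = (float(ols.params[0]), float(ols.params[1]))
    else:
        model = QuantReg(kb, X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # IRLS convergence chatter on clean data
            for p in percentiles:
                res = model.fit(q=p / 100.0)
                curves[p] = (float(res.params[0]), float(res.params[1]))

    # enforce non-crossing over [lo, hi]: two lines are ordered on the whole
    # interval iff ordered at both endpoints
    vals_lo = np.array([curves[p][0] + curves[p][1] * lo for p in percentiles])
    vals_hi = np.array([curves[p][0] + curves[p][1] * hi for p in percentiles])
    vals_lo.sort()
    vals_hi.sort()
    for p, vlo, vhi in zip(percentiles, vals_lo, vals_hi):
        slope = (vhi - vlo) / (hi - lo)
        curves[p] = (vlo - slope * lo, slope)

    return TelomereReference(curves=curves, n_reference=n, age_range=(lo, hi))


@dataclass
class TelomereDelta:
    sample_id: str
    age: float
    group: str
    mean_kb: float
    delta_kb: float  # mean_kb minus the age-matched median curve
    band: str        # e.g. "<10th", ">=50th"
    below_10th: bool
    extrapolated: bool = False


def _band(value: float, reference: TelomereReference, age: float) -> str:
    """Percentile band of a measurement at a given age.

    Below the median, report the lowest percentile curve the value falls
    below ("<10th" echoes the clinical below-10th-percentile criterion);
    at or above the median, report the highest curve the value reaches
    (">=50th", ">=90th", ...).
    """
    ps = reference.percentiles
    if 50 not in ps:
        raise ValueError("reference must include the 50th percentile curve")
    median = reference.evaluate(50, age)
    if value < median:
        for p in [p for p in ps if p <= 50]:
            if value < reference.evaluate(p, age):
                return f"<{p}th"
        return "<50th"
    best = max(p for p in ps if p <= 50 or value >= reference.evaluate(p, age))
    return f">={best}th"


def age_adjusted_delta(
    measurement: TelomereMeasurement, reference: TelomereReference
) -> TelomereDelta:
    """Express a measurement relative to the age-matched reference curves.

    delta_kb = mean of replicates minus the 50th-percentile curve at the
    patient's age.  Ages more than 5 years outside the fitted range are
    evaluated anyway but flagged as extrapolated.
    """
    lo, hi = reference.age_range
    extrapolated = not (lo - 5 <= measurement.age <= hi + 5)
    if extrapolated:
        warnings.warn(
            f"{measurement.sample_id}: age {measurement.age:.1f} is far outside the "
            f"reference range [{lo:.1f}, {hi:.1f}]; delta is an extrapolation",
            stacklevel=2,
        )
    value = measurement.mean_kb
    delta = value - reference.evaluate(50, measurement.age)
    below10 = 10 in reference.curves and value < reference.evaluate(10, measurement.age)
    return TelomereDelta(
        sample_id=measurement.sample_id,
        age=measurement.age,
        group=measurement.group,
        mean_kb=value,
        delta_kb=float(delta),
        band=_band(value, reference, measurement.age),
        below_10th=bool(below10),
        extrapolated=extrapolated,
    )


def compare_telomere_groups(deltas, group_a: str, group_b: str) -> dict:
    """Compare age-adjusted telomere deltas between two groups.

    Welch's t on delta_kb, plus a Fisher exact test on the 2x2 table of
    below-10th-percentile counts.  Groups with fewer than 2 members get a
    descriptive summary only.
    """
    da = [d for d in deltas if d.group == group_a]
    db = [d for d in deltas if d.group == group_b]
    out: dict = {
        "groups": (group_a, group_b),
        "n": (len(da), len(db)),
        "mean_delta_kb": (
            float(np.mean([d.delta_kb for d in da])) if da else None,
            float(np.mean([d.delta_kb for d in db])) if db else None,
        ),
    }
    below = (sum(d.below_10th for d in da), sum(d.below_10th for d in db))
    out["below_10th_counts"] = below
    if len(da) >= 2 and len(db) >= 2:
        res = stats.welch_t([d.delta_kb for d in da], [d.delta_kb for d in db])
        out["welch"] = res
        table = [[below[0], len(da) - below[0]], [below[1], len(db) - below[1]]]
        out["fisher_p"] = float(scipy.stats.fisher_exact(table).pvalue)
    return out
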