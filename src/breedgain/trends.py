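"""Genetic-trend estimation by linear regression.

The rate of genetic gain in a breeding population is estimated by ordinary
least squares of candidate PBV or OP values over cycle number; dividing the
per-cycle slope by the cycle length in years gives the annual gain, also
expressed as a percentage of the population mean.  The same machinery
regresses historical-cultivar values over year of release, and site
predicted means over cycles as an environmental-trend check.

Individual-record OLS is exactly equivalent to a regression of group means
weighted by group counts, so published per-cycle means and counts suffice
to reconstruct the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "regress_records",
    "regress_group_means",
    "regress_over_cycles",
    "regress_historical",
    "environmental_trend",
]


@dataclass
class TrendResult:
    slope: float  # units per group step (cycle or year)
    slope_se: float
    intercept: float
    intercept_se: float
    annual_gain: float  # units per year
    percent_annual_gain: float | None  # % of population mean per year
    n: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _finish(
    slope, slope_se, intercept, intercept_se, p, n, years_per_group, population_mean
) -> TrendResult:
    annual = slope / years_per_group
    pct = 100.0 * annual / population_mean if population_mean else None
    return TrendResult(
        slope=float(slope),
        slope_se=float(slope_se),
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        annual_gain=float(annual),
        percent_annual_gain=pct,
        n=int(n),
        p_value=float(p),
    )


def regress_records(
    x: np.ndarray,
    y: np.ndarray,
    years_per_group: float = 1.0,
    population_mean: float | None = None,
) -> TrendResult:
    """OLS of individual records y on group value x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct group values")
    res = stats.linregress(x, y)
    return _finish(
        res.slope,
        res.stderr,
        res.intercept,
        res.intercept_stderr,
        res.pvalue,
        x.size,
        years_per_group,
        population_mean,
    )


def regress_group_means(
    groups: np.ndarray,
    means: np.ndarray,
    counts: np.ndarray,
    years_per_group: float = 1.0,
    population_mean: float | None = None,
) -> TrendResult:
    """Count-weighted OLS of group means; slope identical to record-level OLS.

    The standard error reported is the record-level one under the
    assumption that within-group variation is what the weights absorbed,
    i.e. computed from the weighted residual sum of squares with
    sum(counts) - 2 degrees of freedom.  (Whether to report mean-level or
    record-level SEs is a presentation choice; the slope is the same.)
    """
    x = np.asarray(groups, float)
    m = np.asarray(means, float)
    w = np.asarray(counts, float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct group values")
    n = w.sum()
    xbar = np.sum(w * x) / n
    ybar = np.sum(w * m) / n
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (m - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    # weighted residual SS of the group means around the line
    resid = m - (intercept + slope * x)
    dof = max(n - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    slope_se = np.sqrt(s2 / sxx)
    intercept_se = np.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    t = slope / slope_se if slope_se > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(t), dof)
    return _finish(
        slope, slope_se, intercept, intercept_se, p, n, years_per_group, population_mean
    )


def regress_over_cycles(
    records: pd.DataFrame,
    years_per_cycle: float = 2.0,
    population_mean: float | None = None,
    value_col: str = "value",
    cycle_col: str = "cycle",
) -> TrendResult:
    """Genetic trend of candidate PBV/OP over selection cycles.

    ``records`` holds one row per candidate genotype with its cycle number
    and metric value.  Slope is in units per cycle; the annual gain divides
    by ``years_per_cycle``.
    """
    return regress_records(
        records[cycle_col].to_numpy(),
        records[value_col].to_numpy(),
        years_per_group=years_per_cycle,
        population_mean=population_mean,
    )


def regress_historical(
    values: np.ndarray,
    release_years: np.ndarray,
    population_mean: float | None = None,
) -> TrendResult:
    """Genetic trend of historical cultivars over their year of release."""
    values = np.asarray(values, float)
    years = np.asarray(release_years, float)
    if np.unique(years).size < 2:
        raise ValueError("cultivars must span at least two release years")
    return regress_records(years, values, 1.0, population_mean)


def environmental_trend(
    site_means: pd.DataFrame,
    cycle_col: str = "cycle",
    value_col: str = "site_mean",
) -> TrendResult:
    """Regression of predicted site means over cycles.

    A non-significant slope supports interpreting the candidate trend as
    genetic rather than environmental.
    """
    return regress_records(
        site_means[cycle_col].to_numpy(), site_means[value_col].to_numpy()
    )


def percent_of_mean(value: float, population_mean: float) -> float:
    """Express a response or gain as a percentage of the population mean."""
    if population_mean == 0:
        raise ValueError("population mean must be nonzero")
    return 100.0 * value / population_mean


def exclude_poorly_connected_cycles(
    connectivity: pd.DataFrame, threshold: int = 10
) -> list:
    """Cycles sharing fewer than ``threshold`` genotypes with every other
    cycle (by the cross-cycle genotype-overlap matrix) are flagged for
    exclusion from trend estimation."""
    keep = []
    for c in connectivity.index:
        others = connectivity.loc[c].drop(labels=[c])
        if len(others) and others.max() >= threshold:
            keep.append(c)
    return [c for c in connectivity.index if c not in keep]
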