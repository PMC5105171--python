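"""Diagnostics of the atmospheric CO2 growth rate.

Implements the linear sink model of the growth rate,

    G(t) = F_anthro(t) + c0 - B * M(t) + eps_t,

where M is atmospheric CO2 mass (PgC), B (yr-1) is an inverse residence time
for excess carbon against land and ocean uptake, and the composite intercept
c0 = B*M0 - F0 absorbs the (non-identifiable) background mass M0 and offset
flux F0.  Deviations of observed growth from this model indicate changes in
global sink strength; a one-sample t-test on post-candidate-year residuals
screens for a structural change.  The module also provides the annual
airborne fraction, non-parametric Mann-Kendall/Sen trend testing and monthly
deseasonalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .forcing import PPM_TO_PGC

__all__ = [
    "SinkModelFit",
    "BreakTestResult",
    "TrendResult",
    "fit_sink_model",
    "residual_break_test",
    "airborne_fraction",
    "mann_kendall_sen",
    "deseasonalize",
]


@dataclass
class SinkModelFit:
    """Estimated linear sink model.

    ``residuals`` (observed - predicted growth, PgC yr-1) cover the whole
    series, not only the fit window; predictions use only F_anthro and M.
    ``f0`` is reported when a background mass ``m0`` is supplied
    (F0 = B*M0 - c0), otherwise NaN.
    """

    b: float  # yr-1
    intercept: float  # composite c0 = B*M0 - F0, PgC yr-1
    b_se: float
    intercept_se: float
    window: tuple[int, int]
    residuals: pd.Series = field(repr=False)
    predicted: pd.Series = field(repr=False)
    m0: float | None = None
    f0: float = float("nan")
    emissions_coef: float = 1.0  # fixed at 1 unless the free-coefficient fit is used


@dataclass(frozen=True)
class BreakTestResult:
    t: float
    df: int
    p: float
    mean_residual: float  # PgC yr-1
    sign: int
    candidate_year: int
    n_post: int


@dataclass(frozen=True)
class TrendResult:
    s: float  # Kendall score
    tau: float  # tau-b
    p: float  # two-sided, normal approximation with continuity correction
    slope: float  # Sen slope, series units per year
    window: tuple[int, int]
    n: int


def fit_sink_model(
    series: pd.DataFrame,
    window: tuple[int, int] | None = None,
    m0: float | None = None,
    free_emissions: bool = False,
) -> SinkModelFit:
    """Ordinary least squares of G (PgC yr-1) on M with an emissions offset.

    The default design treats emissions with a fixed unit coefficient,
    regressing ``G - F_anthro`` on ``[1, M]``; ``free_emissions=True``
    estimates the emissions coefficient as well.  ``window`` is the inclusive
    year range used for fitting (default: whole series; the published
    diagnostic fits the first 30 years); residuals are returned for every
    year of the series.
    """
    yr = series["year"].to_numpy()
    if window is None:
        window = (int(yr[0]), int(yr[-1]))
    mask = (yr >= window[0]) & (yr <= window[1])
    if mask.sum() < 10:
        raise ValueError("fit window must contain at least 10 years")
    m = series["M"].to_numpy(dtype=float)
    g = series["G"].to_numpy(dtype=float)
    f = series["F_anthro"].to_numpy(dtype=float)
    if np.ptp(m[mask]) == 0:
        raise ValueError("M is constant within the fit window: singular design")

    if free_emissions:
        x = sm.add_constant(np.column_stack([f[mask], m[mask]]))
        res = sm.OLS(g[mask], x).fit()
        c0, fcoef, slope = res.params
        c0_se, _, slope_se = res.bse
        predicted = c0 + fcoef * f + slope * m
    else:
        x = sm.add_constant(m[mask])
        res = sm.OLS(g[mask] - f[mask], x).fit()
        c0, slope = res.params
        c0_se, slope_se = res.bse
        fcoef = 1.0
        predicted = c0 + f + slope * m
    b = -slope
    fit = SinkModelFit(
        b=b,
        intercept=c0,
        b_se=slope_se,
        intercept_se=c0_se,
        window=window,
        residuals=pd.Series(g - predicted, index=yr, name="residual"),
        predicted=pd.Series(predicted, index=yr, name="predicted"),
        m0=m0,
        f0=(b * m0 - c0) if m0 is not None else float("nan"),
        emissions_coef=fcoef,
    )
    return fit


def residual_break_test(fit: SinkModelFit, candidate_year: int) -> BreakTestResult:
    """Two-sided one-sample t-test of residuals from ``candidate_year`` onward.

    A significant non-zero mean indicates a structural change in the
    concentration-sink coupling; a negative mean marks a strengthening sink
    (growth slower than the fitted model predicts).
    """
    post = fit.residuals[fit.residuals.index >= candidate_year]
    if post.size < 5:
        raise ValueError("need at least 5 residuals after the candidate year")
    if np.allclose(post, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_1samp(post.to_numpy(), 0.0)
    mean = float(post.mean())
    return BreakTestResult(
        t=float(t_stat), df=post.size - 1, p=float(p), mean_residual=mean,
        sign=int(np.sign(mean)), candidate_year=candidate_year, n_post=post.size,
    )


def airborne_fraction(series: pd.DataFrame) -> pd.Series:
    """Annual airborne fraction AF(t) = G(t) [PgC yr-1] / F_anthro(t)."""
    f = series["F_anthro"].to_numpy(dtype=float)
    if np.any(f <= 0):
        raise ValueError("airborne fraction undefined for non-positive emissions")
    af = pd.Series(series["G"].to_numpy(dtype=float) / f,
                   index=series["year"].to_numpy(), name="airborne_fraction")
    af.index.name = "year"
    return af


def mann_kendall_sen(values, times=None, window: tuple | None = None) -> TrendResult:
    """Mann-Kendall trend test (tau-b, tie-corrected) with Sen's slope.

    ``S = sum_{i<j} sign(x_j - x_i)``; its variance uses the standard tie
    correction and the p-value a continuity-corrected normal approximation.
    The Sen slope is the median of all pairwise slopes.  A constant series is
    reported as (S = 0, slope = 0, p = 1), not an error.
    """
    x = np.asarray(values, dtype=float)
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        x, t = x[mask], t[mask]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points for a trend test")

    diff_x = np.subtract.outer(x, x)[np.triu_indices(n, k=1)]
    diff_t = np.subtract.outer(t, t)[np.triu_indices(n, k=1)]
    # triu pairs are (i, j) with i < j, so sign convention needs x_j - x_i
    s = float(np.sum(np.sign(-diff_x)))

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return counts[counts > 1]

    tx = tie_term(x)
    tt = tie_term(t)
    var_s = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(tx * (tx - 1) * (2 * tx + 5))
        - np.sum(tt * (tt - 1) * (2 * tt + 5))
    ) / 18.0

    d0 = n * (n - 1) / 2.0
    d1 = np.sum(tx * (tx - 1) / 2.0)
    d2 = np.sum(tt * (tt - 1) / 2.0)
    denom = np.sqrt((d0 - d1) * (d0 - d2))
    tau = s / denom if denom > 0 else 0.0

    if var_s <= 0 or s == 0:
        p = 1.0
        z = 0.0
    else:
        z = (s - np.sign(s)) / np.sqrt(var_s)
        p = 2.0 * stats.norm.sf(abs(z))

    valid = diff_t != 0
    slopes = -diff_x[valid] / -diff_t[valid]
    slope = float(np.median(slopes)) if slopes.size else 0.0
    return TrendResult(
        s=s, tau=float(tau), p=float(min(p, 1.0)), slope=slope,
        window=(float(t.min()), float(t.max())), n=n,
    )


def deseasonalize(monthly: pd.Series) -> pd.Series:
    """Subtract the calendar-month climatology from a monthly series.

    ``monthly`` must carry a DatetimeIndex (or PeriodIndex) spanning at least
    two full years; incomplete years contribute to the climatology with the
    months they have.  Per-calendar-month anomaly means are zero.
    """
    idx = pd.DatetimeIndex(monthly.index) if not isinstance(monthly.index, pd.PeriodIndex) else monthly.index.to_timestamp()
    if monthly.size < 24:
        raise ValueError("need at least 2 full years of monthly data")
    clim = monthly.groupby(idx.month).transform("mean")
    out = monthly - clim
    out.name = monthly.name
    return out
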