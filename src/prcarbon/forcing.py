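"""Synthetic gridded forcing and annual carbon-budget series with known truth.

Every downstream stage of the package (LUE photosynthesis, respiration,
attribution experiments, growth-rate diagnostics, SSA) is exercised on
synthetic inputs generated here, so all prescribed trends, sink parameters and
noise levels are known exactly and recoverable.

The gridded forcing emulates a century of monthly global driver fields
(air temperature, VPD, incident PAR-basis light, fAPAR, moisture index alpha,
well-mixed CO2, a PFT map): each driver is a latitude-dependent climatology
plus a hemisphere-aware seasonal cycle, a linear trend and AR(1) noise.  The
annual budget series integrates the linear sink model of the growth rate
forward in time:

    G(t) = F_anthro(t) - F0 - B * (M(t) - M0) + eps_t,
    M(t+1) = M(t) + G(t),

with B an inverse residence time for excess atmospheric carbon (yr^-1), M the
atmospheric CO2 mass (PgC) and G the annual growth (PgC yr^-1).  A step change
in B at a break year emulates a strengthening sink.

Containers are the field's standard ones: an :class:`xarray.Dataset` for the
gridded forcing (schema below) and a :class:`pandas.DataFrame` for the budget
series.  Grid conventions: latitude ascending cell centres, longitude
-180..180, monthly time stamps at month starts.

Forcing dataset schema
----------------------
``tair`` (time, lat, lon) deg C; ``vpd`` (Pa, >= 0); ``i0`` (mol photon m-2
month-1, light before fAPAR scaling); ``fapar`` and ``alpha`` (dimensionless,
0-1); ``ca`` (time,) ppm, spatially uniform; ``pft`` (lat, lon) integer
category; ``cell_area`` (lat,) m2 per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "PPM_TO_PGC",
    "SyntheticTruth",
    "default_trend_spec",
    "make_forcing",
    "make_pft_map",
    "default_emissions",
    "make_budget_series",
    "validate_forcing",
    "validate_budget",
    "cell_areas",
]

#: Atmospheric conversion: 1 ppm CO2 = 2.124 PgC (standard factor).
PPM_TO_PGC = 2.124

EARTH_RADIUS = 6.371e6  # m

FORCING_VARS = ("tair", "vpd", "i0", "fapar", "alpha", "ca", "pft", "cell_area")

_UNITS = {
    "tair": "degC",
    "vpd": "Pa",
    "i0": "mol photon m-2 month-1",
    "fapar": "1",
    "alpha": "1",
    "ca": "ppm",
    "pft": "1",
    "cell_area": "m2",
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Parameters that fully determine a synthetic dataset (with its seed)."""

    trend_slopes: Mapping[str, float] = dc_field(default_factory=dict)
    b_true: float = float("nan")  # yr-1
    f0_true: float = float("nan")  # PgC yr-1
    m0: float = float("nan")  # PgC
    break_year: int | None = None
    b_post: float | None = None
    noise_sd: float = 0.0
    seed: int = 0


def default_trend_spec() -> dict[str, float]:
    """Per-driver linear slopes (units yr-1) emulating the 20th-century study period.

    CO2 rises ~110 ppm over 113 yr (roughly 290 ppm at 1900 to 400 ppm at
    2013); air temperature warms ~0.9 C per century; a modest greening trend
    in fAPAR and a small VPD increase accompany the warming.
    """
    return {
        "tair": 0.009,
        "vpd": 0.5,
        "i0": 0.0,
        "fapar": 0.0004,
        "alpha": 0.0,
        "ca": 110.0 / 113.0,
    }


def cell_areas(lat: np.ndarray, nlat: int | None = None) -> np.ndarray:
    """Area (m2) of each latitude row of a regular lat/lon grid.

    ``lat`` are ascending cell-centre latitudes in degrees; cells are assumed
    equal-width in both coordinates.
    """
    lat = np.asarray(lat, dtype=float)
    dlat = np.diff(lat).mean() if lat.size > 1 else 180.0
    lo = np.radians(lat - dlat / 2.0)
    hi = np.radians(lat + dlat / 2.0)
    # one cell's width in longitude is dlat degrees for the default grids here;
    # the caller divides the full band by nlon, so compute per-cell directly
    return EARTH_RADIUS**2 * np.radians(dlat) * (np.sin(hi) - np.sin(lo))


def _ar1_noise(rng: np.random.Generator, shape, sd: float, rho: float) -> np.ndarray:
    """AR(1) noise along the first axis, stationary variance ``sd**2``."""
    if sd == 0.0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, size=shape)
    out = np.empty(shape)
    out[0] = rng.normal(0.0, sd, size=shape[1:])
    for t in range(1, shape[0]):
        out[t] = rho * out[t - 1] + eps[t]
    return out


def make_pft_map(grid_shape: tuple[int, int], n_pfts: int, seed: int = 0) -> xr.DataArray:
    """Contiguous latitudinal bands of plant functional types.

    The latitude rows are split into ``n_pfts`` contiguous bands; the band
    labels are a seed-determined permutation of 0..n_pfts-1.
    """
    nlat, nlon = grid_shape
    if n_pfts < 1:
        raise ValueError("n_pfts must be >= 1")
    if n_pfts > nlat:
        raise ValueError("n_pfts cannot exceed the number of latitude rows")
    rng = np.random.default_rng(seed)
    labels = rng.permutation(n_pfts)
    rows = np.concatenate(
        [np.full(len(chunk), labels[i]) for i, chunk in enumerate(np.array_split(np.arange(nlat), n_pfts))]
    )
    pft = np.repeat(rows[:, None], nlon, axis=1).astype(np.int32)
    lat = _lat_centers(nlat)
    lon = _lon_centers(nlon)
    return xr.DataArray(
        pft, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"), name="pft",
        attrs={"units": "1", "long_name": "plant functional type"},
    )


def _lat_centers(nlat: int) -> np.ndarray:
    d = 180.0 / nlat
    return np.linspace(-90.0 + d / 2.0, 90.0 - d / 2.0, nlat)


def _lon_centers(nlon: int) -> np.ndarray:
    d = 360.0 / nlon
    return np.linspace(-180.0 + d / 2.0, 180.0 - d / 2.0, nlon)


_DEFAULT_NOISE_SD = {
    "tair": 0.8, "vpd": 40.0, "i0": 25.0, "fapar": 0.015, "alpha": 0.02, "ca": 0.25,
}


def make_forcing(
    grid_shape: tuple[int, int] = (18, 36),
    years: tuple[int, int] = (1900, 2013),
    trend_spec: Mapping[str, float] | None = None,
    seasonal_spec: Mapping[str, float] | None = None,
    noise_spec: Mapping | None = None,
    seed: int = 0,
    ca0: float = 290.0,
    n_pfts: int = 4,
) -> xr.Dataset:
    """Generate a synthetic monthly gridded forcing dataset.

    Each driver is built as latitude climatology + seasonal cycle + linear
    trend + AR(1) noise and then clipped to its physical bounds.  ``years``
    are inclusive; ``trend_spec`` maps driver names to linear slopes per year
    (missing drivers default to zero trend), ``seasonal_spec`` scales the
    built-in seasonal amplitudes (1.0 default), ``noise_spec`` is
    ``{"sd": {driver: sd}, "ar1": rho}`` (pass ``{"sd": 0}`` for noise-free
    fields).  Deterministic for a given seed.

    Raises ``ValueError`` if the fAPAR or alpha trend would push more than 5%
    of cell-months outside [0, 1] before clipping.
    """
    nlat, nlon = grid_shape
    y0, y1 = years
    nyears = y1 - y0 + 1
    if nyears < 2:
        raise ValueError("years must span at least 2 years")
    ntime = nyears * 12
    if trend_spec is None:
        trends = default_trend_spec()
    else:
        trends = {**{k: 0.0 for k in _DEFAULT_NOISE_SD}, **dict(trend_spec)}
    seas = {k: 1.0 for k in _DEFAULT_NOISE_SD}
    if seasonal_spec is not None:
        seas.update(seasonal_spec)
    noise_spec = dict(noise_spec or {})
    rho = float(noise_spec.get("ar1", 0.3))
    sd_spec = noise_spec.get("sd", _DEFAULT_NOISE_SD)
    if np.isscalar(sd_spec):
        sds = {k: float(sd_spec) * v for k, v in _DEFAULT_NOISE_SD.items()} if sd_spec else {k: 0.0 for k in _DEFAULT_NOISE_SD}
    else:
        sds = {**_DEFAULT_NOISE_SD, **dict(sd_spec)}

    rng = np.random.default_rng(seed)
    lat = _lat_centers(nlat)
    lon = _lon_centers(nlon)
    time = pd.date_range(f"{y0}-01-01", periods=ntime, freq="MS")
    phi = np.radians(lat)[None, :, None]  # broadcast over (time, lat, lon)
    month = (np.arange(ntime) % 12 + 1)[:, None, None]  # 1..12
    tfrac = ((np.arange(ntime) + 0.5) / 12.0)[:, None, None]  # years since start

    # hemisphere-aware seasonal phase: +1 in July for the northern hemisphere
    phase = np.cos(2.0 * np.pi * (month - 7) / 12.0) * np.sign(phi + 1e-12)

    def build(clim, amp, key, lo=None, hi=None, strict_bounds=False):
        f = (
            clim
            + seas[key] * amp * phase
            + trends.get(key, 0.0) * tfrac
            + _ar1_noise(rng, (ntime, nlat, nlon), sds.get(key, 0.0), rho)
        )
        if strict_bounds:
            out = ((f < lo) | (f > hi)).mean()
            if out > 0.05:
                raise ValueError(
                    f"trend_spec drives {key} outside [{lo}, {hi}] for "
                    f"{out:.1%} of cell-months (>5%); reduce the {key} slope"
                )
        if lo is not None or hi is not None:
            f = np.clip(f, lo, hi)
        return f

    tair = build(-25.0 + 48.0 * np.cos(phi), 3.0 + 17.0 * np.abs(np.sin(phi)), "tair")
    vpd = build(200.0 + 900.0 * np.cos(phi) ** 2, 150.0 * np.cos(phi) ** 2, "vpd", lo=0.0)
    i0 = build(300.0 + 900.0 * np.cos(phi), 250.0 * np.abs(np.sin(phi)), "i0", lo=0.0)
    fapar = build(0.15 + 0.55 * np.cos(phi) ** 2, 0.08 * np.abs(np.sin(phi)), "fapar",
                  lo=0.0, hi=1.0, strict_bounds=True)
    alpha = build(0.35 + 0.40 * np.cos(phi) ** 2, 0.05 * np.abs(np.sin(phi)), "alpha",
                  lo=0.0, hi=1.0, strict_bounds=True)

    ca = (
        ca0
        + trends.get("ca", 0.0) * tfrac[:, 0, 0]
        + seas["ca"] * 2.0 * np.cos(2.0 * np.pi * (month[:, 0, 0] - 8) / 12.0)
        + _ar1_noise(rng, (ntime, 1), sds.get("ca", 0.0), rho)[:, 0]
    )
    if np.any(ca <= 0):
        raise ValueError("ca trend drives concentrations non-positive")

    area_row = cell_areas(lat) / nlon

    ds = xr.Dataset(
        {
            "tair": (("time", "lat", "lon"), tair),
            "vpd": (("time", "lat", "lon"), vpd),
            "i0": (("time", "lat", "lon"), i0),
            "fapar": (("time", "lat", "lon"), fapar),
            "alpha": (("time", "lat", "lon"), alpha),
            "ca": (("time",), ca),
            "pft": make_pft_map(grid_shape, n_pfts, seed=seed),
            "cell_area": (("lat",), area_row),
        },
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"title": "prcarbon synthetic monthly forcing", "seed": seed},
    )
    for name, unit in _UNITS.items():
        ds[name].attrs.setdefault("units", unit)
    validate_forcing(ds)
    return ds


def validate_forcing(ds: xr.Dataset) -> None:
    """Check the forcing schema and physical invariants; raise on violation."""
    for name in FORCING_VARS:
        if name not in ds:
            raise ValueError(f"forcing dataset is missing variable '{name}'")
    if np.any((ds["fapar"].values < 0) | (ds["fapar"].values > 1)):
        raise ValueError("fapar outside [0, 1]")
    if np.any((ds["alpha"].values < 0) | (ds["alpha"].values > 1)):
        raise ValueError("alpha outside [0, 1]")
    if np.any(ds["vpd"].values < 0):
        raise ValueError("vpd must be non-negative")
    if np.any(ds["ca"].values <= 0):
        raise ValueError("ca must be positive")
    t = pd.DatetimeIndex(ds["time"].values)
    expected = pd.date_range(t[0], periods=t.size, freq="MS")
    if not t.equals(expected):
        raise ValueError("time index must be strictly increasing, monthly and gapless")


def default_emissions(years: np.ndarray) -> np.ndarray:
    """Idealised anthropogenic emissions path (PgC yr-1).

    Exponential fossil growth plus a roughly constant land-use component,
    yielding ~4 PgC yr-1 around 1960 and ~11 PgC yr-1 by the early 2010s.
    """
    years = np.asarray(years, dtype=float)
    return np.exp(0.0205 * (years - 1900.0)) + 0.8


def make_budget_series(
    years: tuple[int, int] = (1959, 2014),
    b_true: float = 0.02,
    f0: float = 0.0,
    m0: float = 280.0 * PPM_TO_PGC,
    emissions_path: np.ndarray | Callable | None = None,
    noise_sd: float = 0.0,
    break_spec: Mapping | None = None,
    seed: int = 0,
    m_init: float | None = None,
    convention: str = "forward",
) -> pd.DataFrame:
    """Integrate the linear sink model forward into an annual budget series.

    ``G(t) = F_anthro(t) - f0 - B*(M(t) - m0) + eps`` with
    ``M(t+1) = M(t) + G(t)`` (explicit annual Euler).  ``break_spec``
    ``{"year": y, "b": value}`` switches B from the break year onward.  The
    returned frame has columns ``year, F_anthro, ca, M, G`` (G in PgC yr-1)
    plus ``G_ppm``; the generating truth is stored in ``df.attrs["truth"]``.

    ``convention`` controls the stored G: ``"forward"`` (default) keeps the
    exact annual increment ``M(t+1)-M(t)``; ``"centered"`` replaces it by the
    centred difference ``(M(t+1)-M(t-1))/2`` (one-sided at the ends).
    """
    if b_true <= 0:
        raise ValueError("b_true must be positive")
    y0, y1 = years
    yr = np.arange(y0, y1 + 1)
    n = yr.size
    if callable(emissions_path):
        f_anthro = np.asarray(emissions_path(yr), dtype=float)
    elif emissions_path is None:
        f_anthro = default_emissions(yr)
    elif np.isscalar(emissions_path):
        f_anthro = np.full(n, float(emissions_path))
    else:
        f_anthro = np.asarray(emissions_path, dtype=float)
        if f_anthro.size != n:
            raise ValueError("emissions_path must cover every year")
    if not np.all(np.isfinite(f_anthro)):
        raise ValueError("emissions must be finite")

    b = np.full(n, b_true)
    break_year = b_post = None
    if break_spec:
        break_year = int(break_spec["year"])
        b_post = float(break_spec.get("b", break_spec.get("B")))
        b[yr >= break_year] = b_post

    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)

    m = np.empty(n + 1)
    m[0] = m0 if m_init is None else m_init
    g = np.empty(n)
    for t in range(n):
        g[t] = f_anthro[t] - f0 - b[t] * (m[t] - m0) + eps[t]
        m[t + 1] = m[t] + g[t]

    if convention == "forward":
        g_stored = g
    elif convention == "centered":
        g_stored = np.empty(n)
        g_stored[1:-1] = (m[2:n] - m[0 : n - 2]) / 2.0
        g_stored[0] = m[1] - m[0]
        g_stored[-1] = m[n] - m[n - 1]
    else:
        raise ValueError("convention must be 'forward' or 'centered'")

    df = pd.DataFrame(
        {
            "year": yr,
            "F_anthro": f_anthro,
            "ca": m[:n] / PPM_TO_PGC,
            "M": m[:n],
            "G": g_stored,
            "G_ppm": g_stored / PPM_TO_PGC,
        }
    )
    df.attrs["truth"] = SyntheticTruth(
        trend_slopes={}, b_true=b_true, f0_true=f0, m0=m0,
        break_year=break_year, b_post=b_post, noise_sd=noise_sd, seed=seed,
    )
    validate_budget(df)
    return df


def validate_budget(df: pd.DataFrame) -> None:
    """Check budget-series invariants (contiguous years, M = ca * 2.124)."""
    required = {"year", "F_anthro", "ca", "M", "G"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"budget series missing columns: {sorted(missing)}")
    yr = df["year"].to_numpy()
    if not np.array_equal(np.diff(yr), np.ones(yr.size - 1)):
        raise ValueError("budget years must be contiguous")
    if not np.allclose(df["M"], df["ca"] * PPM_TO_PGC, rtol=1e-9):
        raise ValueError("M must equal ca * 2.124 PgC/ppm")
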