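"""First-principles light-use-efficiency (LUE) model of gross primary production.

The model follows the coordination hypothesis: under typical daytime field
conditions Rubisco-limited and electron-transport-limited photosynthesis rates
coincide, so GPP can be predicted from absorbed light alone,

    GPP = phi0 * I * (chi*ca - Gamma*) / (chi*ca + 2*Gamma*),

with the ratio of leaf-internal to ambient CO2, chi = ci/ca, predicted from the
least-cost hypothesis (plants minimise the combined carbon costs of water
transport and carboxylation capacity):

    chi = xi / (xi + sqrt(D)),   xi = sqrt(beta * K / (1.6 * eta*)),

where D is the vapour-pressure deficit (Pa), K the effective Michaelis-Menten
coefficient of Rubisco, eta* the viscosity of water relative to 25 C and
beta the unit-cost ratio.  Gamma*, Kc and Ko follow Arrhenius kinetics.

Unit conventions
----------------
Temperatures are degrees Celsius at I/O boundaries (gridded forcing, vapour
pressure helpers) and Kelvin inside the biochemical kernels; every function
states which it takes.  Partial pressures are Pa; ambient CO2 is ppm and is
converted with a single configurable surface pressure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = [
    "PhotosynthesisParams",
    "arrhenius_rate",
    "gamma_star",
    "michaelis_k",
    "sat_vapour_pressure",
    "vpd_from_tminmax",
    "water_viscosity_rel",
    "optimal_chi",
    "gpp",
    "gpp_field",
]

T25_K = 298.15  #: reference temperature for all x25 kinetic constants (K)
C_MOLAR_MASS = 12.011  #: g C per mol C


@dataclass(frozen=True)
class PhotosynthesisParams:
    """Kinetic constants and cost parameters of the LUE model.

    Defaults are the standard Bernacchi-style in-vivo kinetics used by
    least-cost/coordination GPP models. ``phi0`` (the intrinsic quantum
    efficiency) has no universally agreed value; 0.085 mol C (mol photon)^-1
    is a common field-calibrated choice and is fully configurable.
    """

    phi0: float = 0.085  # mol C / mol photon
    beta_cost: float = 356.51  # unit-cost ratio of the least-cost model
    r_gas: float = 8.314  # J mol-1 K-1
    gamma_star_x25: float = 4.22  # Pa at 25 C
    gamma_star_dH: float = 37_830.0  # J mol-1
    kc_x25: float = 39.97  # Pa at 25 C
    kc_dH: float = 79_430.0  # J mol-1
    ko_x25: float = 27_480.0  # Pa at 25 C
    ko_dH: float = 36_380.0  # J mol-1
    atm_pressure: float = 101_325.0  # Pa, used for ppm <-> Pa conversion
    o2_fraction: float = 0.21  # mole fraction of O2 in dry air
    po: float = field(init=False)  # O2 partial pressure, Pa

    def __post_init__(self) -> None:
        if not 0.0 < self.phi0 < 0.125:
            raise ValueError(f"phi0 must be in (0, 0.125), got {self.phi0}")
        for name in ("beta_cost", "gamma_star_x25", "kc_x25", "ko_x25", "atm_pressure"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "po", self.o2_fraction * self.atm_pressure)

    def ppm_to_pa(self, x_ppm):
        return np.asarray(x_ppm, dtype=float) * 1e-6 * self.atm_pressure

    def pa_to_ppm(self, x_pa):
        return np.asarray(x_pa, dtype=float) / self.atm_pressure * 1e6


def _check_kelvin(t_k) -> np.ndarray:
    t_k = np.asarray(t_k, dtype=float)
    if np.any(t_k <= 200.0) or np.any(t_k >= 350.0):
        raise ValueError(
            "temperature must be in (200, 350) K; got values outside that range "
            "(passing degrees Celsius where Kelvin is expected is the usual cause)"
        )
    return t_k


def arrhenius_rate(t_k, x25: float, dH: float, r_gas: float = 8.314):
    """Arrhenius temperature response ``x25 * exp(dH*(T-298.15)/(298.15*R*T))``.

    Parameters are the value at 25 C (``x25``, Pa) and the activation energy
    ``dH`` (J mol-1). Exactly ``x25`` at 298.15 K; strictly increasing in T
    for positive ``dH``.
    """
    t_k = _check_kelvin(t_k)
    return x25 * np.exp(dH * (t_k - T25_K) / (T25_K * r_gas * t_k))


def gamma_star(t_k, params: PhotosynthesisParams | None = None):
    """Photorespiratory CO2 compensation point Gamma* (Pa) at temperature T (K)."""
    p = params or PhotosynthesisParams()
    return arrhenius_rate(t_k, p.gamma_star_x25, p.gamma_star_dH, p.r_gas)


def michaelis_k(t_k, params: PhotosynthesisParams | None = None):
    """Effective Michaelis-Menten coefficient ``K = Kc*(1 + Po/Ko)`` (Pa).

    ``Kc`` and ``Ko`` are the carboxylation/oxygenation coefficients, each with
    its own Arrhenius response; ``Po`` is the O2 partial pressure.
    """
    p = params or PhotosynthesisParams()
    kc = arrhenius_rate(t_k, p.kc_x25, p.kc_dH, p.r_gas)
    ko = arrhenius_rate(t_k, p.ko_x25, p.ko_dH, p.r_gas)
    return kc * (1.0 + p.po / ko)


def sat_vapour_pressure(t_c):
    """Saturation vapour pressure of water (Pa) at air temperature ``t_c`` (deg C).

    Magnus-type approximation to the Clausius-Clapeyron relation with the
    Alduchov & Eskridge (1996) coefficients:
    ``e_s = 610.94 * exp(17.625*T / (T + 243.04))``, T in deg C.
    """
    t_c = np.asarray(t_c, dtype=float)
    if np.any(t_c < -60.0) or np.any(t_c > 60.0):
        raise ValueError("sat_vapour_pressure expects temperatures in [-60, 60] C")
    return 610.94 * np.exp(17.625 * t_c / (t_c + 243.04))


def vpd_from_tminmax(tmin_c, tmax_c, e_actual):
    """Vapour pressure deficit D (Pa) from daily extreme temperatures.

    Saturation pressure is averaged between its values at ``tmin`` and
    ``tmax``; D is floored at zero (supersaturation is truncated).
    """
    tmin_c = np.asarray(tmin_c, dtype=float)
    tmax_c = np.asarray(tmax_c, dtype=float)
    e_actual = np.asarray(e_actual, dtype=float)
    if np.any(tmin_c > tmax_c):
        raise ValueError("tmin must not exceed tmax")
    if np.any(e_actual < 0):
        raise ValueError("actual vapour pressure must be non-negative")
    e_sat = 0.5 * (sat_vapour_pressure(tmin_c) + sat_vapour_pressure(tmax_c))
    return np.maximum(0.0, e_sat - e_actual)


# Vogel-Fulcher-Tammann correlation for the dynamic viscosity of liquid water,
# eta(T) = A * exp(B / (T_K - C)) with A in mPa s. Reproduces tabulated values
# to ~0.1% between 0 and 50 C (0 C: 1.787 mPa s, 25 C: 0.890 mPa s).
_VISC_A = 0.02939  # mPa s
_VISC_B = 507.88  # K
_VISC_C = 149.3  # K


def _water_viscosity(t_c):
    return _VISC_A * np.exp(_VISC_B / (np.asarray(t_c, dtype=float) + 273.15 - _VISC_C))


def water_viscosity_rel(t_c):
    """Viscosity of water relative to its value at 25 C (dimensionless eta*).

    Exactly 1 at 25 C by construction; decreasing in temperature
    (eta*(0 C) ~ 2.0).
    """
    t_c = np.asarray(t_c, dtype=float)
    if np.any(t_c < 0.0) or np.any(t_c > 50.0):
        raise ValueError("water_viscosity_rel expects temperatures in [0, 50] C")
    return _water_viscosity(t_c) / _water_viscosity(25.0)


def optimal_chi(t_k, d_pa, ca_ppm=None, params: PhotosynthesisParams | None = None):
    """Least-cost optimal ratio chi = ci/ca at temperature T (K) and VPD D (Pa).

    ``chi = xi / (xi + sqrt(D))`` with ``xi = sqrt(beta*K/(1.6*eta*))``; all
    pressures in Pa.  At the calibration point (298.15 K, 1 kPa) the default
    ``beta = 356.51`` gives chi ~ 0.80.  ``ca_ppm``, when supplied, is only
    validated against the compensation point (chi does not depend on ca in
    this formulation).  The water-viscosity ratio is evaluated with the
    temperature clamped to the liquid-water range [0, 50] C (boundary value
    held outside it), so gridded fields with sub-zero months stay evaluable.
    """
    p = params or PhotosynthesisParams()
    t_k = _check_kelvin(t_k)
    d_pa = np.asarray(d_pa, dtype=float)
    if np.any(d_pa <= 0.0):
        raise ValueError(
            "optimal_chi requires D > 0 Pa (the least-cost solution degenerates "
            "to chi -> 1 at zero VPD); floor D upstream for saturated cells"
        )
    k = michaelis_k(t_k, p)
    eta = water_viscosity_rel(np.clip(t_k - 273.15, 0.0, 50.0))
    xi = np.sqrt(p.beta_cost * k / (1.6 * eta))
    chi = xi / (xi + np.sqrt(d_pa))
    if ca_ppm is not None:
        gs_ppm = p.pa_to_ppm(gamma_star(t_k, p))
        if np.any(np.asarray(ca_ppm, dtype=float) <= gs_ppm):
            raise ValueError("ca must exceed the compensation point Gamma* (ppm)")
    return chi


def invert_beta_cost(
    chi: float = 0.8,
    t_k: float = T25_K,
    d_pa: float = 1000.0,
    params: PhotosynthesisParams | None = None,
) -> float:
    """Solve the least-cost model for its cost parameter beta.

    Inverts ``chi = xi/(xi + sqrt(D))`` at a calibration point:
    ``beta = 1.6 * eta* * (chi/(1-chi))^2 * D / K``.  With the default
    kinetics, Po = 0.21 * 101,325 Pa and (chi, T, D) = (0.8, 298.15 K, 1 kPa)
    this gives beta ~ 361.
    """
    p = params or PhotosynthesisParams()
    k = float(michaelis_k(t_k, p))
    eta = float(water_viscosity_rel(t_k - 273.15))
    return 1.6 * eta * (chi / (1.0 - chi)) ** 2 * d_pa / k


def gpp(i_abs, ca_ppm, chi, gamma_star_ppm, phi0: float = 0.085):
    """Gross primary production (gC m-2 per unit of ``i_abs`` time basis).

    ``GPP = phi0 * I * (chi*ca - Gamma*)/(chi*ca + 2*Gamma*)`` converted from
    mol C to grams.  ``i_abs`` is absorbed light (mol photon m-2), ``ca_ppm``
    ambient CO2 and ``gamma_star_ppm`` the compensation point, both in ppm.
    Below the compensation point (chi*ca < Gamma*) GPP is clamped to zero with
    a warning.
    """
    i_abs = np.asarray(i_abs, dtype=float)
    if np.any(i_abs < 0):
        raise ValueError("absorbed light must be non-negative")
    ci = np.asarray(chi, dtype=float) * np.asarray(ca_ppm, dtype=float)
    gs = np.asarray(gamma_star_ppm, dtype=float)
    frac = (ci - gs) / (ci + 2.0 * gs)
    if np.any(frac < 0):
        warnings.warn(
            "chi*ca below the CO2 compensation point; clamping GPP to 0",
            stacklevel=2,
        )
        frac = np.maximum(frac, 0.0)
    return phi0 * i_abs * frac * C_MOLAR_MASS


def gpp_field(
    forcing: xr.Dataset,
    params: PhotosynthesisParams | None = None,
    d_floor: float = 10.0,
) -> xr.DataArray:
    """Monthly GPP (gC m-2 month-1) over a gridded forcing dataset.

    Absorbed light is ``i0 * fapar`` per cell and month.  VPD is floored at
    ``d_floor`` Pa so that saturated (D = 0) cells stay within the least-cost
    model's domain.  Propagates the per-cell operations of this module; the
    result is finite everywhere the forcing is.
    """
    p = params or PhotosynthesisParams()
    t_k = forcing["tair"].values + 273.15
    d = np.maximum(forcing["vpd"].values, d_floor)
    ca = forcing["ca"].values  # (time,)
    ca3 = ca[:, None, None]
    try:
        chi = optimal_chi(t_k, d, params=p)
        gs_ppm = p.pa_to_ppm(gamma_star(t_k, p))
        i_abs = forcing["i0"].values * forcing["fapar"].values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sub-compensation cells clamp to 0
            vals = gpp(i_abs, ca3, chi, gs_ppm, p.phi0)
    except ValueError as exc:  # re-raise with grid context
        raise ValueError(f"gpp_field failed on forcing grid: {exc}") from exc
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite GPP at (time={bad[0]}, lat={bad[1]}, lon={bad[2]})"
        )
    out = xr.DataArray(
        vals,
        coords=forcing["tair"].coords,
        dims=forcing["tair"].dims,
        name="gpp",
        attrs={"units": "gC m-2 month-1", "long_name": "gross primary production"},
    )
    return out
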