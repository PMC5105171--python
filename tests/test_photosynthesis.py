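"""Unit and property tests for the LUE photosynthesis kernels."""

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from prcarbon.photosynthesis import (
    PhotosynthesisParams,
    arrhenius_rate,
    gamma_star,
    gpp,
    gpp_field,
    invert_beta_cost,
    michaelis_k,
    optimal_chi,
    sat_vapour_pressure,
    vpd_from_tminmax,
    water_viscosity_rel,
)

P = PhotosynthesisParams()


class TestArrhenius:
    def test_reference_identities(self):
        assert arrhenius_rate(298.15, 4.22, 37_830.0) == pytest.approx(4.22, abs=1e-12)
        assert arrhenius_rate(298.15, 39.97, 79_430.0) == pytest.approx(39.97, abs=1e-12)

    def test_hand_evaluated_value(self):
        # independent evaluation of x25*exp(dH*(T-298.15)/(298.15*R*T)) at 15 C
        t, dh, r = 288.15, 37_830.0, 8.314
        expected = 4.22 * np.exp(dh * (t - 298.15) / (298.15 * r * t))
        assert arrhenius_rate(t, 4.22, dh) == pytest.approx(expected, rel=1e-14)

    def test_monotone_increasing_for_positive_dH(self):
        ts = np.linspace(273.0, 313.0, 50)
        vals = gamma_star(ts, P)
        assert np.all(np.diff(vals) > 0)

    def test_celsius_input_rejected(self):
        with pytest.raises(ValueError, match="Kelvin"):
            arrhenius_rate(25.0, 4.22, 37_830.0)


class TestMichaelisK:
    def test_no_oxygenation_limit(self):
        p0 = PhotosynthesisParams(o2_fraction=1e-12)
        assert michaelis_k(298.15, p0) == pytest.approx(39.97, rel=1e-9)

    def test_plug_in_at_reference(self):
        expected = 39.97 * (1.0 + P.po / 27_480.0)
        assert michaelis_k(298.15, P) == pytest.approx(expected, rel=1e-12)

    def test_increasing_in_o2(self):
        lo = PhotosynthesisParams(o2_fraction=0.1)
        hi = PhotosynthesisParams(o2_fraction=0.3)
        assert michaelis_k(298.15, hi) > michaelis_k(298.15, lo)


class TestVapourPressure:
    def test_triple_point_value(self):
        assert sat_vapour_pressure(0.0) == pytest.approx(611.0, rel=0.01)

    def test_strictly_increasing(self):
        ts = np.linspace(-60.0, 60.0, 200)
        assert np.all(np.diff(sat_vapour_pressure(ts)) > 0)

    def test_clausius_clapeyron_steepness(self):
        assert sat_vapour_pressure(20.0) > 2.0 * sat_vapour_pressure(9.0)

    def test_range_error(self):
        with pytest.raises(ValueError):
            sat_vapour_pressure(80.0)

    @pytest.mark.parametrize(
        "tmin,tmax,ea",
        [(10.0, 20.0, 800.0), (0.0, 15.0, 0.0), (5.0, 5.0, 300.0)],
    )
    def test_vpd_plug_in(self, tmin, tmax, ea):
        expected = max(
            0.0, 0.5 * (sat_vapour_pressure(tmin) + sat_vapour_pressure(tmax)) - ea
        )
        assert vpd_from_tminmax(tmin, tmax, ea) == pytest.approx(expected, rel=1e-12)

    def test_vpd_zero_at_saturation(self):
        ea = 0.5 * (sat_vapour_pressure(10.0) + sat_vapour_pressure(20.0))
        assert vpd_from_tminmax(10.0, 20.0, ea) == 0.0

    def test_vpd_order_error(self):
        with pytest.raises(ValueError):
            vpd_from_tminmax(20.0, 10.0, 100.0)


class TestViscosity:
    def test_unity_at_25C(self):
        assert water_viscosity_rel(25.0) == pytest.approx(1.0, abs=1e-14)

    def test_cold_water_ratio(self):
        # absolute viscosities: ~1.787 mPa s at 0 C vs ~0.890 mPa s at 25 C
        assert water_viscosity_rel(0.0) == pytest.approx(1.787 / 0.890, rel=0.02)

    def test_decreasing(self):
        ts = np.linspace(0.0, 50.0, 51)
        assert np.all(np.diff(water_viscosity_rel(ts)) < 0)

    def test_range_error(self):
        with pytest.raises(ValueError):
            water_viscosity_rel(-5.0)


class TestOptimalChi:
    def test_reference_point(self):
        assert optimal_chi(298.15, 1000.0) == pytest.approx(0.80, abs=0.01)

    def test_decreasing_in_vpd(self):
        assert optimal_chi(298.15, 4000.0) < optimal_chi(298.15, 500.0)

    def test_bounded(self):
        chi = optimal_chi(
            np.linspace(270.0, 315.0, 30), np.linspace(100.0, 5000.0, 30)
        )
        assert np.all((chi > 0) & (chi < 1))

    def test_zero_vpd_rejected(self):
        with pytest.raises(ValueError, match="D > 0"):
            optimal_chi(298.15, 0.0)

    def test_beta_round_trip(self):
        """Inverting the least-cost model at its own calibration point."""
        beta = invert_beta_cost(chi=0.8, t_k=298.15, d_pa=1000.0)
        chi_back = optimal_chi(
            298.15,
            1000.0,
            params=PhotosynthesisParams(beta_cost=beta),
        )
        assert chi_back == pytest.approx(0.8, abs=1e-12)

    def test_compensation_point_guard(self):
        with pytest.raises(ValueError, match="compensation"):
            optimal_chi(298.15, 1000.0, ca_ppm=10.0)


class TestGPP:
    def test_zero_light(self):
        assert gpp(0.0, 400.0, 0.8, 43.0) == 0.0

    def test_co2_compensation_point(self):
        assert gpp(100.0, 43.0 / 0.8, 0.8, 43.0) == pytest.approx(0.0, abs=1e-12)

    def test_plug_in_fraction_ratio(self):
        # brute-force evaluation of the CO2 fraction at 400 and 800 ppm
        f400 = (0.8 * 400 - 43) / (0.8 * 400 + 2 * 43)
        f800 = (0.8 * 800 - 43) / (0.8 * 800 + 2 * 43)
        ratio = gpp(100.0, 800.0, 0.8, 43.0) / gpp(100.0, 400.0, 0.8, 43.0)
        assert ratio == pytest.approx(f800 / f400, rel=1e-12)

    def test_subcompensation_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="compensation"):
            out = gpp(100.0, 40.0, 0.8, 43.0)
        assert out == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ca=st.floats(200.0, 1000.0),
        i=st.floats(1.0, 2000.0),
        chi=st.floats(0.6, 0.95),
    )
    def test_monotone_in_ca_and_light(self, ca, i, chi):
        g0 = gpp(i, ca, chi, 43.0)
        assert gpp(i, ca + 10.0, chi, 43.0) > g0
        assert gpp(i * 1.1, ca, chi, 43.0) > g0


class TestGPPField:
    def test_uniform_forcing_gives_uniform_gpp(self, small_forcing):
        ds = small_forcing.isel(time=slice(0, 12)).copy(deep=True)
        for name in ("tair", "vpd", "i0", "fapar", "alpha"):
            ds[name].values[:] = {"tair": 20.0, "vpd": 800.0, "i0": 900.0,
                                  "fapar": 0.5, "alpha": 0.6}[name]
        g = gpp_field(ds)
        for t in range(g.sizes["time"]):
            assert np.ptp(g.isel(time=t).values) < 1e-10

    def test_linear_in_fapar(self, small_forcing):
        base = gpp_field(small_forcing)
        doubled = small_forcing.copy(deep=True)
        doubled["fapar"].values[:] = np.minimum(doubled["fapar"].values * 2, 1.0)
        # only compare cells that did not hit the fapar=1 ceiling
        ok = (small_forcing["fapar"].values * 2) <= 1.0
        ratio = gpp_field(doubled).values[ok] / np.where(base.values[ok] == 0, np.nan, base.values[ok])
        assert np.nanmax(np.abs(ratio - 2.0)) < 1e-9

    def test_matches_naive_per_cell_loop(self, noisy_forcing):
        ds = noisy_forcing.isel(time=slice(0, 24), lat=slice(0, 5), lon=slice(0, 5))
        fast = gpp_field(ds).values
        p = PhotosynthesisParams()
        slow = np.empty_like(fast)
        for ti in range(ds.sizes["time"]):
            ca = float(ds["ca"][ti])
            for yi in range(ds.sizes["lat"]):
                for xi in range(ds.sizes["lon"]):
                    tk = float(ds["tair"][ti, yi, xi]) + 273.15
                    d = max(float(ds["vpd"][ti, yi, xi]), 10.0)
                    chi = float(optimal_chi(tk, d, params=p))
                    gs = float(p.pa_to_ppm(gamma_star(tk, p)))
                    i_abs = float(ds["i0"][ti, yi, xi] * ds["fapar"][ti, yi, xi])
                    slow[ti, yi, xi] = gpp(i_abs, ca, chi, gs, p.phi0)
        np.testing.assert_allclose(fast, slow, rtol=1e-10)

    def test_finite_and_labelled(self, noisy_forcing):
        g = gpp_field(noisy_forcing)
        assert np.all(np.isfinite(g.values))
        assert g.attrs["units"] == "gC m-2 month-1"
        assert isinstance(g, xr.DataArray)
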