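"""Tests of single-driver detrending experiments and period attribution."""

import numpy as np
import pandas as pd
import pytest

from prcarbon import forcing
from prcarbon.attribution import (
    ExperimentSpec,
    additivity_check,
    apply_fapar_climatology,
    detrend_driver,
    period_delta,
    run_experiment,
)
from prcarbon.respiration import assign_pft_params, default_pft_table


@pytest.fixture(scope="module")
def trended():
    """Noise-free forcing with trends in every driver bundle."""
    return forcing.make_forcing(
        (6, 12), (1900, 1959),
        trend_spec={"ca": 1.0, "tair": 0.02, "fapar": 0.001, "vpd": 1.0, "alpha": -0.0005},
        noise_spec={"sd": 0}, seed=21,
    )


@pytest.fixture(scope="module")
def resp(trended):
    return assign_pft_params(trended["pft"], default_pft_table(int(trended["pft"].values.max()) + 1))


KW = dict(baseline=(1901, 1915), p1=(1901, 1915), p2=(1944, 1958))


class TestDetrendDriver:
    def test_removes_per_cell_month_slope(self, trended):
        out = detrend_driver(trended, "climate", baseline=(1901, 1915))
        v = out["tair"].values.reshape(60, 12, 6, 12)
        yr = np.arange(60.0)
        yc = yr - yr.mean()
        slope = np.tensordot(yc, v, axes=(0, 0)) / np.sum(yc**2)
        assert np.abs(slope).max() < 1e-10

    def test_baseline_mean_preserved(self, trended):
        out = detrend_driver(trended, "fapar", baseline=(1901, 1915))
        years = pd.DatetimeIndex(trended["time"].values).year
        mask = (years >= 1901) & (years <= 1915)
        before = trended["fapar"].values[mask].mean(axis=0)
        after = out["fapar"].values[mask].mean(axis=0)
        np.testing.assert_allclose(after, before, atol=1e-10)

    def test_untrended_driver_unchanged(self, trended):
        out = detrend_driver(trended, "par", baseline=(1901, 1915))  # i0 has no trend
        np.testing.assert_allclose(out["i0"].values, trended["i0"].values, atol=1e-9)

    def test_unknown_driver_rejected(self, trended):
        with pytest.raises(ValueError, match="unknown driver"):
            detrend_driver(trended, "soil_moisture")


class TestFaparClimatology:
    def test_pre_cutoff_replaced_post_untouched(self, trended):
        out = apply_fapar_climatology(trended, (1930, 1944), cutoff_year=1930)
        years = pd.DatetimeIndex(trended["time"].values).year
        post = years >= 1930
        np.testing.assert_array_equal(out["fapar"].values[post],
                                      trended["fapar"].values[post])
        # pre-cutoff: identical across years per calendar month
        pre = out["fapar"].values[~post].reshape(-1, 12, 6, 12)
        for y in range(1, pre.shape[0]):
            np.testing.assert_array_equal(pre[y], pre[0])

    def test_matches_naive_monthly_mean(self, trended):
        out = apply_fapar_climatology(trended, (1930, 1944), cutoff_year=1930)
        years = pd.DatetimeIndex(trended["time"].values).year.to_numpy()
        months = pd.DatetimeIndex(trended["time"].values).month.to_numpy()
        sel = (years >= 1930) & (years <= 1944) & (months == 3)
        clim = trended["fapar"].values[sel].mean(axis=0)
        first_march = np.nonzero(months == 3)[0][0]
        np.testing.assert_allclose(out["fapar"].values[first_march], clim, atol=1e-12)

    def test_empty_window_rejected(self, trended):
        with pytest.raises(ValueError, match="window"):
            apply_fapar_climatology(trended, (1850, 1860))


class TestExperiments:
    def test_control_has_no_period_change(self, trended, resp):
        flux = run_experiment(trended, ExperimentSpec(driver="none", **KW), resp_params=resp)
        res = period_delta(flux, KW["p1"], KW["p2"])
        assert abs(res.delta_gpp) < 1e-9
        assert abs(res.delta_nep) < 1e-9

    def test_single_trend_experiment_equals_full_run(self, resp):
        ds = forcing.make_forcing((6, 12), (1900, 1959), trend_spec={"ca": 1.0},
                                  noise_spec={"sd": 0}, seed=22)
        full = run_experiment(ds, ExperimentSpec(driver="all", **KW), resp_params=resp)
        ca_only = run_experiment(ds, ExperimentSpec(driver="ca", **KW), resp_params=resp)
        np.testing.assert_allclose(ca_only["nep"].values, full["nep"].values, atol=1e-12)

    def test_co2_fertilization_signs(self, trended, resp):
        flux = run_experiment(trended, ExperimentSpec(driver="ca", **KW), resp_params=resp)
        res = period_delta(flux, KW["p1"], KW["p2"])
        assert res.delta_gpp > 0 and res.delta_nep > 0

    def test_warming_increases_respiration(self, resp):
        ds = forcing.make_forcing((6, 12), (1900, 1959), trend_spec={"tair": 0.02},
                                  noise_spec={"sd": 0}, seed=23)
        flux = run_experiment(ds, ExperimentSpec(driver="climate", **KW), resp_params=resp)
        res = period_delta(flux, KW["p1"], KW["p2"])
        assert res.delta_reco > 0

    def test_failure_carries_experiment_label(self, trended):
        bad = trended.copy(deep=True)
        bad["fapar"].values[:] = np.nan
        with pytest.raises(RuntimeError, match="experiment 'ca'"):
            run_experiment(bad, ExperimentSpec(driver="ca", **KW))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="unknown driver"):
            ExperimentSpec(driver="everything")
        with pytest.raises(ValueError, match="P1 must precede"):
            ExperimentSpec(p1=(1990, 2000), p2=(1995, 2005))


@pytest.fixture(scope="module")
def flux(trended, resp):
    return run_experiment(trended, ExperimentSpec(driver="all", **KW), resp_params=resp)


class TestPeriodDelta:
    def test_identical_periods_zero(self, flux):
        res = period_delta(flux, (1920, 1930), (1920, 1930))
        assert res.delta_gpp == 0 and res.delta_nep == 0 and res.delta_reco == 0

    def test_nep_identity(self, flux):
        res = period_delta(flux, KW["p1"], KW["p2"])
        assert res.delta_nep == pytest.approx(res.delta_gpp - res.delta_reco, abs=1e-9)

    def test_zonal_sums_to_global(self, flux):
        res = period_delta(flux, KW["p1"], KW["p2"])
        for name in ("gpp", "reco", "nep"):
            assert res.zonal[f"delta_{name}_pgc"].sum() == pytest.approx(
                getattr(res, f"delta_{name}"), abs=1e-6)

    def test_hand_computed_toy_delta(self):
        """Spreadsheet-style oracle on a 2x2 grid, 2 years of constant fluxes."""
        import xarray as xr

        time = pd.date_range("2000-01-01", periods=24, freq="MS")
        lat = np.array([-45.0, 45.0])
        lon = np.array([-90.0, 90.0])
        gpp = np.zeros((24, 2, 2))
        gpp[:12] = 10.0  # year 2000: 120 gC/m2/yr per cell
        gpp[12:] = 13.0  # year 2001: 156
        reco = np.full((24, 2, 2), 9.0)
        ds = xr.Dataset(
            {"gpp": (("time", "lat", "lon"), gpp),
             "reco": (("time", "lat", "lon"), reco),
             "nep": (("time", "lat", "lon"), gpp - reco)},
            coords={"time": time, "lat": lat, "lon": lon},
        )
        area = np.array([2.0e12, 3.0e12])  # m2 per cell, by latitude row
        res = period_delta(ds, (2000, 2000), (2001, 2001), cell_area=area)
        # delta GPP = 36 gC/m2/yr * total area 1e13 m2 = 3.6e14 gC = 0.36 PgC
        assert res.delta_gpp == pytest.approx(0.36, rel=1e-12)
        assert res.delta_reco == pytest.approx(0.0, abs=1e-15)
        assert res.delta_nep == pytest.approx(0.36, rel=1e-12)

    def test_period_outside_range_rejected(self, flux):
        with pytest.raises(ValueError, match="outside"):
            period_delta(flux, (1800, 1810), KW["p2"])


class TestAdditivity:
    def test_small_trend_interactions_are_minor(self, trended, resp):
        results = {}
        for driver in ("ca", "climate", "fapar", "alpha"):
            flux = run_experiment(trended, ExperimentSpec(driver=driver, **KW), resp_params=resp)
            results[driver] = period_delta(flux, KW["p1"], KW["p2"])
        full_flux = run_experiment(trended, ExperimentSpec(driver="all", **KW), resp_params=resp)
        full = period_delta(full_flux, KW["p1"], KW["p2"])
        report = additivity_check(results, full)
        # columns compose: sum of per-driver deltas equals the reported sum
        drivers = ["ca", "climate", "fapar", "alpha"]
        np.testing.assert_allclose(report[drivers].sum(axis=1), report["sum_single"])
        np.testing.assert_allclose(report["full"] - report["sum_single"],
                                   report["remainder"])
        # first-order regime: interaction remainder below 10% of the full change
        assert abs(report.loc["gpp", "remainder"]) < 0.1 * abs(report.loc["gpp", "full"])
        assert abs(report.loc["nep", "remainder"]) < 0.1 * abs(report.loc["nep", "full"])
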