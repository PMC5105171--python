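"""File formats, run configuration and end-to-end pipeline orchestration.

Gridded fields travel as CF-style NetCDF (dimensions time/lat/lon, units
attributes, latitude ascending, longitude -180..180, monthly time stamps);
budget series as CSV with header ``year,F_anthro,ca,M,G``.  A run
configuration is a flat, fully serialisable mapping: persisting it and
re-running reproduces identical outputs (all randomness flows from one root
seed, split per stage).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import attribution, forcing, growth, respiration, sensitivity, ssa
from .forcing import PPM_TO_PGC
from .photosynthesis import PhotosynthesisParams

__all__ = [
    "RunConfig",
    "read_forcing",
    "write_forcing",
    "read_budget_csv",
    "write_budget_csv",
    "run_pipeline",
]

log = logging.getLogger("prcarbon")

BUDGET_COLUMNS = ["year", "F_anthro", "ca", "M", "G"]


def write_forcing(ds: xr.Dataset, path) -> None:
    """Write a forcing (or flux) dataset as NetCDF3 (CF-style attributes kept)."""
    ds.to_netcdf(path, engine="scipy")


def read_forcing(path) -> xr.Dataset:
    """Read a forcing dataset back; validates the schema, loads into memory."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    forcing.validate_forcing(ds)
    return ds


def write_budget_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, columns=BUDGET_COLUMNS, index=False, float_format="%.10g")


def read_budget_csv(path, mass_per_ppm: float = PPM_TO_PGC) -> pd.DataFrame:
    """Read an annual budget CSV; derive M and G when absent.

    A minimal file needs ``year,F_anthro,ca``.  M is derived as
    ``ca * mass_per_ppm``; G as the forward annual increment
    ``G(t) = M(t+1) - M(t)`` with the final year left NaN (no later
    observation exists under this convention).  Non-contiguous years raise.
    """
    df = pd.read_csv(path)
    missing = {"year", "F_anthro", "ca"} - set(df.columns)
    if missing:
        raise ValueError(f"budget CSV missing columns: {sorted(missing)}")
    yr = df["year"].to_numpy()
    if not np.array_equal(np.diff(yr), np.ones(yr.size - 1)):
        raise ValueError("budget CSV years must be contiguous")
    if "M" not in df.columns:
        df["M"] = df["ca"] * mass_per_ppm
    if "G" not in df.columns:
        g = np.diff(df["M"].to_numpy()).astype(float)
        df["G"] = np.append(g, np.nan)
    df["G_ppm"] = df["G"] / mass_per_ppm
    forcing.validate_budget(df)
    return df


@dataclass
class RunConfig:
    """Serialisable configuration of an end-to-end synthetic run."""

    outdir: str = "prcarbon_run"
    seed: int = 0
    grid: tuple[int, int] = (18, 36)
    years: tuple[int, int] = (1900, 2013)
    budget_years: tuple[int, int] = (1959, 2014)
    b_true: float = 0.02
    noise_sd: float = 0.2
    break_year: int | None = 2002
    break_b_factor: float = 1.3
    fit_window_years: int = 30
    baseline: tuple[int, int] = (1901, 1915)
    p1: tuple[int, int] = (1901, 1915)
    p2: tuple[int, int] = (1995, 2010)
    ssa_min_period: float = 5.0
    n_surrogates: int = 100
    drivers: tuple[str, ...] = ("ca", "climate", "fapar", "alpha")
    phot_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("grid", "years", "budget_years", "baseline", "p1", "p2", "drivers"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _stage_seeds(root_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from one root seed (< 2**31)."""
    ss = np.random.SeedSequence(root_seed)
    names = ("forcing", "budget", "ssa")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on synthetic inputs and persist versioned outputs.

    Stages: synthetic forcing -> PR-model attribution experiments; synthetic
    budget series -> sink-model fit, break test, airborne fraction, SSA of the
    growth rate; CO2-sensitivity curve.  Writes NetCDF/CSV/JSON outputs plus
    the config used; raises ``RuntimeError`` naming the failing stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    config.to_yaml(out / "config.yaml")
    results: dict = {"outdir": str(out)}
    errors: list[str] = []

    phot = PhotosynthesisParams(**config.phot_overrides)

    def stage(name, fn):
        try:
            log.info("stage %s", name)
            results[name] = fn()
        except Exception as exc:  # aggregated below with stage names
            errors.append(f"{name}: {exc}")

    def _forcing():
        ds = forcing.make_forcing(config.grid, config.years, seed=seeds["forcing"])
        write_forcing(ds, out / "forcing.nc")
        return ds

    stage("forcing", _forcing)

    def _attribution():
        ds = results["forcing"]
        pft_table = respiration.default_pft_table(int(ds["pft"].values.max()) + 1)
        resp = respiration.assign_pft_params(ds["pft"], pft_table)
        deltas, flux_full = {}, None
        for driver in (*config.drivers, "all", "none"):
            spec = attribution.ExperimentSpec(driver=driver, baseline=config.baseline,
                                              p1=config.p1, p2=config.p2)
            flux = attribution.run_experiment(ds, spec, phot, resp)
            res = attribution.period_delta(flux, config.p1, config.p2)
            deltas[driver] = res
            if driver == "all":
                flux_full = res
                write_forcing(flux.drop_vars("cell_area"), out / "flux_full.nc")
            res.zonal.to_csv(out / f"zonal_{driver}.csv")
        singles = {d: r for d, r in deltas.items() if d in config.drivers}
        add = attribution.additivity_check(singles, flux_full)
        add.to_csv(out / "additivity.csv")
        summary = {d: r.as_dict() for d, r in deltas.items()}
        (out / "attribution.json").write_text(json.dumps(summary, indent=2, default=float))
        return summary

    if "forcing" in results:
        stage("attribution", _attribution)

    def _budget():
        break_spec = None
        if config.break_year:
            break_spec = {"year": config.break_year, "b": config.b_true * config.break_b_factor}
        df = forcing.make_budget_series(
            config.budget_years, b_true=config.b_true, noise_sd=config.noise_sd,
            break_spec=break_spec, seed=seeds["budget"],
        )
        write_budget_csv(df, out / "budget.csv")
        return df

    stage("budget", _budget)

    def _growth():
        df = results["budget"]
        y0 = int(df["year"].iloc[0])
        fit = growth.fit_sink_model(df, (y0, y0 + config.fit_window_years - 1))
        report = {
            "B": fit.b, "B_se": fit.b_se, "intercept": fit.intercept,
            "window": list(fit.window),
        }
        if config.break_year:
            bt = growth.residual_break_test(fit, config.break_year)
            report["break_test"] = dataclasses.asdict(bt)
        af = growth.airborne_fraction(df)
        tr = growth.mann_kendall_sen(af.to_numpy(), af.index.to_numpy())
        report["airborne_fraction_trend"] = dataclasses.asdict(tr)
        (out / "sink_fit.json").write_text(json.dumps(report, indent=2, default=float))
        fit.residuals.to_csv(out / "residuals.csv", header=True)
        return report

    if "budget" in results:
        stage("growth", _growth)

    def _ssa():
        df = results["budget"]
        g = df["G_ppm"].to_numpy()
        x5 = ssa.extract_band(ssa.ssa_decompose(g), config.ssa_min_period)
        sd = ssa.subsignal_uncertainty(
            g, min_period=config.ssa_min_period,
            n_surrogates=config.n_surrogates, seed=seeds["ssa"],
        )
        pd.DataFrame({"year": df["year"], "G_ppm": g, "X5": x5, "X5_sd": sd}).to_csv(
            out / "ssa_growth.csv", index=False)
        return {"x5_var_share": float(np.var(x5) / np.var(g))}

    if "budget" in results:
        stage("ssa", _ssa)

    def _sensitivity():
        curve = sensitivity.sensitivity_curve(np.arange(300.0, 801.0, 25.0))
        curve.to_csv(out / "sensitivity.csv", index=False)
        return {"beta_400": float(sensitivity.beta_co2(400.0)),
                "beta_800": float(sensitivity.beta_co2(800.0))}

    stage("sensitivity", _sensitivity)

    if errors:
        raise RuntimeError("pipeline stage failures: " + "; ".join(errors))
    return results
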