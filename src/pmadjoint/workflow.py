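"""Config-driven end-to-end run: generate -> simulate -> adjoint (+check) ->
attribute -> regional -> counterfactual -> report.

Every stage writes its artefacts into a fixed directory layout with
deterministic bytes (no timestamps), so rerunning with the same configuration
reproduces the bundle exactly; a structured run log records each stage and
the SHA-256 of every file it wrote.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import regional as _regional
from .adjoint import SensitivityField
from .attribution import aggregate_ledger, compute_contributions, monthly_shares
from .counterfactual import change_report, country_change, delta_contributions
from .fusion import population_weighted_mean
from .grids import Field, field_to_netcdf
from .health import uncertainty_bounds
from .pipeline import Pipeline
from .report import summary_ratios
from .synthetic import WorldConfig, config_from_dict, generate_world, save_world


@dataclasses.dataclass
class PipelineConfig:
    """Toggles and locations of one full run."""

    world: WorldConfig = dataclasses.field(default_factory=WorldConfig)
    years: tuple[str, str] = ("2005", "2015")
    nonlinear_chemistry: bool = True
    response: str = "paf"                 # "paf" or "linear"
    renormalize_to_J: bool = False
    gradient_check_samples: int = 0       # 0 = skip the check stage
    out_dir: str = "pmadjoint_run"

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        world = config_from_dict(raw.pop("world", {}) or {})
        cfg = cls(world=world, **{k: v for k, v in raw.items()
                                  if k in {f.name for f in dataclasses.fields(cls)}
                                  and k != "world"})
        if seed is not None:
            cfg.world = dataclasses.replace(cfg.world, seed=int(seed))
        cfg.years = tuple(str(y) for y in cfg.years)
        return cfg


def _sha(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def sensitivity_to_netcdf(lam: SensitivityField, path) -> None:
    ds = xr.Dataset(coords={"month": np.arange(1, 13), "lat": lam.grid.lat,
                            "lon": lam.grid.lon})
    for sp, arr in sorted(lam.values.items()):
        ds[f"lambda_{sp}"] = xr.DataArray(arr, dims=("month", "lat", "lon"))
        ds[f"lambda_{sp}"].attrs.update(units="deaths kg-1", species=sp)
    ds.attrs.update({k: str(v) for k, v in lam.meta.items()})
    ds.coords["lat"].attrs["units"] = "degrees_north"
    ds.coords["lon"].attrs["units"] = "degrees_east"
    ds.to_netcdf(path, engine="scipy")


def sensitivity_from_netcdf(path) -> SensitivityField:
    from .grids import GridSpec
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = GridSpec(lat=ds["lat"].values, lon=ds["lon"].values)
    vals = {str(ds[v].attrs["species"]): ds[v].transpose("month", "lat", "lon").values
            for v in ds.data_vars if v.startswith("lambda_")}
    return SensitivityField(grid, vals, dict(ds.attrs))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report dictionary (also written to
    ``<out>/report/report.json``)."""
    out = pathlib.Path(config.out_dir)
    log: list[dict] = []

    def _log(stage: str, files: list[pathlib.Path]) -> None:
        log.append({"stage": stage,
                    "files": {f.name: _sha(f) for f in sorted(files)}})

    # -- generate -----------------------------------------------------------
    world = generate_world(config.world)
    wdir = out / "world"
    save_world(world, wdir)
    _log("generate", list(wdir.iterdir()))

    year_b = config.years[1]
    pipe = Pipeline(world, year=year_b,
                    nonlinear_chemistry=config.nonlinear_chemistry,
                    response=config.response)
    base = pipe.base()

    # -- simulate -----------------------------------------------------------
    sdir = out / "simulate"
    sdir.mkdir(parents=True, exist_ok=True)
    field_to_netcdf(Field(world.coarse, base.pm25_monthly, "ug m-3",
                          "pm25_monthly"), sdir / "pm25_monthly.nc")
    field_to_netcdf(Field(world.coarse, base.pm25_monthly.mean(axis=0), "ug m-3",
                          "pm25_annual"), sdir / "pm25_annual.nc")
    field_to_netcdf(Field(world.fine, base.exposure_annual_fine, "ug m-3",
                          "exposure_annual"), sdir / "exposure_annual_fine.nc")
    _log("simulate", list(sdir.iterdir()))

    # -- adjoint ------------------------------------------------------------
    adir = out / "adjoint"
    adir.mkdir(parents=True, exist_ok=True)
    lam = pipe.adjoint()
    sensitivity_to_netcdf(lam, adir / "sensitivity.nc")
    afiles = [adir / "sensitivity.nc"]
    if config.gradient_check_samples > 0:
        chk = pipe.gradient_check(n_samples=config.gradient_check_samples,
                                  seed=config.world.seed)
        with open(adir / "gradient_check.json", "w") as fh:
            json.dump({k: chk[k] for k in ("max_rel_error", "median_rel_error",
                                           "n_samples")}, fh, sort_keys=True, indent=1)
        afiles.append(adir / "gradient_check.json")
    _log("adjoint", afiles)

    # -- attribute ----------------------------------------------------------
    tdir = out / "attribute"
    tdir.mkdir(parents=True, exist_ok=True)
    lam_fine = lam.to_fine(world.fine)
    ledger = compute_contributions(
        lam_fine, world.emissions[year_b],
        renormalize_to=base.cost.J if config.renormalize_to_J else None)
    for by in ("species", "main_sector", "detailed_sector", "country",
               "sector_x_species"):
        aggregate_ledger(ledger, by, mask=world.mask).to_csv(
            tdir / f"by_{by}.csv", index=False)
    monthly_shares(ledger, "species").to_csv(tdir / "monthly_shares_species.csv")
    monthly_shares(ledger, "main_sector").to_csv(tdir / "monthly_shares_sector.csv")
    field_to_netcdf(Field(world.fine, ledger.per_cell(), "deaths",
                          "contribution_per_cell"), tdir / "contribution_per_cell.nc")
    _log("attribute", list(tdir.iterdir()))

    # -- regional -----------------------------------------------------------
    rdir = out / "regional"
    rdir.mkdir(parents=True, exist_ok=True)
    cost_bc20 = pipe.evaluate(boundary_scale=0.8)
    linear_mode = (not config.nonlinear_chemistry) and config.response == "linear"
    J_extra, extra_cell = _regional.extra_regional_contribution(
        base.cost, cost_bc20, linear_mode=linear_mode)
    split = _regional.residual_split(base.cost.J, J_extra, ledger.total)
    caused = ledger.per_cell()
    incurred = base.cost.per_cell
    cr_total = _regional.contribution_ratio(caused, incurred, world.mask, "vs_total")
    incurred_within = np.clip(incurred - extra_cell, 0.0, None)
    cr_within = _regional.contribution_ratio(caused, incurred_within, world.mask,
                                             "within_region")
    pd.DataFrame([{
        "J_total": split.J_total, "J_extra": split.J_extra,
        "J_anthro": split.J_anthro, "J_residual": split.J_residual,
        "within_domain": split.within_domain,
    }]).to_csv(rdir / "split.csv", index=False)
    cr_total.country_table.to_csv(rdir / "cr_vs_total_by_country.csv", index=False)
    cr_within.country_table.to_csv(rdir / "cr_within_by_country.csv", index=False)
    for name, cr in (("cr_vs_total", cr_total), ("cr_within", cr_within)):
        safe = np.where(np.isfinite(cr.cr), cr.cr, 0.0)
        field_to_netcdf(Field(world.fine, safe, "ratio", name), rdir / f"{name}.nc")
    _log("regional", list(rdir.iterdir()))

    # -- counterfactual -----------------------------------------------------
    cdir = out / "counterfactual"
    cdir.mkdir(parents=True, exist_ok=True)
    delta = delta_contributions(lam_fine, world.emissions[config.years[0]],
                                world.emissions[year_b])
    for by in ("species", "main_sector", "detailed_sector"):
        change_report(delta, by).to_csv(cdir / f"change_{by}.csv", index=False)
    country_change(delta, world.mask).to_csv(cdir / "change_country.csv", index=False)
    _log("counterfactual", list(cdir.iterdir()))

    # -- report -------------------------------------------------------------
    pdir = out / "report"
    pdir.mkdir(parents=True, exist_ok=True)
    bounds = uncertainty_bounds(base.exposure_annual_fine, pipe.health,
                                pipe.response, pipe.slopes["mid"])
    pwm = population_weighted_mean(base.exposure_annual_fine,
                                   world.population.values,
                                   world.mask.receptor_mask())
    numbers = {
        "total": base.cost.J, "anthropogenic": ledger.total,
        "extra_regional": J_extra, "residual": split.J_residual,
        "within_domain": split.within_domain,
        "low": bounds["J_low"], "mid": bounds["J_mid"], "high": bounds["J_high"],
    }
    ratios = summary_ratios(numbers)
    ratios.to_csv(pdir / "summary_ratios.csv", index=False)
    report = {
        "deaths_total": base.cost.J,
        "deaths_low": bounds["J_low"],
        "deaths_high": bounds["J_high"],
        "deaths_anthropogenic_firstorder": ledger.total,
        "deaths_extra_regional": J_extra,
        "deaths_residual": split.J_residual,
        "population_weighted_exposure": pwm,
        "avoided_deaths_2005_2015": -delta.total_change,
        "cause_shares": base.cost.cause_shares(),
        "summary_ratios": {r["name"]: r["value"] for _, r in ratios.iterrows()},
    }
    with open(pdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    _log("report", list(pdir.iterdir()))
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, sort_keys=True, indent=1)
    return report
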