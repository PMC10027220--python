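"""Seeded generator of every input the attribution pipeline consumes.

The generated "world" mimics the statistical structure of the study inputs:
a European-scale domain with an ocean band in the west, contiguous countries
tiling the land, log-normally clustered urban population on a rural floor,
sectoral emission archetypes (point sources for energy/industry, population-
proportional area sources for residential/waste, corridor sources for
transport/shipping/aviation, cropland blocks for agriculture) with seasonal
cycles (winter residential heating peak, Feb-Apr agricultural-crop peak),
west-to-east gradients in baseline mortality, GBD-style relative-risk curves
with low/mid/high bounds, monthly winds, per-tracer boundary-inflow
concentrations, and a noisy satellite annual-mean PM2.5 estimate.

Every output is a deterministic function of the configured seed; each
component draws from its own named substream so adding or resizing one
component never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import zlib
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from scipy import ndimage

from .grids import (DEFAULT_SECTOR_TO_MAIN, DETAILED_SECTORS, MAIN_SECTORS,
                    SPECIES, CountryMask, EmissionInventory, Field, GridSpec,
                    refine_grid, regular_grid)
from . import ctm as _ctm
from .health import CAUSES, HealthInputs, MortalityTable, RRCurveSet


class WorldError(ValueError):
    pass


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent of every other component's stream."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

#: 2015 annual anthropogenic emission totals, kg/yr per (species, main sector)
DEFAULT_EMISSION_TOTALS: dict[tuple[str, str], float] = {
    ("NOx", "ground_transport"): 3.2e9,
    ("NOx", "energy"): 1.6e9,
    ("NOx", "industry"): 1.0e9,
    ("NOx", "shipping"): 1.1e9,
    ("NOx", "aviation"): 0.35e9,
    ("NOx", "residential"): 0.35e9,
    ("NOx", "waste"): 0.05e9,
    ("NOx", "agricultural"): 0.25e9,
    ("NH3", "agricultural"): 3.5e9,
    ("NH3", "residential"): 0.25e9,
    ("NH3", "waste"): 0.15e9,
    ("NH3", "ground_transport"): 0.10e9,
    ("SO2", "energy"): 1.3e9,
    ("SO2", "industry"): 0.8e9,
    ("SO2", "shipping"): 0.35e9,
    ("SO2", "residential"): 0.20e9,
    ("SO2", "waste"): 0.05e9,
    ("OC", "residential"): 0.65e9,
    ("OC", "ground_transport"): 0.12e9,
    ("OC", "industry"): 0.10e9,
    ("OC", "agricultural"): 0.10e9,
    ("OC", "waste"): 0.08e9,
    ("OC", "energy"): 0.03e9,
    ("BC", "residential"): 0.18e9,
    ("BC", "ground_transport"): 0.16e9,
    ("BC", "industry"): 0.06e9,
    ("BC", "shipping"): 0.05e9,
    ("BC", "energy"): 0.02e9,
    ("BC", "agricultural"): 0.03e9,
    ("SOAP", "industry"): 1.1e9,
    ("SOAP", "residential"): 0.9e9,
    ("SOAP", "ground_transport"): 0.5e9,
    ("SOAP", "energy"): 0.2e9,
    ("SOAP", "waste"): 0.1e9,
}

#: relative species-level change of 2015 totals vs 2005 (2005 = 2015/(1+change))
DEFAULT_SPECIES_CHANGE = {
    "NH3": -0.013, "NOx": -0.193, "SO2": -0.349, "SOAP": -0.268,
    "OC": -0.05, "BC": -0.15,
}

#: detailed-sector split of each main sector's total
DETAILED_SPLIT: dict[str, dict[str, float]] = {
    "energy": {"energy-power": 0.80, "energy-other": 0.20},
    "industry": {"industry-combustion": 0.60, "industry-process": 0.40},
    "ground_transport": {"road-transport": 0.75, "ground-transport-other": 0.25},
    "shipping": {"domestic-shipping": 0.30, "international-shipping": 0.70},
    "aviation": {"aviation-lto": 0.35, "aviation-cruise": 0.65},
    "residential": {"residential-heating": 0.70, "residential-other": 0.30},
    "waste": {"waste": 1.0},
    "agricultural": {"agriculture-livestock": 0.55, "agriculture-crops": 0.30,
                     "agriculture-waste-burning": 0.15},
}


def _normalised_profile(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    return raw * 12.0 / raw.sum()


def default_seasonal_profiles() -> dict[str, np.ndarray]:
    """Monthly weights per detailed sector, each summing to 12."""
    m = np.arange(12)
    winter = 1.0 + 0.9 * np.cos(2 * np.pi * m / 12)           # Jan peak
    mild_winter = 1.0 + 0.3 * np.cos(2 * np.pi * m / 12)
    summer = 1.0 - 0.15 * np.cos(2 * np.pi * m / 12)
    spring = np.array([0.8, 1.8, 2.0, 1.8, 1.0, 0.6, 0.6, 0.6, 0.8, 0.8, 0.8, 0.4])
    flat = np.ones(12)
    profiles = {
        "residential-heating": winter,
        "residential-other": mild_winter,
        "energy-power": mild_winter,
        "energy-other": mild_winter,
        "agriculture-crops": spring,
        "agriculture-waste-burning": spring,
        "agriculture-livestock": 1.0 + 0.2 * np.cos(2 * np.pi * (m - 3) / 12),
        "aviation-lto": summer,
        "aviation-cruise": summer,
        "domestic-shipping": summer,
        "international-shipping": flat,
        "road-transport": flat,
        "ground-transport-other": flat,
        "industry-combustion": mild_winter,
        "industry-process": flat,
        "waste": flat,
    }
    return {sec: _normalised_profile(p) for sec, p in profiles.items()}


def default_rr_params() -> dict[str, tuple[float, float]]:
    """(a, b) of the mid curve RR(C) = 1 + a*log1p((C - TMREL)/b) per cause."""
    return {
        "IHD": (0.30, 35.0), "stroke": (0.25, 35.0), "COPD": (0.20, 40.0),
        "LRI": (0.22, 30.0), "LC": (0.15, 40.0), "T2D": (0.12, 35.0),
    }


DEFAULT_BOUNDARY_INFLOW = {
    "sulfate": 3.0, "nitrate": 1.5, "nh3": 0.75,
    "OC": 2.0, "BC": 0.38, "SOA": 2.5, "dust": 6.25,
}


@dataclasses.dataclass
class WorldConfig:
    """Full configuration of a synthetic world (see module docstring)."""

    seed: int = 0
    # domain: coarse grid and the fine refinement nested in it
    lat0_edge: float = 33.0
    lon0_edge: float = -15.0
    coarse_dlat: float = 0.8
    coarse_dlon: float = 1.0
    coarse_nlat: int = 30
    coarse_nlon: int = 40
    refinement: int = 4
    ocean_lon_max: float = -10.0         # cells west of this are ocean
    n_countries: int = 12
    receptor_countries: tuple[int, ...] | None = None   # None = all countries
    population_total: float = 598.97e6
    n_cities: int = 25
    emission_totals: dict[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EMISSION_TOTALS))
    species_change_2005: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SPECIES_CHANGE))
    seasonal_profiles: dict[str, np.ndarray] = dataclasses.field(
        default_factory=default_seasonal_profiles)
    # health
    tmrel: float = 2.4
    rr_params: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=default_rr_params)
    rr_low_factor: float = 0.55          # low curve: 1 + f*(mid - 1)
    rr_high_factor: float = 1.65
    mortality_west_total: float = 295.0  # six-cause y0 total, west edge country
    mortality_east_total: float = 1025.0
    mortality_low_factor: float = 0.85
    mortality_high_factor: float = 1.20
    population_low_factor: float = 0.80
    population_high_factor: float = 1.54
    # satellite
    satellite_noise_cv: float = 0.10
    satellite_background: float = 7.0
    satellite_land_mean: float = 12.0
    # meteorology and boundary inflow
    u_mean: float = 3.0
    u_seasonal_amp: float = 1.2
    v_mean: float = 0.4
    v_seasonal_amp: float = 0.8
    wind_spatial_sd: float = 0.5
    diffusivity: float = 4.0e4
    boundary_inflow: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BOUNDARY_INFLOW))

    def __post_init__(self) -> None:
        for v in self.emission_totals.values():
            if v < 0:
                raise WorldError("emission totals must be >= 0")
        if self.population_total < 0:
            raise WorldError("population total must be >= 0")
        if self.satellite_noise_cv < 0:
            raise WorldError("satellite noise CV must be >= 0")
        for sec, p in self.seasonal_profiles.items():
            if abs(float(np.sum(p)) - 12.0) > 1e-9:
                raise WorldError(f"seasonal profile for {sec!r} must sum to 12")

    def coarse_grid(self) -> GridSpec:
        return regular_grid(self.lat0_edge, self.lon0_edge, self.coarse_dlat,
                            self.coarse_dlon, self.coarse_nlat, self.coarse_nlon)

    def fine_grid(self) -> GridSpec:
        return refine_grid(self.coarse_grid(), self.refinement, self.refinement)


@dataclasses.dataclass
class SyntheticWorld:
    """All inputs of one study: grids, mask, population, health, emissions,
    meteorology, boundary inflow and the satellite exposure estimate."""

    config: WorldConfig
    coarse: GridSpec
    fine: GridSpec
    mask: CountryMask
    population: Field
    mortality: MortalityTable
    rr_curves: RRCurveSet
    emissions: dict[str, EmissionInventory]      # year -> inventory (fine grid)
    wind_u: np.ndarray                           # (12, nlat_c, nlon_c) m/s
    wind_v: np.ndarray
    boundary: dict[str, float]                   # tracer -> µg/m^3 at inflow edges
    satellite: Field                             # fine annual-mean PM2.5 estimate
    truth_annual: Field                          # noise-free annual PM2.5 proxy

    def health_inputs(self) -> HealthInputs:
        cfg = self.config
        return HealthInputs(
            population=self.population, mortality=self.mortality,
            curves=self.rr_curves, mask=self.mask,
            population_bound_factors={"low": cfg.population_low_factor,
                                      "mid": 1.0,
                                      "high": cfg.population_high_factor})

    def ctm_params(self, nonlinear: bool = True, **overrides) -> _ctm.CTMParams:
        kw = dict(wind_u=self.wind_u, wind_v=self.wind_v,
                  diffusivity=self.config.diffusivity, nonlinear_nh3=nonlinear)
        kw.update(overrides)
        return _ctm.CTMParams(**kw)


# ---------------------------------------------------------------------------
# component builders
# ---------------------------------------------------------------------------

def _land_mask(fine: GridSpec, cfg: WorldConfig) -> np.ndarray:
    return np.broadcast_to(fine.lon >= cfg.ocean_lon_max, fine.shape).copy()


def _build_mask(fine: GridSpec, cfg: WorldConfig) -> CountryMask:
    """Contiguous country blocks tiling the land part of the domain."""
    land = _land_mask(fine, cfg)
    n = cfg.n_countries
    if n < 1:
        raise WorldError("need at least one country")
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    land_cols = np.where(land[0])[0]
    col_blocks = np.array_split(land_cols, ncols)
    row_blocks = np.array_split(np.arange(fine.nlat), nrows)
    ids = np.zeros(fine.shape, dtype=np.int64)
    cid = 0
    for cb in col_blocks:
        for rb in row_blocks:
            cid += 1
            if cid > n:
                break
            ids[np.ix_(rb, cb)] = cid
    # leftover blocks (when nrows*ncols > n) fold into the last country
    ids[(ids == 0) & land] = n
    receptor = cfg.receptor_countries
    if receptor is None:
        receptor = tuple(range(1, n + 1))
    if len(receptor) == 0:
        raise WorldError("receptor country set must not be empty")
    return CountryMask(fine, ids, frozenset(receptor))


def _build_population(fine: GridSpec, land: np.ndarray, cfg: WorldConfig) -> Field:
    rng = _rng(cfg.seed, "population")
    dens = np.where(land, 1.0, 0.0)
    land_idx = np.argwhere(land)
    city_rows = land_idx[rng.integers(0, len(land_idx), cfg.n_cities)]
    ii, jj = np.meshgrid(np.arange(fine.nlat), np.arange(fine.nlon), indexing="ij")
    for (ci, cj) in city_rows:
        amp = rng.lognormal(mean=3.0, sigma=1.0)
        sd = rng.uniform(1.5, 4.0)
        dens += amp * np.exp(-0.5 * ((ii - ci) ** 2 + (jj - cj) ** 2) / sd**2) * land
    pop = dens / dens.sum() * cfg.population_total
    return Field(fine, pop, units="persons", name="population")


def _city_centers(fine: GridSpec, land: np.ndarray, cfg: WorldConfig,
                  k: int) -> np.ndarray:
    """Indices of the k most populated fine cells (city proxies)."""
    pop = _build_population(fine, land, cfg).values
    flat = np.argsort(pop.ravel())[::-1][:k]
    return np.column_stack(np.unravel_index(flat, fine.shape))


def _line_cells(a: np.ndarray, b: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise the straight segment a->b onto the grid; returns a 0/1 image."""
    npts = 4 * int(np.hypot(*(b - a))) + 2
    ii = np.clip(np.round(np.linspace(a[0], b[0], npts)).astype(int), 0, shape[0] - 1)
    jj = np.clip(np.round(np.linspace(a[1], b[1], npts)).astype(int), 0, shape[1] - 1)
    img = np.zeros(shape)
    img[ii, jj] = 1.0
    return img


def _point_pattern(rng, land_idx, shape, n_sites) -> np.ndarray:
    pat = np.zeros(shape)
    sites = land_idx[rng.integers(0, len(land_idx), n_sites)]
    amps = rng.lognormal(0.0, 1.0, n_sites)
    for (i, j), a in zip(sites, amps):
        pat[i, j] += a
    return pat


def _block_pattern(rng, land, shape, n_blocks) -> np.ndarray:
    pat = np.zeros(shape)
    for _ in range(n_blocks):
        h = rng.integers(4, 12)
        w = rng.integers(4, 16)
        i0 = rng.integers(0, max(shape[0] - h, 1))
        j0 = rng.integers(0, max(shape[1] - w, 1))
        pat[i0:i0 + h, j0:j0 + w] += rng.uniform(0.5, 1.5)
    return pat * land


def _sector_patterns(fine: GridSpec, land: np.ndarray, pop: np.ndarray,
                     cfg: WorldConfig) -> dict[str, np.ndarray]:
    """Normalised (sum 1) spatial pattern per detailed sector."""
    shape = fine.shape
    land_idx = np.argwhere(land)
    ocean = ~land
    cities = _city_centers(fine, land, cfg, k=10)
    pats: dict[str, np.ndarray] = {}

    rng = _rng(cfg.seed, "pattern-energy")
    pats["energy-power"] = _point_pattern(rng, land_idx, shape, 10)
    pats["energy-other"] = _point_pattern(rng, land_idx, shape, 15)
    rng = _rng(cfg.seed, "pattern-industry")
    pats["industry-combustion"] = _point_pattern(rng, land_idx, shape, 25)
    pats["industry-process"] = _point_pattern(rng, land_idx, shape, 25)

    pats["residential-heating"] = pop * land
    pats["residential-other"] = pop * land
    pats["waste"] = pop * land

    rng = _rng(cfg.seed, "pattern-roads")
    roads = np.zeros(shape)
    for _ in range(12):
        a, b = cities[rng.integers(0, len(cities), 2)]
        roads += _line_cells(a, b, shape)
    roads *= land
    if not roads.any():                    # degenerate tiny domains
        roads = pop * land
    pats["road-transport"] = roads
    pats["ground-transport-other"] = 0.5 * roads / max(roads.sum(), 1e-300) \
        + 0.5 * pop / max(pop.sum(), 1e-300)

    # shipping: corridors in the ocean band
    ship = np.zeros(shape)
    if ocean.any():
        ocean_cols = np.where(ocean[0])[0]
        mid = ocean_cols[len(ocean_cols) // 2]
        ship[:, mid] = 1.0                                  # north-south lane
        ship[shape[0] // 2, ocean_cols] = 1.0               # east-west lane
    else:
        ship = pop.copy()
    pats["international-shipping"] = ship
    coast = np.zeros(shape)
    if ocean.any() and land.any():
        first_land = np.where(land[0])[0][0]
        coast[:, max(first_land - 1, 0):first_land + 1] = 1.0
    pats["domestic-shipping"] = coast if coast.any() else ship

    # aviation: LTO at the biggest cities, cruise corridors across the domain
    lto = np.zeros(shape)
    for (i, j) in cities[:6]:
        lto[i, j] += 1.0
    pats["aviation-lto"] = lto
    rng = _rng(cfg.seed, "pattern-aviation")
    cruise = np.zeros(shape)
    for _ in range(6):
        a = np.array([rng.integers(0, shape[0]), 0])
        b = np.array([rng.integers(0, shape[0]), shape[1] - 1])
        cruise += _line_cells(a, b, shape)
    pats["aviation-cruise"] = cruise

    rng = _rng(cfg.seed, "pattern-agriculture")
    pats["agriculture-livestock"] = _block_pattern(rng, land, shape, 8)
    pats["agriculture-crops"] = _block_pattern(rng, land, shape, 8)
    pats["agriculture-waste-burning"] = _block_pattern(rng, land, shape, 5)

    out = {}
    for sec, p in pats.items():
        s = p.sum()
        out[sec] = p / s if s > 0 else np.where(land, 1.0 / land.sum(), 0.0)
    return out


def _build_inventory(fine: GridSpec, patterns: Mapping[str, np.ndarray],
                     cfg: WorldConfig, year: str,
                     species_factors: Mapping[str, float]) -> EmissionInventory:
    data: dict[tuple[str, str], np.ndarray] = {}
    for (sp, main), total in cfg.emission_totals.items():
        if total == 0:
            continue
        for sec, frac in DETAILED_SPLIT[main].items():
            profile = cfg.seasonal_profiles[sec]
            arr = (total * species_factors.get(sp, 1.0) * frac / 12.0
                   * profile[:, None, None] * patterns[sec][None, :, :])
            key = (sp, sec)
            data[key] = data.get(key, 0) + arr
    return EmissionInventory(fine, data, year=year)


def _build_mortality(mask: CountryMask, fine: GridSpec, cfg: WorldConfig) -> MortalityTable:
    rng = _rng(cfg.seed, "mortality")
    split = {"IHD": 0.45, "stroke": 0.24, "COPD": 0.12, "LRI": 0.08,
             "LC": 0.08, "T2D": 0.03}
    rows = []
    lon2d = np.broadcast_to(fine.lon, fine.shape)
    lo, hi = fine.lon.min(), fine.lon.max()
    for cid in mask.country_ids:
        mean_lon = lon2d[mask.ids == cid].mean()
        t = (mean_lon - lo) / (hi - lo)
        total = cfg.mortality_west_total + t * (cfg.mortality_east_total
                                                - cfg.mortality_west_total)
        for cause in CAUSES:
            mid = total * split[cause] * rng.uniform(0.9, 1.1)
            rows.append({"country_id": int(cid), "cause": cause,
                         "low": mid * cfg.mortality_low_factor, "mid": mid,
                         "high": mid * cfg.mortality_high_factor})
    return MortalityTable(pd.DataFrame(rows))


def _build_rr_curves(cfg: WorldConfig) -> RRCurveSet:
    knots = np.array([cfg.tmrel, 5, 10, 15, 20, 25, 30, 40, 50, 60, 80, 100])
    knot_map, rr = {}, {}
    for cause, (a, b) in cfg.rr_params.items():
        mid = 1.0 + a * np.log1p((knots - cfg.tmrel) / b)
        rr[cause] = {
            "low": 1.0 + cfg.rr_low_factor * (mid - 1.0),
            "mid": mid,
            "high": 1.0 + cfg.rr_high_factor * (mid - 1.0),
        }
        knot_map[cause] = knots.copy()
    return RRCurveSet(knots=knot_map, rr=rr, tmrel=cfg.tmrel)


def _build_met(coarse: GridSpec, cfg: WorldConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = _rng(cfg.seed, "meteorology")
    m = np.arange(12)
    u_season = cfg.u_mean + cfg.u_seasonal_amp * np.cos(2 * np.pi * m / 12)
    v_season = cfg.v_mean + cfg.v_seasonal_amp * np.sin(2 * np.pi * m / 12)
    u_sp = rng.normal(0.0, cfg.wind_spatial_sd, coarse.shape)
    v_sp = rng.normal(0.0, cfg.wind_spatial_sd, coarse.shape)
    u = u_season[:, None, None] + ndimage.gaussian_filter(u_sp, 2.0)[None]
    v = v_season[:, None, None] + ndimage.gaussian_filter(v_sp, 2.0)[None]
    return u, v


def _build_truth(fine: GridSpec, land: np.ndarray, pop: np.ndarray,
                 inv: EmissionInventory, cfg: WorldConfig) -> Field:
    """Noise-free annual-mean PM2.5 proxy: background plus smoothed population
    and emission-density terms, scaled to the configured land mean."""
    emis_density = sum((arr.sum(axis=0) for arr in inv.data.values()),
                       np.zeros(fine.shape))
    emis_density = emis_density / max(emis_density.max(), 1e-300)
    pop_n = pop / max(pop.max(), 1e-300)
    signal = ndimage.gaussian_filter(0.6 * pop_n + 0.4 * emis_density, 3.0)
    # compress the urban peaks (sqrt) so the max/mean contrast stays in the
    # realistic range of annual-mean PM2.5 maps (~2-3x the regional mean)
    signal = np.sqrt(signal / max(signal.max(), 1e-300))
    target = cfg.satellite_land_mean
    mean_land = signal[land].mean() if land.any() else signal.mean()
    scale = (target - cfg.satellite_background) / max(mean_land, 1e-12)
    truth = cfg.satellite_background + scale * signal
    return Field(fine, truth, units="ug m-3", name="pm25_truth")


def generate_satellite(world_or_cfg, truth_annual: Field) -> Field:
    """Satellite estimate = truth x multiplicative log-normal noise with mean 1
    and the configured coefficient of variation (seeded)."""
    cfg = world_or_cfg.config if isinstance(world_or_cfg, SyntheticWorld) else world_or_cfg
    cv = cfg.satellite_noise_cv
    if cv < 0:
        raise WorldError("satellite noise CV must be >= 0")
    if np.any(truth_annual.values < 0):
        raise WorldError("truth field must be >= 0")
    if cv == 0:
        return Field(truth_annual.grid, truth_annual.values.copy(),
                     truth_annual.units, "pm25_satellite")
    rng = _rng(cfg.seed, "satellite")
    sigma2 = np.log1p(cv**2)
    noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2),
                          size=truth_annual.values.shape)
    return Field(truth_annual.grid, truth_annual.values * noise,
                 truth_annual.units, "pm25_satellite")


def scale_inventory(inv: EmissionInventory,
                    factors: Mapping, year: str | None = None) -> EmissionInventory:
    """Multiply emission mass by per-(species, sector) or per-species factors,
    leaving the spatial and seasonal pattern unchanged."""
    return inv.scaled(factors, year=year)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build the complete synthetic world from a configuration (deterministic:
    identical configs produce bit-identical worlds)."""
    coarse = config.coarse_grid()
    fine = config.fine_grid()
    land = _land_mask(fine, config)
    mask = _build_mask(fine, config)
    population = _build_population(fine, land, config)
    patterns = _sector_patterns(fine, land, population.values, config)
    inv2015 = _build_inventory(fine, patterns, config, "2015", {})
    factors_2005 = {sp: 1.0 / (1.0 + dv)
                    for sp, dv in config.species_change_2005.items()}
    inv2005 = inv2015.scaled(factors_2005, year="2005")
    mortality = _build_mortality(mask, fine, config)
    curves = _build_rr_curves(config)
    wind_u, wind_v = _build_met(coarse, config)
    truth = _build_truth(fine, land, population.values, inv2015, config)
    satellite = generate_satellite(config, truth)
    return SyntheticWorld(
        config=config, coarse=coarse, fine=fine, mask=mask,
        population=population, mortality=mortality, rr_curves=curves,
        emissions={"2015": inv2015, "2005": inv2005},
        wind_u=wind_u, wind_v=wind_v,
        boundary=dict(config.boundary_inflow),
        satellite=satellite, truth_annual=truth,
    )


# ---------------------------------------------------------------------------
# world persistence (one directory per world)
# ---------------------------------------------------------------------------

from .grids import (field_from_netcdf, field_to_netcdf,  # noqa: E402
                    inventory_from_netcdf, inventory_to_netcdf)


def _config_to_dict(cfg: WorldConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["seasonal_profiles"] = {k: [float(x) for x in v]
                              for k, v in d["seasonal_profiles"].items()}
    d["emission_totals"] = {f"{sp}|{main}": float(v)
                            for (sp, main), v in d["emission_totals"].items()}
    d["rr_params"] = {k: [float(a), float(b)] for k, (a, b) in d["rr_params"].items()}
    if d["receptor_countries"] is not None:
        d["receptor_countries"] = [int(x) for x in d["receptor_countries"]]
    return d


def config_from_dict(d: Mapping) -> WorldConfig:
    d = dict(d)
    if "emission_totals" in d:
        d["emission_totals"] = {tuple(k.split("|")): float(v)
                                for k, v in d["emission_totals"].items()}
    if "seasonal_profiles" in d:
        d["seasonal_profiles"] = {k: np.asarray(v, dtype=float)
                                  for k, v in d["seasonal_profiles"].items()}
    if "rr_params" in d:
        d["rr_params"] = {k: (float(v[0]), float(v[1]))
                          for k, v in d["rr_params"].items()}
    if d.get("receptor_countries") is not None:
        d["receptor_countries"] = tuple(int(x) for x in d["receptor_countries"])
    return WorldConfig(**d)


def save_world(world: SyntheticWorld, out_dir) -> None:
    """Write every world component in the shared gridded/CSV formats plus a
    manifest of seeds and totals (deterministic byte-for-byte)."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = world.config
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=True)
    # gridded fields
    field_to_netcdf(world.population, out / "population.nc")
    field_to_netcdf(world.satellite, out / "satellite.nc")
    field_to_netcdf(world.truth_annual, out / "truth_annual.nc")
    ids = Field(world.fine, world.mask.ids.astype(float), units="country_id",
                name="country_ids")
    field_to_netcdf(ids, out / "mask.nc")
    met = xr.Dataset(coords={"month": np.arange(1, 13), "lat": world.coarse.lat,
                             "lon": world.coarse.lon})
    met["wind_u"] = xr.DataArray(world.wind_u, dims=("month", "lat", "lon"))
    met["wind_u"].attrs["units"] = "m s-1"
    met["wind_v"] = xr.DataArray(world.wind_v, dims=("month", "lat", "lon"))
    met["wind_v"].attrs["units"] = "m s-1"
    met.to_netcdf(out / "met.nc", engine="scipy")
    for year, inv in sorted(world.emissions.items()):
        inventory_to_netcdf(inv, out / f"emissions_{year}.nc")
    # tables
    world.mortality.table.sort_values(["country_id", "cause"]).to_csv(
        out / "mortality.csv", index=False)
    rows = []
    for cause in world.rr_curves.causes():
        k = world.rr_curves.knots[cause]
        r = world.rr_curves.rr[cause]
        for i in range(len(k)):
            rows.append({"cause": cause, "exposure": k[i], "rr_low": r["low"][i],
                         "rr_mid": r["mid"][i], "rr_high": r["high"][i]})
    pd.DataFrame(rows).to_csv(out / "rr_curves.csv", index=False)
    with open(out / "boundary.json", "w") as fh:
        json.dump(world.boundary, fh, sort_keys=True, indent=1)
    receptor = sorted(world.mask.receptor_ids)
    manifest = {
        "seed": cfg.seed,
        "receptor_countries": receptor,
        "population_total": float(world.population.values.sum()),
        "emission_totals_kg": {
            year: {sp: inv.total(species=sp) for sp in inv.species}
            for year, inv in sorted(world.emissions.items())
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)


def load_world(in_dir) -> SyntheticWorld:
    """Rebuild a SyntheticWorld from a directory written by save_world."""
    src = pathlib.Path(in_dir)
    with open(src / "config.yaml") as fh:
        cfg = config_from_dict(yaml.safe_load(fh))
    population = field_from_netcdf(src / "population.nc")
    satellite = field_from_netcdf(src / "satellite.nc")
    truth = field_from_netcdf(src / "truth_annual.nc")
    ids = field_from_netcdf(src / "mask.nc").values.astype(np.int64)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    fine = population.grid
    mask = CountryMask(fine, ids, frozenset(manifest["receptor_countries"]))
    with xr.open_dataset(src / "met.nc", engine="scipy") as met:
        met = met.load()
    emissions = {}
    for path in sorted(src.glob("emissions_*.nc")):
        inv = inventory_from_netcdf(path)
        emissions[inv.year] = inv
    mortality = MortalityTable(pd.read_csv(src / "mortality.csv"))
    rr_df = pd.read_csv(src / "rr_curves.csv")
    knots, rr = {}, {}
    for cause, sub in rr_df.groupby("cause", sort=False):
        sub = sub.sort_values("exposure")
        knots[cause] = sub["exposure"].to_numpy()
        rr[cause] = {"low": sub["rr_low"].to_numpy(),
                     "mid": sub["rr_mid"].to_numpy(),
                     "high": sub["rr_high"].to_numpy()}
    curves = RRCurveSet(knots=knots, rr=rr, tmrel=cfg.tmrel)
    with open(src / "boundary.json") as fh:
        boundary = json.load(fh)
    return SyntheticWorld(
        config=cfg, coarse=cfg.coarse_grid(), fine=fine, mask=mask,
        population=population, mortality=mortality, rr_curves=curves,
        emissions=emissions, wind_u=met["wind_u"].values,
        wind_v=met["wind_v"].values, boundary=boundary,
        satellite=satellite, truth_annual=truth,
    )
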