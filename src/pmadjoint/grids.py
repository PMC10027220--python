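"""Regular lat-lon grids, gridded fields, country masks and emission inventories.

Everything downstream (transport, health impact, attribution) shares the
containers defined here.  Grids are cell-centred and regular, with half-open
cell bounds ``[center - step/2, center + step/2)``; a fine grid must nest in a
coarse grid by an integer refinement factor in each direction.  Relative cell
areas are proportional to ``cos(latitude)`` and are used for all intensive
(area-weighted) aggregation; physical cell areas in m^2 are used by the
transport model to convert emitted mass to concentration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_M = 6.371e6

#: the six emitted anthropogenic species carried by the inventory
SPECIES = ("NOx", "NH3", "SO2", "OC", "BC", "SOAP")

#: eight main anthropogenic sectors
MAIN_SECTORS = (
    "shipping",
    "aviation",
    "energy",
    "industry",
    "ground_transport",
    "waste",
    "agricultural",
    "residential",
)

#: sixteen detailed sectors, each nested in exactly one main sector
DEFAULT_SECTOR_TO_MAIN: dict[str, str] = {
    "energy-power": "energy",
    "energy-other": "energy",
    "industry-combustion": "industry",
    "industry-process": "industry",
    "road-transport": "ground_transport",
    "ground-transport-other": "ground_transport",
    "domestic-shipping": "shipping",
    "international-shipping": "shipping",
    "aviation-lto": "aviation",
    "aviation-cruise": "aviation",
    "residential-heating": "residential",
    "residential-other": "residential",
    "waste": "waste",
    "agriculture-livestock": "agricultural",
    "agriculture-crops": "agricultural",
    "agriculture-waste-burning": "agricultural",
}

DETAILED_SECTORS = tuple(DEFAULT_SECTOR_TO_MAIN)

_TOL = 1e-9


class GridError(ValueError):
    """Raised for inconsistent grids (non-uniform steps, failed nesting...)."""


class GridIOError(ValueError):
    """Raised when a gridded file lacks required coordinates or metadata."""


def _uniform_step(centers: np.ndarray, what: str) -> float:
    if centers.ndim != 1 or centers.size < 2:
        raise GridError(f"{what} centers must be a 1-D array of length >= 2")
    steps = np.diff(centers)
    if np.any(steps <= 0):
        raise GridError(f"{what} centers must be strictly ascending")
    if np.max(np.abs(steps - steps[0])) > _TOL:
        raise GridError(f"{what} step is not uniform within {_TOL}")
    return float(steps[0])


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """A regular cell-centred latitude-longitude grid."""

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        _uniform_step(lat, "lat")
        _uniform_step(lon, "lon")

    # -- basic geometry ----------------------------------------------------
    @property
    def nlat(self) -> int:
        return self.lat.size

    @property
    def nlon(self) -> int:
        return self.lon.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def ncell(self) -> int:
        return self.nlat * self.nlon

    @property
    def dlat(self) -> float:
        return float(self.lat[1] - self.lat[0])

    @property
    def dlon(self) -> float:
        return float(self.lon[1] - self.lon[0])

    @property
    def lat_edges(self) -> np.ndarray:
        return np.concatenate([self.lat - self.dlat / 2, [self.lat[-1] + self.dlat / 2]])

    @property
    def lon_edges(self) -> np.ndarray:
        return np.concatenate([self.lon - self.dlon / 2, [self.lon[-1] + self.dlon / 2]])

    def area_weights(self) -> np.ndarray:
        """Relative cell areas, shape (nlat, nlon), mean exactly 1 per grid."""
        w = np.cos(np.deg2rad(self.lat))
        if np.any(w <= 0):
            raise GridError("area weights require |latitude| < 90")
        w = w / w.mean()
        return np.broadcast_to(w[:, None], self.shape).copy()

    def cell_area_m2(self) -> np.ndarray:
        """Physical cell areas in m^2, shape (nlat, nlon)."""
        a = (
            EARTH_RADIUS_M**2
            * np.deg2rad(self.dlat)
            * np.deg2rad(self.dlon)
            * np.cos(np.deg2rad(self.lat))
        )
        return np.broadcast_to(a[:, None], self.shape).copy()

    # -- nesting -----------------------------------------------------------
    def refinement_from(self, fine: "GridSpec") -> tuple[int, int]:
        """Integer (lat, lon) refinement factors of ``fine`` nested in ``self``.

        Raises :class:`GridError` if the fine grid does not nest exactly
        (steps not an integer divisor, or edges misaligned).
        """
        rlat = self.dlat / fine.dlat
        rlon = self.dlon / fine.dlon
        if abs(rlat - round(rlat)) > 1e-6 or abs(rlon - round(rlon)) > 1e-6:
            raise GridError("fine grid step does not divide coarse grid step")
        rlat, rlon = int(round(rlat)), int(round(rlon))
        if fine.nlat != self.nlat * rlat or fine.nlon != self.nlon * rlon:
            raise GridError("grid extents do not match an exact nesting")
        if (
            abs(fine.lat_edges[0] - self.lat_edges[0]) > 1e-6
            or abs(fine.lon_edges[0] - self.lon_edges[0]) > 1e-6
        ):
            raise GridError("fine grid edges are not aligned with the coarse grid")
        return rlat, rlon

    def equals(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat, atol=_TOL)
            and np.allclose(self.lon, other.lon, atol=_TOL)
        )


def regular_grid(lat0_edge: float, lon0_edge: float, dlat: float, dlon: float,
                 nlat: int, nlon: int) -> GridSpec:
    """Convenience constructor from the south-west domain edge."""
    lat = lat0_edge + dlat / 2 + dlat * np.arange(nlat)
    lon = lon0_edge + dlon / 2 + dlon * np.arange(nlon)
    return GridSpec(lat=lat, lon=lon)


def refine_grid(coarse: GridSpec, rlat: int, rlon: int) -> GridSpec:
    """The fine grid obtained by splitting every coarse cell rlat x rlon."""
    return regular_grid(
        coarse.lat_edges[0], coarse.lon_edges[0],
        coarse.dlat / rlat, coarse.dlon / rlon,
        coarse.nlat * rlat, coarse.nlon * rlon,
    )


@dataclasses.dataclass
class Field:
    """A gridded quantity: values over (..., lat, lon) plus units."""

    grid: GridSpec
    values: np.ndarray
    units: str = ""
    name: str = "field"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[-2:] != self.grid.shape:
            raise GridError(
                f"field shape {self.values.shape} does not end in grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GridError("field contains non-finite values")

    def copy(self) -> "Field":
        return Field(self.grid, self.values.copy(), self.units, self.name)


@dataclasses.dataclass
class CountryMask:
    """Integer country id per cell; id 0 means unassigned (ocean/outside)."""

    grid: GridSpec
    ids: np.ndarray
    receptor_ids: frozenset[int]
    names: dict[int, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.ids.shape != self.grid.shape:
            raise GridError("mask shape does not match grid")
        if np.any(self.ids < 0):
            raise GridError("country ids must be >= 0")
        self.receptor_ids = frozenset(int(i) for i in self.receptor_ids)
        if 0 in self.receptor_ids:
            raise GridError("the unassigned id 0 cannot be receptor-flagged")

    @property
    def country_ids(self) -> np.ndarray:
        ids = np.unique(self.ids)
        return ids[ids > 0]

    def receptor_mask(self) -> np.ndarray:
        """Boolean (nlat, nlon) array: cell lies in a receptor-flagged country."""
        return np.isin(self.ids, sorted(self.receptor_ids))

    def name_of(self, cid: int) -> str:
        if cid == 0:
            return "unassigned"
        return self.names.get(cid, f"country-{cid:02d}")


# ---------------------------------------------------------------------------
# regridding
# ---------------------------------------------------------------------------

def _blocked(values: np.ndarray, coarse: GridSpec, rlat: int, rlon: int) -> np.ndarray:
    """Reshape (..., nlat_f, nlon_f) into (..., nlat_c, rlat, nlon_c, rlon)."""
    lead = values.shape[:-2]
    return values.reshape(lead + (coarse.nlat, rlat, coarse.nlon, rlon))


def aggregate_fine_to_coarse(field: Field, coarse: GridSpec, how: str = "mean") -> Field:
    """Aggregate an intensive (``how='mean'``, area-weighted) or extensive
    (``how='sum'``) fine field onto the coarse grid it nests in."""
    rlat, rlon = coarse.refinement_from(field.grid)
    blocks = _blocked(field.values, coarse, rlat, rlon)
    if how == "sum":
        out = blocks.sum(axis=(-3, -1))
    elif how == "mean":
        w = field.grid.area_weights()[:, 0]  # per fine row
        wb = w.reshape(coarse.nlat, rlat)[None, :, :, None, None]
        wb = np.broadcast_to(wb[0], (coarse.nlat, rlat, coarse.nlon, rlon))
        out = (blocks * wb).sum(axis=(-3, -1)) / wb.sum(axis=(-3, -1))
    else:
        raise ValueError(f"unknown aggregation {how!r}")
    return Field(coarse, out, field.units, field.name)


def disaggregate_coarse_to_fine(field: Field, fine: GridSpec,
                                pattern: Field | None = None) -> Field:
    """Spread a coarse field onto a nested fine grid.

    Without a pattern every fine child copies its parent value.  With a
    nonnegative pattern, each child gets ``parent * pattern / wmean(pattern
    over siblings)`` so the per-parent area-weighted mean is conserved.
    Parents whose pattern sums to zero fall back to the uniform copy (a
    warning is issued).
    """
    rlat, rlon = field.grid.refinement_from(fine)
    lead = field.values.shape[:-2]
    rep = np.repeat(np.repeat(field.values, rlat, axis=-2), rlon, axis=-1)
    if pattern is None:
        return Field(fine, rep, field.units, field.name)
    if not pattern.grid.equals(fine):
        raise GridError("pattern must live on the target fine grid")
    if np.any(pattern.values < 0):
        raise GridError("pattern must be nonnegative")
    weights = downscale_weights(pattern, field.grid)
    return Field(fine, rep * weights, field.units, field.name)


def downscale_weights(pattern: Field, coarse: GridSpec) -> np.ndarray:
    """Per-fine-cell multiplicative weights with area-weighted mean 1 in every
    parent; parents with an all-zero pattern get uniform weights of 1."""
    mean = aggregate_fine_to_coarse(pattern, coarse, how="mean").values
    rlat, rlon = coarse.refinement_from(pattern.grid)
    mean_rep = np.repeat(np.repeat(mean, rlat, axis=-2), rlon, axis=-1)
    weights = np.ones_like(pattern.values)
    ok = mean_rep > 0
    if not ok.all():
        warnings.warn("pattern sums to zero within some parents; "
                      "falling back to uniform disaggregation there")
    np.divide(pattern.values, mean_rep, out=weights, where=ok)
    return weights


def country_aggregate(field: Field, mask: CountryMask, statistic: str = "sum",
                      weights: Field | None = None) -> pd.DataFrame:
    """Aggregate a 2-D field by country id.

    ``statistic`` is one of ``sum`` (plain cell sum), ``mean`` (area-weighted
    mean) or ``popweighted`` (weighted mean with the supplied weights field,
    e.g. population).  Cells with id 0 are reported as ``unassigned``.
    """
    if not field.grid.equals(mask.grid):
        raise GridError("field and mask must share a grid")
    if field.values.ndim != 2:
        raise GridError("country_aggregate expects a 2-D field")
    ids = mask.ids.ravel()
    vals = field.values.ravel()
    nbin = int(ids.max()) + 1
    if statistic == "sum":
        agg = np.bincount(ids, weights=vals, minlength=nbin)
    elif statistic == "mean":
        w = field.grid.area_weights().ravel()
        agg = np.bincount(ids, weights=vals * w, minlength=nbin)
        denom = np.bincount(ids, weights=w, minlength=nbin)
        agg = np.divide(agg, denom, out=np.full(nbin, np.nan), where=denom > 0)
    elif statistic == "popweighted":
        if weights is None or not weights.grid.equals(field.grid):
            raise GridError("popweighted statistic needs a weights field on the same grid")
        w = weights.values.ravel()
        agg = np.bincount(ids, weights=vals * w, minlength=nbin)
        denom = np.bincount(ids, weights=w, minlength=nbin)
        agg = np.divide(agg, denom, out=np.full(nbin, np.nan), where=denom > 0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    present = sorted(set(np.unique(ids)))
    rows = [
        {"country_id": int(cid), "country": mask.name_of(int(cid)), "value": agg[int(cid)]}
        for cid in present
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# emission inventory
# ---------------------------------------------------------------------------

class EmissionInventory:
    """Monthly gridded emission mass per (species, detailed sector).

    Data are stored as a mapping ``(species, sector) -> array (12, nlat, nlon)``
    in kg per month; pairs not present are implicitly zero.  The detailed
    sector -> main sector map is total and fixed for the inventory.
    """

    def __init__(self, grid: GridSpec, data: Mapping[tuple[str, str], np.ndarray],
                 year: str = "2015",
                 species: tuple[str, ...] = SPECIES,
                 sectors: tuple[str, ...] = DETAILED_SECTORS,
                 sector_to_main: Mapping[str, str] | None = None) -> None:
        self.grid = grid
        self.year = str(year)
        self.species = tuple(species)
        self.sectors = tuple(sectors)
        self.sector_to_main = dict(sector_to_main or DEFAULT_SECTOR_TO_MAIN)
        missing = set(self.sectors) - set(self.sector_to_main)
        if missing:
            raise GridError(f"sector->main map is not total; missing {sorted(missing)}")
        self.data: dict[tuple[str, str], np.ndarray] = {}
        for (sp, sec), arr in data.items():
            if sp not in self.species:
                raise GridError(f"unknown species {sp!r}")
            if sec not in self.sectors:
                raise GridError(f"unknown sector {sec!r}")
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (12,) + grid.shape:
                raise GridError(f"emission array for {(sp, sec)} has shape {arr.shape}")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise GridError(f"emission mass for {(sp, sec)} must be finite and >= 0")
            self.data[(sp, sec)] = arr

    # -- access ------------------------------------------------------------
    def mass(self, species: str, sector: str) -> np.ndarray:
        """(12, nlat, nlon) kg/month; zeros for absent pairs."""
        arr = self.data.get((species, sector))
        if arr is None:
            return np.zeros((12,) + self.grid.shape)
        return arr

    def per_species(self) -> dict[str, np.ndarray]:
        """Sector-summed monthly mass per species."""
        out = {sp: np.zeros((12,) + self.grid.shape) for sp in self.species}
        for (sp, _), arr in self.data.items():
            out[sp] += arr
        return out

    def total(self, species: str | None = None, sector: str | None = None,
              main_sector: str | None = None) -> float:
        tot = 0.0
        for (sp, sec), arr in self.data.items():
            if species is not None and sp != species:
                continue
            if sector is not None and sec != sector:
                continue
            if main_sector is not None and self.sector_to_main[sec] != main_sector:
                continue
            tot += float(arr.sum())
        return tot

    # -- transforms ----------------------------------------------------------
    def scaled(self, factors: Mapping[tuple[str, str], float] | Mapping[str, float],
               year: str | None = None) -> "EmissionInventory":
        """Multiply masses by per-(species, sector) or per-species factors."""
        keyed: dict[tuple[str, str], float] = {}
        for key, f in factors.items():
            if f < 0:
                raise GridError("scaling factors must be >= 0")
            if isinstance(key, str):
                if key not in self.species:
                    raise GridError(f"unknown species {key!r} in factors")
                for sec in self.sectors:
                    keyed[(key, sec)] = float(f)
            else:
                sp, sec = key
                if sp not in self.species or sec not in self.sectors:
                    raise GridError(f"unknown (species, sector) key {key!r} in factors")
                keyed[(sp, sec)] = float(f)
        data = {
            pair: arr * keyed.get(pair, 1.0)
            for pair, arr in self.data.items()
        }
        return EmissionInventory(self.grid, data, year or self.year, self.species,
                                 self.sectors, self.sector_to_main)

    def aggregated_to(self, coarse: GridSpec) -> "EmissionInventory":
        """Mass-conserving (sum) aggregation of every pair onto a coarse grid."""
        rlat, rlon = coarse.refinement_from(self.grid)
        data = {
            pair: _blocked(arr, coarse, rlat, rlon).sum(axis=(-3, -1))
            for pair, arr in self.data.items()
        }
        return EmissionInventory(coarse, data, self.year, self.species,
                                 self.sectors, self.sector_to_main)


# ---------------------------------------------------------------------------
# gridded file I/O (CF-style, NetCDF3 via the scipy backend)
# ---------------------------------------------------------------------------

_MONTHS = np.arange(1, 13)


def field_to_netcdf(field: Field, path) -> None:
    nd = field.values.ndim
    if nd == 2:
        dims = ("lat", "lon")
    elif nd == 3:
        dims = ("month", "lat", "lon")
    else:
        raise GridIOError(f"cannot serialise a {nd}-D field")
    coords = {"lat": field.grid.lat, "lon": field.grid.lon}
    if nd == 3:
        coords["month"] = np.arange(1, field.values.shape[0] + 1)
    da = xr.DataArray(field.values, dims=dims, coords=coords, name=field.name or "field")
    da.attrs["units"] = field.units
    da.coords["lat"].attrs["units"] = "degrees_north"
    da.coords["lon"].attrs["units"] = "degrees_east"
    da.to_dataset().to_netcdf(path, engine="scipy")


def field_from_netcdf(path, name: str | None = None) -> Field:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for coord in ("lat", "lon"):
        if coord not in ds.coords:
            raise GridIOError(f"gridded file is missing the {coord!r} coordinate variable")
    if name is None:
        candidates = [v for v in ds.data_vars if {"lat", "lon"} <= set(ds[v].dims)]
        if len(candidates) != 1:
            raise GridIOError("cannot infer the field variable; pass name=")
        name = candidates[0]
    da = ds[name]
    if "units" not in da.attrs:
        raise GridIOError(f"variable {name!r} is missing a units attribute")
    order = [d for d in ("month", "lat", "lon") if d in da.dims]
    da = da.transpose(*order)
    grid = GridSpec(lat=ds["lat"].values, lon=ds["lon"].values)
    return Field(grid, da.values, units=str(da.attrs["units"]), name=name)


def inventory_to_netcdf(inv: EmissionInventory, path) -> None:
    coords = {"month": _MONTHS, "lat": inv.grid.lat, "lon": inv.grid.lon}
    ds = xr.Dataset(coords=coords)
    for k, (sp, sec) in enumerate(sorted(inv.data)):
        var = f"emis_{k:03d}"
        ds[var] = xr.DataArray(inv.data[(sp, sec)], dims=("month", "lat", "lon"))
        ds[var].attrs.update(units="kg", species=sp, sector=sec)
    ds.attrs["year"] = inv.year
    ds.attrs["species"] = json.dumps(list(inv.species))
    ds.attrs["sectors"] = json.dumps(list(inv.sectors))
    ds.attrs["sector_to_main"] = json.dumps(inv.sector_to_main)
    ds.coords["lat"].attrs["units"] = "degrees_north"
    ds.coords["lon"].attrs["units"] = "degrees_east"
    ds.to_netcdf(path, engine="scipy")


def inventory_from_netcdf(path) -> EmissionInventory:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for coord in ("month", "lat", "lon"):
        if coord not in ds.coords:
            raise GridIOError(f"inventory file is missing the {coord!r} coordinate variable")
    for attr in ("year", "species", "sectors", "sector_to_main"):
        if attr not in ds.attrs:
            raise GridIOError(f"inventory file is missing the {attr!r} attribute")
    grid = GridSpec(lat=ds["lat"].values, lon=ds["lon"].values)
    data: dict[tuple[str, str], np.ndarray] = {}
    for var in ds.data_vars:
        da = ds[var]
        if "species" not in da.attrs or "sector" not in da.attrs:
            raise GridIOError(f"variable {var!r} is missing species/sector attributes")
        if "units" not in da.attrs:
            raise GridIOError(f"variable {var!r} is missing a units attribute")
        da = da.transpose("month", "lat", "lon")
        data[(str(da.attrs["species"]), str(da.attrs["sector"]))] = da.values
    return EmissionInventory(
        grid, data, year=str(ds.attrs["year"]),
        species=tuple(json.loads(ds.attrs["species"])),
        sectors=tuple(json.loads(ds.attrs["sectors"])),
        sector_to_main=json.loads(ds.attrs["sector_to_main"]),
    )
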