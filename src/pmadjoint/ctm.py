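"""Toy monthly chemical-transport model on the coarse grid.

Each month is an independent steady state of a conservative flux-form balance

    0 = advection(c) + diffusion(c) - k c + q + b,

with first-order upwind advection, a 5-point diffusion stencil, first-order
deposition, an emission source q (precursor mass converted to aerosol with a
fixed yield at the source), and advective inflow b of boundary concentrations
at the domain edges.  The discrete operator is assembled as an explicit sparse
matrix, so the adjoint model is literally its transpose.

Transported tracers are the six aerosol pathways (sulfate from SO2, a nitrate
potential from NOx, primary OC and BC, SOA from SOAP), gaseous ammonia from
NH3 emissions, and fine dust which enters only through the boundary.  PM2.5
components are diagnosed from the tracers; in the nonlinear mode nitrate is
limited by the ammonia left after sulfate neutralisation through a smooth
(differentiable) min.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .grids import EmissionInventory, Field, GridSpec

#: PM2.5 components summed into total PM2.5
PM25_COMPONENTS = ("sulfate", "nitrate", "ammonium", "OC", "BC", "SOA", "dust")

#: transported tracers (nh3 is gaseous and not part of PM2.5 itself)
TRACERS = ("sulfate", "nitrate", "nh3", "OC", "BC", "SOA", "dust")

#: emitted species -> transported tracer receiving the converted mass
SPECIES_TO_TRACER = {
    "SO2": "sulfate",
    "NOx": "nitrate",
    "NH3": "nh3",
    "OC": "OC",
    "BC": "BC",
    "SOAP": "SOA",
}

#: mass of NH3 consumed per mass of sulfate neutralised (2 mol NH3 / mol SO4)
NH3_PER_SULFATE = 2.0 * 17.0 / 96.0

#: days per month of a non-leap year
MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

DEFAULT_DEPOSITION_PER_DAY = {
    "sulfate": 0.18, "nitrate": 0.22, "nh3": 0.45,
    "OC": 0.20, "BC": 0.16, "SOA": 0.20, "dust": 0.40,
}

#: precursor -> aerosol mass yield applied at the source
DEFAULT_YIELDS = {"SO2": 0.60, "NOx": 0.40, "NH3": 1.0, "OC": 1.0, "BC": 1.0, "SOAP": 0.18}


class CTMError(ValueError):
    pass


@dataclasses.dataclass
class CTMParams:
    """Physics of the toy transport model (all monthly fields on the coarse grid)."""

    wind_u: np.ndarray                  # (12, nlat, nlon) m/s, eastward
    wind_v: np.ndarray                  # (12, nlat, nlon) m/s, northward
    diffusivity: float = 4.0e4          # m^2/s horizontal eddy diffusivity
    deposition_per_day: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DEPOSITION_PER_DAY))
    yields: dict[str, float] = dataclasses.field(default_factory=lambda: dict(DEFAULT_YIELDS))
    ammonium_yield: float = 0.35        # aerosol ammonium mass per gaseous NH3 mass
    nonlinear_nh3: bool = True
    smin_sharpness: float = 0.5         # µg/m^3, smoothing scale of the nitrate limit
    nitrate_limit_yield: float = 1.8    # nitrate mass formable per free-NH3 mass
    mixing_height: float = 1000.0       # m, depth of the surface mixing volume
    substeps: int = 4096                # explicit-step count used for the CFL guard

    def __post_init__(self) -> None:
        self.wind_u = np.asarray(self.wind_u, dtype=float)
        self.wind_v = np.asarray(self.wind_v, dtype=float)
        for tr in TRACERS:
            if self.deposition_per_day.get(tr, 0.0) <= 0:
                raise CTMError(f"deposition rate for {tr!r} must be > 0")
        if any(y < 0 for y in self.yields.values()):
            raise CTMError("species yields must be >= 0")
        if self.mixing_height <= 0 or self.diffusivity < 0:
            raise CTMError("mixing_height must be > 0 and diffusivity >= 0")


@dataclasses.dataclass
class ConcentrationSet:
    """Monthly surface concentrations per PM2.5 component, µg/m^3, coarse grid."""

    grid: GridSpec
    components: dict[str, np.ndarray]          # name -> (12, nlat, nlon)
    tracers: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.components.items():
            if np.any(arr < -1e-12):
                raise CTMError(f"negative concentration in component {name!r}")


# ---------------------------------------------------------------------------
# discrete operators
# ---------------------------------------------------------------------------

def build_transport_operator(grid: GridSpec, u: np.ndarray, v: np.ndarray,
                             diffusivity: float) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the conservative transport tendency operator for one month.

    Returns ``(T, inflow)`` where ``T`` (ncell x ncell, 1/s) holds upwind
    advection, 5-point diffusion (no-flux at edges for diffusion) and advective
    outflow at the domain edges, and ``inflow`` (ncell, 1/s) is the coefficient
    multiplying the edge boundary concentration of a tracer.  Face velocities
    are the mean of the two adjacent cell values.
    """
    nlat, nlon = grid.shape
    n = grid.ncell
    area = grid.cell_area_m2()
    H = 1.0  # mixing height cancels between volume and face area for horizontal flow
    vol = area * H
    dx_row = EARTH_R_DX(grid)          # (nlat,) east-west cell extent, m
    dy = float(np.deg2rad(grid.dlat) * 6.371e6)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    inflow = np.zeros((nlat, nlon))

    def idx(i, j):
        return i * nlon + j

    ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")

    def add(r, c, v_):
        rows.append(np.asarray(r).ravel())
        cols.append(np.asarray(c).ravel())
        vals.append(np.asarray(v_).ravel())

    # --- zonal faces between (i, j) and (i, j+1) ---------------------------
    uf = 0.5 * (u[:, :-1] + u[:, 1:])                       # (nlat, nlon-1)
    a_face = (dy * H) * np.ones_like(uf)                    # face area per unit H
    il, jl = ii[:, :-1], jj[:, :-1]
    ir, jr = ii[:, 1:], jj[:, 1:]
    vl, vr = vol[:, :-1], vol[:, 1:]
    # advective flux uf * A * c_donor: donor loses coef/vol_donor, receiver
    # gains coef/vol_receiver (conservative by construction)
    up_pos = uf >= 0
    coef = np.abs(uf) * a_face
    don_i = np.where(up_pos, il, ir)
    don_j = np.where(up_pos, jl, jr)
    rec_i = np.where(up_pos, ir, il)
    rec_j = np.where(up_pos, jr, jl)
    vdon = vol[don_i, don_j]
    vrec = vol[rec_i, rec_j]
    add(idx(don_i, don_j), idx(don_i, don_j), -coef / vdon)
    add(idx(rec_i, rec_j), idx(don_i, don_j), coef / vrec)
    # diffusive flux K * A * (c_r - c_l) / dx(row)
    dcoef = diffusivity * a_face / dx_row[:, None]
    add(idx(il, jl), idx(il, jl), -dcoef / vl)
    add(idx(il, jl), idx(ir, jr), dcoef / vl)
    add(idx(ir, jr), idx(ir, jr), -dcoef / vr)
    add(idx(ir, jr), idx(il, jl), dcoef / vr)

    # --- meridional faces between (i, j) and (i+1, j) ----------------------
    vf = 0.5 * (v[:-1, :] + v[1:, :])                       # (nlat-1, nlon)
    # face length is the east-west extent at the shared edge (use mean of rows)
    face_len = 0.5 * (dx_row[:-1] + dx_row[1:])
    a_face = (face_len[:, None] * H) * np.ones_like(vf)
    is_, js_ = ii[:-1, :], jj[:-1, :]
    in_, jn_ = ii[1:, :], jj[1:, :]
    up_pos = vf >= 0                                         # northward -> donor south
    don_i = np.where(up_pos, is_, in_)
    don_j = np.where(up_pos, js_, jn_)
    rec_i = np.where(up_pos, in_, is_)
    rec_j = np.where(up_pos, jn_, js_)
    coef = np.abs(vf) * a_face
    add(idx(don_i, don_j), idx(don_i, don_j), -coef / vol[don_i, don_j])
    add(idx(rec_i, rec_j), idx(don_i, don_j), coef / vol[rec_i, rec_j])
    dcoef = diffusivity * a_face / dy
    vs, vn = vol[:-1, :], vol[1:, :]
    add(idx(is_, js_), idx(is_, js_), -dcoef / vs)
    add(idx(is_, js_), idx(in_, jn_), dcoef / vs)
    add(idx(in_, jn_), idx(in_, jn_), -dcoef / vn)
    add(idx(in_, jn_), idx(is_, js_), dcoef / vn)

    # --- domain edges: advective inflow/outflow ----------------------------
    # west edge (j = 0): u > 0 brings boundary air in, u < 0 flows out
    for edge, wind, axis_idx, face_area in (
        ("west", u[:, 0], (np.arange(nlat), np.zeros(nlat, int)), dy * H * np.ones(nlat)),
        ("east", u[:, -1], (np.arange(nlat), np.full(nlat, nlon - 1)), dy * H * np.ones(nlat)),
        ("south", v[0, :], (np.zeros(nlon, int), np.arange(nlon)), dx_row[0] * H * np.ones(nlon)),
        ("north", v[-1, :], (np.full(nlon, nlat - 1), np.arange(nlon)), dx_row[-1] * H * np.ones(nlon)),
    ):
        i_e, j_e = axis_idx
        sign_in = 1.0 if edge in ("west", "south") else -1.0
        w = wind * sign_in                                   # > 0 means inflow
        coef = np.abs(wind) * face_area / vol[i_e, j_e]
        infl = w > 0
        inflow[i_e[infl], j_e[infl]] += coef[infl]
        out = ~infl
        add(idx(i_e[out], j_e[out]), idx(i_e[out], j_e[out]), -coef[out])

    T = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    T.sum_duplicates()
    return T, inflow.ravel()


def EARTH_R_DX(grid: GridSpec) -> np.ndarray:
    """East-west cell extent per latitude row, metres."""
    return np.deg2rad(grid.dlon) * 6.371e6 * np.cos(np.deg2rad(grid.lat))


def check_cfl(grid: GridSpec, params: CTMParams, month: int) -> float:
    """CFL number of one explicit substep of the configured discretisation."""
    dx = EARTH_R_DX(grid).min()
    dy = np.deg2rad(grid.dlat) * 6.371e6
    u = np.abs(params.wind_u[month]).max()
    v = np.abs(params.wind_v[month]).max()
    k = max(params.deposition_per_day.values()) / 86400.0
    rate = u / dx + v / dy + 2 * params.diffusivity * (1 / dx**2 + 1 / dy**2) + k
    dt = MONTH_DAYS[month] * 86400.0 / params.substeps
    return float(rate * dt)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def emission_to_source(mass_month: np.ndarray, grid: GridSpec, month: int,
                       mixing_height: float) -> np.ndarray:
    """kg/month in a cell -> µg m^-3 s^-1 volume source (flattened)."""
    vol = grid.cell_area_m2() * mixing_height
    seconds = MONTH_DAYS[month] * 86400.0
    return (mass_month * 1e9 / (vol * seconds)).ravel()


class MonthlySolver:
    """Caches the LU factorisations (k I - T) per (month, tracer)."""

    def __init__(self, grid: GridSpec, params: CTMParams) -> None:
        self.grid = grid
        self.params = params
        self.ops: list[tuple[sp.csr_matrix, np.ndarray]] = []
        for m in range(12):
            cfl = check_cfl(grid, params, m)
            if cfl >= 1.0:
                raise CTMError(
                    f"CFL number {cfl:.2f} >= 1 in month {m + 1}; "
                    "increase params.substeps")
            self.ops.append(build_transport_operator(
                grid, params.wind_u[m], params.wind_v[m], params.diffusivity))
        self._lu: dict[tuple[int, str], object] = {}
        self._lu_T: dict[tuple[int, str], object] = {}

    def system_matrix(self, month: int, tracer: str) -> sp.csc_matrix:
        T, _ = self.ops[month]
        k = self.params.deposition_per_day[tracer] / 86400.0
        return (sp.identity(self.grid.ncell, format="csc") * k - T).tocsc()

    def solve(self, month: int, tracer: str, rhs: np.ndarray) -> np.ndarray:
        key = (month, tracer)
        if key not in self._lu:
            self._lu[key] = sp.linalg.splu(self.system_matrix(month, tracer))
        return self._lu[key].solve(rhs)

    def solve_adjoint(self, month: int, tracer: str, rhs: np.ndarray) -> np.ndarray:
        key = (month, tracer)
        if key not in self._lu_T:
            self._lu_T[key] = sp.linalg.splu(self.system_matrix(month, tracer).T.tocsc())
        return self._lu_T[key].solve(rhs)

    def inflow(self, month: int) -> np.ndarray:
        return self.ops[month][1]


def solve_tracers(solver: MonthlySolver, emissions_per_species: Mapping[str, np.ndarray],
                  boundary: Mapping[str, float],
                  boundary_scale: float = 1.0) -> dict[str, np.ndarray]:
    """Steady-state tracer concentrations per month, µg/m^3.

    ``emissions_per_species`` maps species -> (12, nlat, nlon) kg/month on the
    coarse grid; ``boundary`` maps tracer -> edge concentration (µg/m^3).
    """
    grid, params = solver.grid, solver.params
    out = {tr: np.zeros((12,) + grid.shape) for tr in TRACERS}
    sources = {tr: np.zeros((12, grid.ncell)) for tr in TRACERS}
    for spp, mass in emissions_per_species.items():
        tr = SPECIES_TO_TRACER[spp]
        y = params.yields[spp]
        for m in range(12):
            sources[tr][m] += y * emission_to_source(mass[m], grid, m, params.mixing_height)
    for tr in TRACERS:
        cb = boundary_scale * float(boundary.get(tr, 0.0))
        for m in range(12):
            rhs = sources[tr][m] + cb * solver.inflow(m)
            if not rhs.any():
                continue
            out[tr][m] = solver.solve(m, tr, rhs).reshape(grid.shape)
    return out


# -- nonlinear nitrate limitation -------------------------------------------

def _softplus(x: np.ndarray, tau: float) -> np.ndarray:
    return tau * np.logaddexp(0.0, x / tau)


def _smin(a: np.ndarray, b: np.ndarray, tau: float) -> np.ndarray:
    return -tau * np.logaddexp(-a / tau, -b / tau)


def apply_nh3_limitation(sulfate: np.ndarray, nitrate_potential: np.ndarray,
                         nh3_available: np.ndarray, *, limit_yield: float = 1.8,
                         sharpness: float = 0.5) -> np.ndarray:
    """Ammonia-limited nitrate: smooth min of the NOx-derived potential and the
    nitrate formable from the NH3 left after sulfate neutralisation, clamped at
    zero (the smooth min dips slightly negative when both arguments vanish)."""
    free = _softplus(nh3_available - NH3_PER_SULFATE * sulfate, sharpness)
    return np.maximum(_smin(nitrate_potential, limit_yield * free, sharpness), 0.0)


def nh3_limitation_partials(sulfate: np.ndarray, nitrate_potential: np.ndarray,
                            nh3_available: np.ndarray, *, limit_yield: float = 1.8,
                            sharpness: float = 0.5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise partial derivatives of the limited nitrate w.r.t.
    (nitrate_potential, nh3_available, sulfate)."""
    tau = sharpness
    x = nh3_available - NH3_PER_SULFATE * sulfate
    sig = 1.0 / (1.0 + np.exp(-x / tau))          # d softplus / dx
    free = _softplus(x, tau)
    cap = limit_yield * free
    # softmin weights
    lo = np.minimum(nitrate_potential, cap)
    ea = np.exp(-(nitrate_potential - lo) / tau)
    eb = np.exp(-(cap - lo) / tau)
    wa = ea / (ea + eb)
    wb = eb / (ea + eb)
    active = (_smin(nitrate_potential, cap, tau) > 0.0)   # clamp region: zero slope
    d_pot = wa * active
    d_nh3 = wb * limit_yield * sig * active
    d_sulf = -wb * limit_yield * sig * NH3_PER_SULFATE * active
    return d_pot, d_nh3, d_sulf


def diagnose_components(tracers: Mapping[str, np.ndarray], params: CTMParams) -> dict[str, np.ndarray]:
    """PM2.5 components from transported tracers (applies the NH3 coupling)."""
    comps: dict[str, np.ndarray] = {}
    comps["sulfate"] = tracers["sulfate"]
    comps["ammonium"] = params.ammonium_yield * tracers["nh3"]
    if params.nonlinear_nh3:
        comps["nitrate"] = apply_nh3_limitation(
            tracers["sulfate"], tracers["nitrate"], tracers["nh3"],
            limit_yield=params.nitrate_limit_yield, sharpness=params.smin_sharpness)
    else:
        comps["nitrate"] = tracers["nitrate"]
    for name in ("OC", "BC", "SOA", "dust"):
        comps[name] = tracers[name]
    return comps


def run_forward(emissions: EmissionInventory, params: CTMParams,
                boundary: Mapping[str, float], coarse: GridSpec,
                boundary_scale: float = 1.0,
                solver: MonthlySolver | None = None) -> ConcentrationSet:
    """Run the toy CTM for one year.

    The inventory is aggregated (mass-conserving) to the coarse grid if it
    lives on a finer one.  Returns monthly concentrations per PM2.5 component.
    """
    if not emissions.grid.equals(coarse):
        emissions = emissions.aggregated_to(coarse)
    solver = solver or MonthlySolver(coarse, params)
    tracers = solve_tracers(solver, emissions.per_species(), boundary, boundary_scale)
    comps = diagnose_components(tracers, params)
    return ConcentrationSet(coarse, comps, tracers)


def compute_pm25(conc: ConcentrationSet) -> tuple[Field, Field]:
    """Total PM2.5 as the sum of the seven components.

    Returns ``(monthly, annual)`` fields; the annual field is the unweighted
    mean of the 12 monthly fields.
    """
    missing = [c for c in PM25_COMPONENTS if c not in conc.components]
    if missing:
        raise CTMError(f"missing PM2.5 components: {missing}")
    monthly = sum(conc.components[c] for c in PM25_COMPONENTS)
    annual = monthly.mean(axis=0)
    return (Field(conc.grid, monthly, "ug m-3", "pm25_monthly"),
            Field(conc.grid, annual, "ug m-3", "pm25_annual"))
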