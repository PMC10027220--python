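"""End-to-end orchestration: forward run, satellite fusion, cost function,
adjoint sweep and finite-difference verification.

A :class:`Pipeline` fixes the study conditions (world, chemistry mode, health
response, inventory year) and caches the base run: transport LU factors,
tracer fields, the satellite correction ratios and downscaling weights.  All
perturbed evaluations (gradient checks, boundary perturbations, alternative
inventories) reuse the frozen BASE correction ratios, since re-deriving the
satellite rescaling would cancel the perturbation being measured.

Two canonical modes:

* ``Pipeline(world)`` - nonlinear chemistry (NH3-limited nitrate) and the GBD
  PAF response; the reporting configuration.
* ``Pipeline.linear(world)`` - linear chemistry and the linearised secant
  response, making J an exactly linear functional of (emissions, boundary);
  the configuration in which first-order attribution is exact.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np

from . import ctm as _ctm
from .adjoint import SensitivityField, monthly_exposure_chain
from .ctm import (MONTH_DAYS, TRACERS, CTMParams, MonthlySolver,
                  diagnose_components, nh3_limitation_partials, solve_tracers)
from .fusion import rescale_ratios
from .grids import EmissionInventory, Field, aggregate_fine_to_coarse, downscale_weights
from .health import (CostFunctionResult, HealthInputs, cost_function,
                     cost_gradient, paf_slopes)


@dataclasses.dataclass
class BaseRun:
    """Cached artefacts of the base (unperturbed) forward run."""

    solver: MonthlySolver
    emissions_coarse: dict[str, np.ndarray]     # species -> (12, nlat, nlon) kg
    tracers: dict[str, np.ndarray]
    components: dict[str, np.ndarray]
    pm25_monthly: np.ndarray                    # (12, nlat, nlon) coarse
    ratios: np.ndarray                          # satellite correction per coarse cell
    sat_coarse_annual: np.ndarray
    weights: np.ndarray                         # fine downscaling weights
    exposure_annual_fine: np.ndarray
    cost: CostFunctionResult


class Pipeline:
    def __init__(self, world, params: CTMParams | None = None,
                 health: HealthInputs | None = None, year: str = "2015",
                 nonlinear_chemistry: bool = True, response: str = "paf",
                 reference_exposure: float = 25.0,
                 boundary_scale: float = 1.0) -> None:
        self.world = world
        self.params = params or world.ctm_params(nonlinear=nonlinear_chemistry)
        self.health = health or world.health_inputs()
        self.year = year
        self.response = response
        self.boundary_scale_base = float(boundary_scale)
        self.slopes = {
            b: paf_slopes(self.health.curves, reference_exposure, b)
            for b in ("low", "mid", "high")
        } if response == "linear" else {b: None for b in ("low", "mid", "high")}
        self._base: BaseRun | None = None

    @classmethod
    def linear(cls, world, boundary_scale: float = 1.0, **kw) -> "Pipeline":
        """Linear-chemistry, linear-response pipeline (exact first order)."""
        kw.setdefault("nonlinear_chemistry", False)
        kw.setdefault("response", "linear")
        return cls(world, boundary_scale=boundary_scale, **kw)

    # -- base run -----------------------------------------------------------
    @property
    def inventory(self) -> EmissionInventory:
        return self.world.emissions[self.year]

    def base(self) -> BaseRun:
        if self._base is None:
            self._base = self._run_base()
        return self._base

    def _run_base(self) -> BaseRun:
        coarse = self.world.coarse
        solver = MonthlySolver(coarse, self.params)
        emis = self.inventory.aggregated_to(coarse).per_species()
        tracers = solve_tracers(solver, emis, self.world.boundary,
                                self.boundary_scale_base)
        comps = diagnose_components(tracers, self.params)
        pm25 = sum(comps[c] for c in _ctm.PM25_COMPONENTS)
        model_field = Field(coarse, pm25, "ug m-3", "pm25_monthly")
        ratios = rescale_ratios(model_field, self.world.satellite)
        sat_coarse = aggregate_fine_to_coarse(self.world.satellite, coarse).values
        weights = downscale_weights(self.world.satellite, coarse)
        annual_fine = self._fuse_annual(pm25, ratios, sat_coarse, weights)
        cost = cost_function(annual_fine, self.health, "mid", self.response,
                             self.slopes["mid"])
        return BaseRun(solver, emis, tracers, comps, pm25, ratios, sat_coarse,
                       weights, annual_fine, cost)

    def _fuse_annual(self, pm25_monthly: np.ndarray, ratios: np.ndarray,
                     sat_coarse: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Annual-mean fine exposure from monthly coarse PM2.5 with frozen
        correction ratios and downscaling weights."""
        annual = pm25_monthly.mean(axis=0)
        ok = np.isfinite(ratios)
        corrected = np.where(ok, annual * np.where(ok, ratios, 1.0), sat_coarse)
        rlat, rlon = self.world.coarse.refinement_from(self.world.fine)
        rep = np.repeat(np.repeat(corrected, rlat, axis=0), rlon, axis=1)
        return rep * weights

    # -- perturbed evaluations (frozen ratios) -------------------------------
    def cost_from_tracers(self, tracers: dict[str, np.ndarray],
                          bound: str = "mid") -> CostFunctionResult:
        base = self.base()
        comps = diagnose_components(tracers, self.params)
        pm25 = sum(comps[c] for c in _ctm.PM25_COMPONENTS)
        annual_fine = self._fuse_annual(pm25, base.ratios, base.sat_coarse_annual,
                                        base.weights)
        return cost_function(annual_fine, self.health, bound, self.response,
                             self.slopes[bound])

    def evaluate(self, emissions: EmissionInventory | None = None,
                 boundary_scale: float | None = None,
                 bound: str = "mid") -> CostFunctionResult:
        """J under an alternative inventory and/or scaled boundary inflow,
        holding the BASE satellite correction frozen."""
        base = self.base()
        if emissions is None and boundary_scale is None:
            return self.cost_from_tracers(base.tracers, bound)
        emis = (emissions.aggregated_to(self.world.coarse).per_species()
                if emissions is not None else base.emissions_coarse)
        bscale = self.boundary_scale_base if boundary_scale is None else boundary_scale
        tracers = solve_tracers(base.solver, emis, self.world.boundary, bscale)
        return self.cost_from_tracers(tracers, bound)

    def exposure_annual_fine(self, tracers: dict[str, np.ndarray] | None = None) -> np.ndarray:
        base = self.base()
        if tracers is None:
            return base.exposure_annual_fine
        comps = diagnose_components(tracers, self.params)
        pm25 = sum(comps[c] for c in _ctm.PM25_COMPONENTS)
        return self._fuse_annual(pm25, base.ratios, base.sat_coarse_annual,
                                 base.weights)

    # -- adjoint --------------------------------------------------------------
    def _tracer_seeds(self, g_months: np.ndarray) -> dict[str, np.ndarray]:
        """dJ/d(tracer) per month, (12, nlat, nlon), from dJ/d(PM2.5) per
        month through the pointwise chemistry diagnosis (linearised about the
        base tracers)."""
        base = self.base()
        p = self.params
        seeds = {tr: g_months.copy() for tr in TRACERS}
        if p.nonlinear_nh3:
            d_pot, d_nh3, d_sulf = nh3_limitation_partials(
                base.tracers["sulfate"], base.tracers["nitrate"], base.tracers["nh3"],
                limit_yield=p.nitrate_limit_yield, sharpness=p.smin_sharpness)
            seeds["nitrate"] = g_months * d_pot
            seeds["nh3"] = g_months * (p.ammonium_yield + d_nh3)
            seeds["sulfate"] = g_months * (1.0 + d_sulf)
        else:
            seeds["nh3"] = g_months * p.ammonium_yield
        return seeds

    def _annual_gradient_coarse(self) -> np.ndarray:
        """dJ/d(annual coarse PM2.5), through health, downscale and rescale."""
        base = self.base()
        g_fine = cost_gradient(base.exposure_annual_fine, self.health, "mid",
                               self.response, self.slopes["mid"])
        wg = Field(self.world.fine, base.weights * g_fine)
        rlat, rlon = self.world.coarse.refinement_from(self.world.fine)
        lead = wg.values.reshape(self.world.coarse.nlat, rlat,
                                 self.world.coarse.nlon, rlon)
        child_sum = lead.sum(axis=(1, 3))
        ok = np.isfinite(base.ratios)
        return np.where(ok, np.where(ok, base.ratios, 0.0) * child_sum, 0.0)

    def adjoint(self) -> SensitivityField:
        """Reverse sweep: dJ/dE per (species, month, coarse cell), deaths/kg."""
        base = self.base()
        coarse = self.world.coarse
        g_annual = self._annual_gradient_coarse()
        g_months = monthly_exposure_chain(g_annual)
        vol = coarse.cell_area_m2() * self.params.mixing_height
        lam = {sp: np.zeros((12,) + coarse.shape) for sp in self.inventory.species}
        psi_cache: dict[tuple[int, str], np.ndarray] = {}
        seeds = self._tracer_seeds(g_months)
        for m in range(12):
            for tr in TRACERS:
                psi = base.solver.solve_adjoint(m, tr, seeds[tr][m].ravel())
                psi_cache[(m, tr)] = psi.reshape(coarse.shape)
        for sp in self.inventory.species:
            tr = _ctm.SPECIES_TO_TRACER[sp]
            y = self.params.yields[sp]
            for m in range(12):
                seconds = MONTH_DAYS[m] * 86400.0
                lam[sp][m] = y * psi_cache[(m, tr)] * 1e9 / (vol * seconds)
        meta = {
            "cost_hash": hashlib.sha256(
                f"{self.response}:{self.year}:{sorted(self.health.mask.receptor_ids)}"
                .encode()).hexdigest()[:16],
            "linearization": "base-2015" if self.params.nonlinear_nh3 else "linear",
        }
        return SensitivityField(coarse, lam, meta)

    def adjoint_fine(self) -> SensitivityField:
        return self.adjoint().to_fine(self.world.fine)

    # -- verification ----------------------------------------------------------
    def gradient_check(self, n_samples: int = 30, rel_step: float = 0.005,
                       seed: int = 0, tolerance: float | None = None) -> dict:
        """Central finite differences of J vs adjoint sensitivities at
        ``n_samples`` random (species, month, fine cell) entries with E > 0.

        Entries are drawn with probability proportional to their emitted
        mass: a central difference of J (a sum of ~1e5 deaths) cannot resolve
        the effect of a near-massless entry above floating-point cancellation,
        so the check verifies the gradient where the emissions -- and hence
        the contributions -- actually are.  The perturbed J reuses the cached
        LU factors (only the perturbed tracer/month is re-solved) and the
        frozen satellite correction.  Returns max/median relative error and
        the per-sample table.
        """
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        base = self.base()
        coarse, fine = self.world.coarse, self.world.fine
        rlat, rlon = coarse.refinement_from(fine)
        lam_fine = self.adjoint_fine()
        rng = np.random.default_rng(seed)
        per_species = self.inventory.per_species()
        species_list = list(per_species)
        masses = np.array([per_species[sp].sum() for sp in species_list])
        results = []
        vol = coarse.cell_area_m2() * self.params.mixing_height
        degenerate = masses.sum() == 0            # zero-emission base state
        for _ in range(n_samples):
            if degenerate:
                sp = species_list[rng.integers(len(species_list))]
                arr = per_species[sp]
                flat = int(rng.integers(arr.size))
            else:
                sp = species_list[rng.choice(len(species_list), p=masses / masses.sum())]
                arr = per_species[sp]
                flat = rng.choice(arr.size, p=(arr / arr.sum()).ravel())
            m, fi, fj = np.unravel_index(flat, arr.shape)
            m, fi, fj = int(m), int(fi), int(fj)
            tr = _ctm.SPECIES_TO_TRACER[sp]
            e0 = per_species[sp][m, fi, fj]
            delta = rel_step * e0 if e0 > 0 else rel_step
            ci, cj = fi // rlat, fj // rlon
            seconds = MONTH_DAYS[m] * 86400.0
            rhs = np.zeros(coarse.ncell)
            rhs[ci * coarse.nlon + cj] = (self.params.yields[sp] * delta * 1e9
                                          / (vol[ci, cj] * seconds))
            dc = base.solver.solve(m, tr, rhs).reshape(coarse.shape)
            tr_plus = {t: v for t, v in base.tracers.items()}
            tr_minus = {t: v for t, v in base.tracers.items()}
            tr_plus[tr] = base.tracers[tr].copy()
            tr_plus[tr][m] += dc
            tr_minus[tr] = base.tracers[tr].copy()
            tr_minus[tr][m] -= dc
            # difference the per-cell fields before summing: differencing two
            # ~1e5 totals would lose ~eps*J of signal to cancellation
            cell_plus = self.cost_from_tracers(tr_plus).per_cell
            cell_minus = self.cost_from_tracers(tr_minus).per_cell
            fd = float((cell_plus - cell_minus).sum()) / (2.0 * delta)
            lam = lam_fine.values[sp][m, fi, fj]
            denom = max(abs(fd), abs(lam), 1e-300)
            results.append({"species": sp, "month": m + 1, "cell": (fi, fj),
                            "fd": fd, "adjoint": lam,
                            "rel_error": abs(fd - lam) / denom})
        errs = np.array([r["rel_error"] for r in results])
        if tolerance is None:
            tolerance = 1e-6 if not self.params.nonlinear_nh3 else 1e-3
        report = {"max_rel_error": float(errs.max()),
                  "median_rel_error": float(np.median(errs)),
                  "n_samples": len(results), "tolerance": float(tolerance),
                  "samples": results}
        report["passed"] = bool(report["max_rel_error"] < tolerance)
        return report
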