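"""Adjoint correctness: operator transposes, closed-form chain rule,
finite-difference verification, monthly exposure chain."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pmadjoint import Pipeline
from pmadjoint.adjoint import monthly_exposure_chain
from pmadjoint.ctm import CTMParams, MonthlySolver, MONTH_DAYS, TRACERS
from pmadjoint.grids import (CountryMask, Field, aggregate_fine_to_coarse,
                             downscale_weights, refine_grid, regular_grid)
from pmadjoint.health import HealthInputs, MortalityTable, RRCurveSet, paf_slopes
from pmadjoint.synthetic import SyntheticWorld, WorldConfig, generate_world
from conftest import tiny_config


class TestOperatorTransposes:
    """<A u, w> = <u, A^T w> for every linear building block."""

    def test_transport_matrix_all_months(self, tiny_world, rng):
        params = tiny_world.ctm_params(nonlinear=False)
        solver = MonthlySolver(tiny_world.coarse, params)
        n = tiny_world.coarse.ncell
        for m in range(12):
            T, _ = solver.ops[m]
            u, w = rng.standard_normal(n), rng.standard_normal(n)
            lhs, rhs = np.dot(T @ u, w), np.dot(u, T.T @ w)
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)

    def test_steady_state_solves_all_months(self, tiny_world, rng):
        """The solve and the adjoint solve are mutual transposes:
        <M^-1 u, w> = <u, M^-T w>."""
        params = tiny_world.ctm_params(nonlinear=False)
        solver = MonthlySolver(tiny_world.coarse, params)
        n = tiny_world.coarse.ncell
        for m in range(12):
            for tr in ("sulfate", "dust"):
                u, w = rng.standard_normal(n), rng.standard_normal(n)
                lhs = np.dot(solver.solve(m, tr, u), w)
                rhs = np.dot(u, solver.solve_adjoint(m, tr, w))
                assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_aggregation_vs_replication(self, rng):
        """Area-weighted fine->coarse averaging is adjoint to weighted
        replication (the regridding pair used by the exposure chain)."""
        coarse = regular_grid(40.0, 0.0, 1.0, 1.0, 4, 5)
        fine = refine_grid(coarse, 2, 2)
        wfine = fine.area_weights()
        u = rng.standard_normal(fine.shape)
        w = rng.standard_normal(coarse.shape)
        Au = aggregate_fine_to_coarse(Field(fine, u), coarse).values
        # adjoint spreads each parent's seed by its children's weight fractions
        sumw = wfine.reshape(coarse.nlat, 2, coarse.nlon, 2).sum(axis=(1, 3))
        Atw = (np.repeat(np.repeat(w / sumw, 2, axis=0), 2, axis=1)) * wfine
        assert np.sum(Au * w) == pytest.approx(np.sum(u * Atw), rel=1e-10)

    def test_downscale_weights_chain(self, tiny_world, rng):
        """Fine exposure = weights x replicate(coarse); its adjoint is the
        child sum of weights x seed, as used by the reverse sweep."""
        coarse, fine = tiny_world.coarse, tiny_world.fine
        r = tiny_world.config.refinement
        wts = downscale_weights(tiny_world.satellite, coarse)
        u = rng.standard_normal(coarse.shape)
        w = rng.standard_normal(fine.shape)
        fwd = wts * np.repeat(np.repeat(u, r, axis=0), r, axis=1)
        adj = (wts * w).reshape(coarse.nlat, r, coarse.nlon, r).sum(axis=(1, 3))
        assert np.sum(fwd * w) == pytest.approx(np.sum(u * adj), rel=1e-10)


class TestClosedBoxChainRule:
    def test_single_cell_sensitivity_matches_hand_chain(self):
        """Closed box (no wind/diffusion), one populated cell, linear
        response: lambda[m] = s_h x (1/12) x 1e9 / (k V tau_m)."""
        coarse = regular_grid(45.0, 10.0, 1.0, 1.0, 2, 2)
        grid = coarse  # refinement 1: fine == coarse
        mass = np.zeros((12,) + grid.shape)
        mass[:, 0, 0] = 2.0e5
        from pmadjoint.grids import EmissionInventory
        inv = EmissionInventory(grid, {("OC", "residential-heating"): mass})
        pop = np.zeros(grid.shape)
        pop[0, 0] = 1e5
        mask = CountryMask(grid, np.ones(grid.shape, dtype=int), frozenset({1}))
        mort = MortalityTable(pd.DataFrame(
            [{"country_id": 1, "cause": "IHD", "low": 500.0, "mid": 500.0,
              "high": 500.0}]))
        knots = np.array([0.0, 1.0, 200.0])
        rrv = np.array([1.0, 1.002, 1.4])
        curves = RRCurveSet(knots={"IHD": knots},
                            rr={"IHD": {"low": rrv, "mid": rrv, "high": rrv}},
                            tmrel=0.0)
        params = CTMParams(wind_u=np.zeros((12,) + grid.shape),
                           wind_v=np.zeros((12,) + grid.shape),
                           diffusivity=0.0, nonlinear_nh3=False)
        k = params.deposition_per_day["OC"] / 86400.0
        vol = grid.cell_area_m2()[0, 0] * params.mixing_height
        conc = mass[0, 0, 0] * 1e9 / (k * vol * MONTH_DAYS * 86400.0)
        annual = conc.mean()
        sat = Field(grid, np.full(grid.shape, annual), "ug m-3")  # ratio = 1
        cfg = WorldConfig(seed=0, coarse_nlat=2, coarse_nlon=2, refinement=1,
                          lat0_edge=44.5, lon0_edge=9.5, coarse_dlat=1.0,
                          coarse_dlon=1.0, n_countries=1, ocean_lon_max=-999.0,
                          tmrel=0.0)
        world = SyntheticWorld(
            config=cfg, coarse=coarse, fine=grid, mask=mask,
            population=Field(grid, pop, "persons"), mortality=mort,
            rr_curves=curves, emissions={"2015": inv},
            wind_u=params.wind_u, wind_v=params.wind_v, boundary={},
            satellite=sat, truth_annual=sat)
        health = HealthInputs(population=world.population, mortality=mort,
                              curves=curves, mask=mask)
        pipe = Pipeline(world, params=params, health=health,
                        nonlinear_chemistry=False, response="linear",
                        reference_exposure=annual)
        lam = pipe.adjoint()
        s_h = 1e5 * 500.0 / 1e5 * paf_slopes(curves, annual)["IHD"]
        for m in range(12):
            expected = s_h / 12.0 * 1e9 / (k * vol * MONTH_DAYS[m] * 86400.0)
            assert lam.values["OC"][m, 0, 0] == pytest.approx(expected, rel=1e-9)
        assert lam.values["OC"][:, 1, 1].max() == 0.0   # unpopulated cells

    def test_zero_population_gives_zero_sensitivities(self):
        world = generate_world(tiny_config(seed=21))
        world.population.values[:] = 0.0
        pipe = Pipeline(world)
        lam = pipe.adjoint()
        for sp, arr in lam.values.items():
            assert not arr.any(), sp


class TestFiniteDifference:
    def test_linear_mode_gradient(self, tiny_world):
        chk = Pipeline.linear(tiny_world).gradient_check(n_samples=12, seed=3)
        assert chk["max_rel_error"] < 1e-6

    def test_nonlinear_mode_gradient(self, tiny_world):
        chk = Pipeline(tiny_world).gradient_check(n_samples=12, seed=3)
        assert chk["max_rel_error"] < 1e-3

    def test_deterministic_given_seed(self, tiny_world):
        pipe = Pipeline.linear(tiny_world)
        a = pipe.gradient_check(n_samples=5, seed=9)
        b = pipe.gradient_check(n_samples=5, seed=9)
        assert a["max_rel_error"] == b["max_rel_error"]

    def test_zero_emission_base_reports_finite_errors(self):
        cfg = tiny_config(seed=13)
        cfg.emission_totals = {k: 0.0 for k in cfg.emission_totals}
        world = generate_world(cfg)
        chk = Pipeline.linear(world).gradient_check(n_samples=5, seed=1)
        assert np.isfinite(chk["max_rel_error"])
        assert chk["n_samples"] == 5


class TestMonthlyExposureChain:
    def test_each_month_is_one_twelfth(self):
        g = np.full((3, 4), 12.0)
        months = monthly_exposure_chain(g)
        assert months.shape == (12, 3, 4)
        assert np.allclose(months, 1.0)

    def test_months_sum_back_to_annual(self, rng):
        g = rng.standard_normal((5, 6))
        np.testing.assert_allclose(monthly_exposure_chain(g).sum(axis=0), g,
                                   rtol=1e-12)

    def test_matches_single_month_finite_difference(self, tiny_world):
        """Perturbing one month's PM2.5 by dc changes J by (dJ/dC_ann)/12 dc."""
        pipe = Pipeline.linear(tiny_world)
        base = pipe.base()
        tr = {t: v for t, v in base.tracers.items()}
        tr["OC"] = base.tracers["OC"].copy()
        dc = 1e-3
        ci, cj = 4, 6
        tr["OC"][2, ci, cj] += dc
        dj = pipe.cost_from_tracers(tr).J - base.cost.J
        g_ann = pipe._annual_gradient_coarse()
        assert dj / dc == pytest.approx(g_ann[ci, cj] / 12.0, rel=1e-6, abs=1e-12)


class TestSensitivitySign:
    def test_linear_mode_sensitivities_nonnegative(self, tiny_world):
        """More emission cannot reduce deaths when the response is
        nondecreasing: every linear-mode sensitivity is >= 0."""
        lam = Pipeline.linear(tiny_world).adjoint()
        for sp, arr in lam.values.items():
            assert arr.min() >= 0.0, sp
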