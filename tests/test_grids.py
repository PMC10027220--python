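"""Grid geometry, regridding, country aggregation and gridded I/O."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from pmadjoint.grids import (CountryMask, EmissionInventory, Field, GridError,
                             GridIOError, GridSpec, aggregate_fine_to_coarse,
                             country_aggregate, disaggregate_coarse_to_fine,
                             field_from_netcdf, field_to_netcdf,
                             inventory_from_netcdf, inventory_to_netcdf,
                             refine_grid, regular_grid)


@pytest.fixture()
def grids():
    coarse = regular_grid(35.0, -10.0, 2.0, 2.5, 5, 5)
    fine = refine_grid(coarse, 4, 4)
    return coarse, fine


def loop_area_weighted_mean(values, fine, coarse, rlat, rlon):
    w = np.cos(np.deg2rad(fine.lat))
    out = np.zeros(coarse.shape)
    for ci in range(coarse.nlat):
        for cj in range(coarse.nlon):
            num = den = 0.0
            for di in range(rlat):
                for dj in range(rlon):
                    fi, fj = ci * rlat + di, cj * rlon + dj
                    num += values[fi, fj] * w[fi]
                    den += w[fi]
            out[ci, cj] = num / den
    return out


class TestGridSpec:
    def test_rejects_nonuniform_steps(self):
        with pytest.raises(GridError, match="uniform"):
            GridSpec(lat=np.array([0.0, 1.0, 2.5]), lon=np.array([0.0, 1.0]))

    def test_rejects_descending_centers(self):
        with pytest.raises(GridError, match="ascending"):
            GridSpec(lat=np.array([2.0, 1.0]), lon=np.array([0.0, 1.0]))

    def test_area_weights_positive_and_row_shared(self, grids):
        coarse, _ = grids
        w = coarse.area_weights()
        assert np.all(w > 0)
        assert np.allclose(w, w[:, :1])          # constant along a row
        assert w.mean() == pytest.approx(1.0)

    def test_non_nesting_grids_rejected(self, grids):
        coarse, _ = grids
        other = regular_grid(35.3, -10.0, 2.0 / 3, 2.5 / 3, 15, 15)
        with pytest.raises(GridError):
            coarse.refinement_from(other)


class TestRegridding:
    def test_constant_field_aggregates_to_constant(self, grids):
        coarse, fine = grids
        agg = aggregate_fine_to_coarse(Field(fine, np.full(fine.shape, 7.0)), coarse)
        assert np.allclose(agg.values, 7.0)

    def test_aggregate_matches_loop_oracle(self, grids, rng):
        coarse, fine = grids
        vals = rng.random(fine.shape)
        agg = aggregate_fine_to_coarse(Field(fine, vals), coarse)
        expected = loop_area_weighted_mean(vals, fine, coarse, 4, 4)
        np.testing.assert_allclose(agg.values, expected, atol=1e-12)

    def test_disaggregate_without_pattern_replicates(self, grids):
        coarse, fine = grids
        out = disaggregate_coarse_to_fine(Field(coarse, np.full(coarse.shape, 3.0)), fine)
        assert np.allclose(out.values, 3.0)

    def test_uniform_pattern_equals_no_pattern(self, grids, rng):
        coarse, fine = grids
        f = Field(coarse, rng.random(coarse.shape))
        plain = disaggregate_coarse_to_fine(f, fine)
        patterned = disaggregate_coarse_to_fine(
            f, fine, Field(fine, np.full(fine.shape, 4.2)))
        np.testing.assert_allclose(plain.values, patterned.values, atol=1e-12)

    def test_patterned_disaggregation_conserves_parent_mean(self, grids, rng):
        coarse, fine = grids
        f = Field(coarse, rng.random(coarse.shape))
        pattern = Field(fine, rng.random(fine.shape) + 0.01)
        out = disaggregate_coarse_to_fine(f, fine, pattern)
        back = aggregate_fine_to_coarse(out, coarse)
        np.testing.assert_allclose(back.values, f.values, atol=1e-12)

    def test_zero_pattern_parent_falls_back_uniform(self, grids, rng):
        coarse, fine = grids
        f = Field(coarse, np.ones(coarse.shape))
        pat = rng.random(fine.shape) + 0.1
        pat[:4, :4] = 0.0                         # kill one parent's pattern
        with pytest.warns(UserWarning, match="uniform"):
            out = disaggregate_coarse_to_fine(f, fine, Field(fine, pat))
        assert np.allclose(out.values[:4, :4], 1.0)

    def test_aggregate_of_disaggregate_is_identity(self, grids, rng):
        coarse, fine = grids
        f = Field(coarse, rng.random(coarse.shape))
        roundtrip = aggregate_fine_to_coarse(
            disaggregate_coarse_to_fine(f, fine), coarse)
        np.testing.assert_allclose(roundtrip.values, f.values, rtol=0, atol=1e-15)


class TestCountryAggregate:
    @pytest.fixture()
    def mask(self, grids):
        _, fine = grids
        ids = np.zeros(fine.shape, dtype=int)
        ids[:, 4:10] = 1
        ids[:, 10:] = 2
        return CountryMask(fine, ids, receptor_ids=frozenset({1, 2}))

    def test_indicator_field_counts_cells(self, grids, mask):
        _, fine = grids
        indicator = Field(fine, (mask.ids == 1).astype(float))
        tab = country_aggregate(indicator, mask, "sum").set_index("country_id")
        assert tab.loc[1, "value"] == (mask.ids == 1).sum()
        assert tab.loc[2, "value"] == 0.0

    def test_sum_partition_closure(self, grids, mask, rng):
        _, fine = grids
        f = Field(fine, rng.random(fine.shape))
        tab = country_aggregate(f, mask, "sum")
        assert tab["value"].sum() == pytest.approx(f.values.sum(), rel=1e-9)

    def test_popweighted_uniform_concentration(self, grids, mask, rng):
        _, fine = grids
        conc = Field(fine, np.full(fine.shape, 8.5))
        pop = Field(fine, rng.random(fine.shape) + 0.1)
        tab = country_aggregate(conc, mask, "popweighted", weights=pop)
        assert np.allclose(tab["value"], 8.5)

    def test_grid_mismatch_rejected(self, grids, mask):
        coarse, _ = grids
        with pytest.raises(GridError):
            country_aggregate(Field(coarse, np.zeros(coarse.shape)), mask)

    def test_additive_under_mask_refinement(self, grids, mask, rng):
        """Splitting a country into two ids preserves the pair's total."""
        _, fine = grids
        f = Field(fine, rng.random(fine.shape))
        before = country_aggregate(f, mask, "sum").set_index("country_id")
        split_ids = mask.ids.copy()
        split_ids[: fine.nlat // 2][mask.ids[: fine.nlat // 2] == 1] = 3
        split = CountryMask(fine, split_ids, receptor_ids=frozenset({1, 2, 3}))
        after = country_aggregate(f, split, "sum").set_index("country_id")
        assert after.loc[1, "value"] + after.loc[3, "value"] == pytest.approx(
            before.loc[1, "value"], rel=1e-12)


class TestGriddedIO:
    def test_field_roundtrip_bit_exact(self, grids, rng, tmp_path):
        _, fine = grids
        f = Field(fine, rng.random((12,) + fine.shape), units="ug m-3", name="pm25")
        field_to_netcdf(f, tmp_path / "f.nc")
        g = field_from_netcdf(tmp_path / "f.nc")
        assert np.array_equal(f.values, g.values)
        assert g.units == "ug m-3"

    def test_inventory_roundtrip_preserves_keys(self, grids, rng, tmp_path):
        _, fine = grids
        data = {
            ("NOx", "road-transport"): rng.random((12,) + fine.shape),
            ("OC", "residential-heating"): rng.random((12,) + fine.shape),
        }
        inv = EmissionInventory(fine, data, year="2015")
        inventory_to_netcdf(inv, tmp_path / "inv.nc")
        back = inventory_from_netcdf(tmp_path / "inv.nc")
        assert back.year == "2015"
        assert back.species == inv.species and back.sectors == inv.sectors
        for key in data:
            assert np.array_equal(back.data[key], inv.data[key])

    def test_shuffled_dimension_order_reads_canonical(self, grids, rng, tmp_path):
        _, fine = grids
        vals = rng.random((12,) + fine.shape)
        da = xr.DataArray(vals.transpose(2, 0, 1), dims=("lon", "month", "lat"),
                          coords={"lon": fine.lon, "month": np.arange(1, 13),
                                  "lat": fine.lat}, name="pm25")
        da.attrs["units"] = "ug m-3"
        da.to_dataset().to_netcdf(tmp_path / "t.nc", engine="scipy")
        f = field_from_netcdf(tmp_path / "t.nc")
        assert np.array_equal(f.values, vals)

    def test_missing_units_rejected(self, grids, rng, tmp_path):
        _, fine = grids
        da = xr.DataArray(rng.random(fine.shape), dims=("lat", "lon"),
                          coords={"lat": fine.lat, "lon": fine.lon}, name="x")
        da.to_dataset().to_netcdf(tmp_path / "u.nc", engine="scipy")
        with pytest.raises(GridIOError, match="units"):
            field_from_netcdf(tmp_path / "u.nc")

    def test_missing_coordinate_rejected(self, tmp_path, rng):
        ds = xr.Dataset({"x": (("a", "b"), rng.random((3, 4)))})
        ds.to_netcdf(tmp_path / "c.nc", engine="scipy")
        with pytest.raises(GridIOError, match="lat"):
            field_from_netcdf(tmp_path / "c.nc")


class TestEmissionInventory:
    def test_negative_mass_rejected(self, grids):
        _, fine = grids
        bad = {("NOx", "waste"): -np.ones((12,) + fine.shape)}
        with pytest.raises(GridError, match=">= 0"):
            EmissionInventory(fine, bad)

    def test_coarse_aggregation_conserves_mass(self, grids, rng):
        coarse, fine = grids
        inv = EmissionInventory(
            fine, {("SO2", "energy-power"): rng.random((12,) + fine.shape)})
        agg = inv.aggregated_to(coarse)
        assert agg.total() == pytest.approx(inv.total(), rel=1e-12)
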