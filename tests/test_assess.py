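"""Normalization, tertiles, bivariate hotspots, focal cover, S/D grids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from beescape.assess import (
    aggregate_sd,
    bivariate_matrix,
    compare_scenarios,
    field_natural_cover,
    minmax_scale,
    natural_cover_pct,
    priority_ranking,
    sd_ratio,
    tertile_classify,
)
from beescape.grid import natural_mask
from conftest import make_grid, make_lulc
from _oracles import field_cover_oracle, natural_cover_oracle


class TestMinmaxScale:
    def test_basic_rescaling(self):
        arr = np.array([[2.0, 4.0, 6.0]])
        np.testing.assert_allclose(
            minmax_scale(arr, np.ones_like(arr, bool)), [[0.0, 0.5, 1.0]]
        )

    def test_constant_maps_to_zeros(self):
        arr = np.full((3, 3), 5.0)
        assert minmax_scale(arr, np.ones((3, 3), bool)).max() == 0.0

    def test_output_spans_unit_interval(self):
        rng = np.random.default_rng(0)
        arr = rng.random((10, 10)) * 7 - 3
        out = minmax_scale(arr, np.ones((10, 10), bool))
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)

    def test_region_mask_controls_range(self):
        arr = np.array([[0.0, 10.0], [2.0, 4.0]])
        mask = np.array([[False, False], [True, True]])
        out = minmax_scale(arr, mask)
        assert out[1, 0] == 0.0 and out[1, 1] == 1.0
        assert out[0, 1] == pytest.approx(4.0)  # outside-region values extrapolate


class TestTertiles:
    def test_one_to_nine_splits_in_thirds(self):
        codes = tertile_classify(np.arange(1, 10))
        assert codes.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_all_equal_all_low_with_warning(self):
        with pytest.warns(UserWarning):
            codes = tertile_classify(np.full(6, 3.0))
        assert (codes == 0).all()

    def test_three_distinct_blocks(self):
        codes = tertile_classify(np.array([0, 0, 0, 5, 5, 5, 9, 9, 9]))
        assert codes.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tertile_classify(np.array([1.0, 2.0]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rank_based_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(15)
        assert (tertile_classify(vals) == tertile_classify(np.exp(3 * vals))).all()


class TestBivariateMatrix:
    def test_matrix_mass_balance_and_diagonal(self):
        idx = list(range(1, 10))
        s = pd.Series(np.arange(9.0), index=idx)
        areas = pd.Series(1.0, index=idx)
        res = bivariate_matrix(s, s * 2, areas)  # identical rank order
        assert res.matrix_pct.sum() == pytest.approx(100.0)
        assert np.trace(res.matrix_pct) == pytest.approx(100.0)

    def test_uniform_grid_one_field_per_cell(self):
        idx = list(range(9))
        s = pd.Series([0, 1, 2] * 3, index=idx, dtype=float)
        d = pd.Series([0, 0, 0, 1, 1, 1, 2, 2, 2], index=idx, dtype=float)
        res = bivariate_matrix(s, d, pd.Series(1.0, index=idx))
        np.testing.assert_allclose(res.matrix_pct, 100.0 / 9.0)

    def test_anticorrelated_fills_corners(self):
        idx = list(range(9))
        s = pd.Series(np.arange(9.0), index=idx)
        res = bivariate_matrix(s, s.iloc[::-1].set_axis(idx), pd.Series(1.0, index=idx))
        assert np.trace(np.fliplr(res.matrix_pct)) == pytest.approx(100.0)

    def test_hotspots_are_low_supply_high_demand(self):
        idx = list(range(9))
        s = pd.Series(np.arange(9.0), index=idx)
        d = pd.Series(np.arange(9.0)[::-1], index=idx, dtype=float)
        res = bivariate_matrix(s, d, pd.Series(1.0, index=idx))
        # low supply tertile = fields 0..2; their demand tertile is high
        assert res.hotspot_ids == [0, 1, 2]

    def test_hotspots_stable_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        idx = list(range(30))
        s = pd.Series(rng.random(30), index=idx)
        d = pd.Series(rng.random(30), index=idx)
        a = pd.Series(rng.random(30) + 0.5, index=idx)
        base = bivariate_matrix(s, d, a)
        trans = bivariate_matrix(np.exp(s), d**3, a)
        assert base.hotspot_ids == trans.hotspot_ids


class TestNaturalCover:
    def test_pure_landscapes(self):
        g = make_grid(10, 10)
        np.testing.assert_allclose(natural_cover_pct(np.ones((10, 10)), g, 150), 100.0)
        np.testing.assert_allclose(natural_cover_pct(np.zeros((10, 10)), g, 150), 0.0)

    def test_half_plane_boundary_cell_near_fifty(self):
        g = make_grid(40, 40)
        mask = np.zeros((40, 40))
        mask[:, :20] = 1.0
        cover = natural_cover_pct(mask, g, radius_m=300.0)
        # cell adjacent to the divide, far from edges
        assert cover[20, 19] == pytest.approx(50.0, abs=5.0)
        assert cover[20, 19] + cover[20, 20] == pytest.approx(100.0, abs=1.0)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(9)
        mask = (rng.random((20, 20)) < 0.3).astype(float)
        g = make_grid(20, 20)
        got = natural_cover_pct(mask, g, radius_m=200.0)
        want = natural_cover_oracle(mask, 30.0, 200.0)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_field_cover_uniform_raster(self):
        g = make_grid(20, 20)
        cover = np.full((20, 20), 37.0)
        assert field_natural_cover(cover, g, (300.0, 300.0), 150.0) == pytest.approx(37.0)

    def test_field_cover_matches_oracle(self):
        rng = np.random.default_rng(12)
        cover = rng.random((20, 20)) * 100
        g = make_grid(20, 20)
        centroid = (287.0, 341.0)
        got = field_natural_cover(cover, g, centroid, 200.0)
        want = field_cover_oracle(cover, 30.0, 0.0, 600.0, centroid, 200.0)
        assert got == pytest.approx(want, abs=1e-9)


class TestPriorityRanking:
    def test_boundary_values(self):
        covers = pd.Series({1: 4.9, 2: 5.0, 3: 10.0, 4: 19.99, 5: 20.0})
        areas = pd.Series(1.0, index=covers.index)
        r = priority_ranking(covers, areas, ag_zone_ha=5.0)
        assert r.category.tolist() == ["high", "intermediate", "low", "low", "none"]

    def test_percentages(self):
        covers = pd.Series({1: 3.0, 2: 12.0, 3: 25.0})
        areas = pd.Series(10.0, index=covers.index)
        r = priority_ranking(covers, areas, ag_zone_ha=30.0)
        assert r.pct("high") == pytest.approx(100 / 3)
        assert r.pct("low") == pytest.approx(100 / 3)
        assert r.pct("none") == pytest.approx(100 / 3)
        assert r.summary["pct_of_ag_zone"].sum() == pytest.approx(100.0)


class TestSDRatio:
    def test_pointwise_rules(self):
        s = np.array([[0.5, 0.4, 0.0]])
        d = np.array([[0.5, 0.2, 0.7]])
        raw = np.array([[1.0, 0.0, 1.0]])
        out = sd_ratio(s, d, raw)
        assert out[0, 0] == pytest.approx(1.0)
        assert np.isnan(out[0, 1])  # no demand -> undefined
        assert out[0, 2] == 0.0


class TestAggregateSD:
    def _lulc(self, n=67):
        return make_lulc(np.full((n, n), 10))  # ~2x2 km of cropland

    def test_uniform_above_one(self):
        lulc = self._lulc()
        sd = np.full(lulc.grid.shape, 1.2)
        ag = np.ones(lulc.grid.shape, bool)
        g = aggregate_sd(sd, lulc, ag)
        assert g.pct_ge1 == pytest.approx(100.0)

    def test_uniform_below_one(self):
        lulc = self._lulc()
        g = aggregate_sd(np.full(lulc.grid.shape, 0.8), lulc, np.ones(lulc.grid.shape, bool))
        assert g.pct_ge1 == 0.0

    def test_checkerboard_blocks_half(self):
        # 2x2 blocks of 1-km tiles alternating 0.5 / 1.5
        lulc = self._lulc(67)
        sd = np.full(lulc.grid.shape, 0.5)
        x = (np.arange(67) + 0.5) * 30 // 1000
        BR, BC = np.meshgrid(x.astype(int), x.astype(int), indexing="ij")
        sd[(BR + BC) % 2 == 1] = 1.5
        g = aggregate_sd(sd, lulc, np.ones(lulc.grid.shape, bool))
        assert g.pct_ge1 == pytest.approx(50.0, abs=1.0)

    def test_low_overlap_tiles_dropped(self):
        lulc = self._lulc()
        ag = np.zeros(lulc.grid.shape, bool)
        ag[:20, :20] = True  # only one corner tile reaches 25% overlap
        g = aggregate_sd(np.full(lulc.grid.shape, 1.2), lulc, ag)
        assert g.n_retained < len(g.cells)

    def test_no_agriculture_rejected(self):
        lulc = self._lulc()
        with pytest.raises(ValueError):
            aggregate_sd(np.ones(lulc.grid.shape), lulc, np.zeros(lulc.grid.shape, bool))


class TestCompareScenarios:
    def test_baseline_deltas_zero(self, default_run):
        row = default_run.comparison.loc["no_restoration"]
        assert row["delta_sd_pct_ge1"] == 0.0
        assert row["restored_pct_territory"] == 0.0

    def test_rows_per_scenario(self, default_run):
        assert len(default_run.comparison) == 5

    def test_demand_shared_across_scenarios(self, default_run):
        # demand is computed once, from histories and flags only
        res = default_run
        assert res.demand.raster.sum() > 0
        for name, sc in res.scenarios.items():
            assert sc.lulc.grid.shape == res.demand.raster.shape
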