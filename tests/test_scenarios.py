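"""Flower-strip geometry and the five restoration scenarios."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon, box

from beescape.grid import FieldRegistry, natural_mask, rasterize_fields
from beescape.marginal import MarginalLandReport, find_marginal_lands
from beescape.scenarios import (
    build_flower_strip,
    longest_edge,
    scenario_flower_strips,
    scenario_maximal,
    scenario_mixed,
    scenario_no_restoration,
    scenario_reforest_marginal,
)
from conftest import history, make_field, make_lulc

YEARS = list(range(2012, 2022))


def empty_report(shape=(1, 1)):
    return MarginalLandReport([], [], np.zeros(shape, np.uint8), 0.0, 0.0)


def report_for(abandoned, registry, shape):
    return MarginalLandReport(
        abandoned_ids=sorted(abandoned),
        degraded_ids=[],
        degraded_pixel_mask=np.zeros(shape, np.uint8),
        total_abandoned_ha=sum(registry[i].area_ha for i in abandoned),
        total_degraded_ha=0.0,
    )


class TestLongestEdge:
    def test_rectangle(self):
        e = longest_edge(box(0, 0, 600, 100))
        assert e.length == pytest.approx(600.0)

    def test_square_tie_break_deterministic(self):
        p = box(0, 0, 100, 100)
        e1, e2 = longest_edge(p), longest_edge(Polygon(list(p.exterior.coords)[::-1]))
        assert e1.length == e2.length == pytest.approx(100.0)
        assert e1.equals(e2)  # same canonical ring start regardless of input order

    def test_l_shape_first_of_tied_edges(self):
        # two 300-m edges tie; the scan picks the first in canonical ring order
        coords = [(0, 0), (300, 0), (300, 100), (150, 100), (150, 300), (0, 300)]
        poly = Polygon(coords)
        e = longest_edge(poly)
        assert e.length == pytest.approx(300.0)
        ring = list(shapely.normalize(poly).exterior.coords)
        firsts = [
            (a, b)
            for a, b in zip(ring[:-1], ring[1:])
            if abs(shapely.LineString([a, b]).length - 300.0) < 1e-9
        ]
        assert e.equals(shapely.LineString(firsts[0]))

    def test_degenerate_rejected(self):
        with pytest.raises((ValueError, shapely.errors.GEOSException)):
            longest_edge(Polygon([(0, 0), (1, 1), (2, 2)]))


class TestBuildFlowerStrip:
    def test_long_rectangle_strip_area(self):
        s = build_flower_strip(box(0, 0, 600, 100), 1)
        assert s.area_ha == pytest.approx(0.30, rel=1e-6)
        assert s.polygon.within(box(0, 0, 600, 100).buffer(1e-9))

    def test_square_strip_area(self):
        s = build_flower_strip(box(0, 0, 100, 100), 1)
        assert s.area_ha == pytest.approx(0.05, rel=1e-6)

    def test_irregular_convex_field_contained(self):
        poly = Polygon([(0, 0), (500, 30), (560, 300), (80, 380), (-20, 150)])
        s = build_flower_strip(poly, 1)
        assert s.polygon.within(poly.buffer(1e-9))
        assert s.area_ha <= 5.0 * s.base_segment.length / 10_000.0 + 1e-9
        assert s.area_ha > 0


def _toy_landscape():
    """60x60-cell crop landscape with four aligned fields in a row."""
    codes = np.full((60, 60), 10)
    lulc = make_lulc(codes)
    fields = [
        make_field(1, 60, 60, 360, 660, history(YEARS, False)),  # marginal
        make_field(2, 420, 60, 720, 660, history(YEARS, True, "canola")),
        make_field(3, 840, 60, 1140, 660, history(YEARS, True, "canola")),
        make_field(4, 1320, 60, 1620, 660, history(YEARS, True, "canola")),
    ]
    registry = FieldRegistry(fields)
    labels = rasterize_fields(registry, lulc.grid)
    return lulc, registry, labels


class TestReforestMarginal:
    def test_no_marginal_identity(self):
        lulc, registry, labels = _toy_landscape()
        sc = scenario_reforest_marginal(lulc, registry, labels, empty_report(labels.shape))
        assert np.array_equal(sc.lulc.codes, lulc.codes)
        assert sc.reforested_ha == 0.0

    def test_single_abandoned_field_ledger_and_cells(self):
        codes = np.full((20, 20), 10)
        lulc = make_lulc(codes)
        f = make_field(1, 60, 60, 360, 360, history(YEARS, False))  # 9 ha
        registry = FieldRegistry([f])
        labels = rasterize_fields(registry, lulc.grid)
        sc = scenario_reforest_marginal(
            lulc, registry, labels, report_for({1}, registry, labels.shape)
        )
        assert sc.reforested_ha == pytest.approx(9.0)
        assert (sc.lulc.codes == 20).sum() == 100

    def test_synthetic_bundle_ledger_matches_truth(self, default_bundle):
        b = default_bundle
        rep = find_marginal_lands(b.lulc, b.registry, b.labels, b.ndvi)
        sc = scenario_reforest_marginal(b.lulc, b.registry, b.labels, rep)
        expected = sum(b.registry[i].area_ha for i in rep.marginal_ids)
        assert sc.reforested_ha == pytest.approx(expected)
        assert sc.restored_fraction == pytest.approx(expected / b.lulc.territory_ha)


class TestFlowerStripsScenario:
    def test_single_field_ledger(self):
        codes = np.full((30, 30), 10)
        lulc = make_lulc(codes)
        f = make_field(1, 60, 60, 660, 160, history(YEARS, True, "canola"))
        registry = FieldRegistry([f])
        labels = rasterize_fields(registry, lulc.grid)
        sc = scenario_flower_strips(lulc, registry, labels, empty_report(labels.shape))
        assert sc.strips_ha == pytest.approx(0.30, rel=1e-6)
        assert (sc.lulc.codes == 23).any()

    def test_all_marginal_no_strips(self):
        lulc, registry, labels = _toy_landscape()
        rep = report_for({1, 2, 3, 4}, registry, labels.shape)
        sc = scenario_flower_strips(lulc, registry, labels, rep)
        assert sc.strips == [] and sc.strips_ha == 0.0

    def test_identical_rectangles_additive(self):
        lulc, registry, labels = _toy_landscape()
        sc = scenario_flower_strips(lulc, registry, labels, empty_report(labels.shape))
        one = build_flower_strip(registry[2].polygon, 2)
        assert sc.strips_ha == pytest.approx(4 * one.area_ha, rel=1e-6)


class TestMixedScenario:
    def test_no_priority_fields_is_identity_with_warning(self):
        lulc, registry, labels = _toy_landscape()
        rep = report_for({1}, registry, labels.shape)
        covers = {2: 50.0, 3: 50.0, 4: 50.0}  # nobody under 5% cover
        with pytest.warns(UserWarning, match="no priority"):
            sc = scenario_mixed(
                lulc, registry, labels, rep, hotspot_ids=[2, 3, 4], field_covers=covers
            )
        assert np.array_equal(sc.lulc.codes, lulc.codes)
        assert sc.reforested_ha == 0.0 and sc.strips_ha == 0.0

    def test_generous_target_removes_nothing(self):
        lulc, registry, labels = _toy_landscape()
        rep = report_for({1}, registry, labels.shape)
        covers = {2: 1.0, 3: 1.0, 4: 1.0}
        sc = scenario_mixed(
            lulc, registry, labels, rep,
            hotspot_ids=[2, 3, 4], field_covers=covers, target_fraction=0.9,
        )
        assert len(sc.strips) == 3
        assert sc.reforested_ha == pytest.approx(registry[1].area_ha)

    def test_removal_order_closest_to_marginal_first(self):
        # fields 2/3/4 sit 60/480/960 m from the marginal field; force one
        # removal and expect field 2's strip (the closest) to be dropped
        lulc, registry, labels = _toy_landscape()
        rep = report_for({1}, registry, labels.shape)
        covers = {2: 1.0, 3: 1.0, 4: 1.0}
        full = scenario_mixed(
            lulc, registry, labels, rep,
            hotspot_ids=[2, 3, 4], field_covers=covers, target_fraction=0.9,
        )
        total = full.reforested_ha + full.strips_ha
        one_strip = full.strips[0].area_ha
        target = (total - 0.5 * one_strip) / lulc.territory_ha
        sc = scenario_mixed(
            lulc, registry, labels, rep,
            hotspot_ids=[2, 3, 4], field_covers=covers, target_fraction=target,
        )
        assert sorted(s.field_id for s in sc.strips) == [3, 4]

    def test_target_below_reforestation_drops_all_strips(self):
        lulc, registry, labels = _toy_landscape()
        rep = report_for({1}, registry, labels.shape)
        covers = {2: 1.0, 3: 1.0, 4: 1.0}
        with pytest.warns(UserWarning, match="all strips removed"):
            sc = scenario_mixed(
                lulc, registry, labels, rep,
                hotspot_ids=[2, 3, 4], field_covers=covers, target_fraction=1e-6,
            )
        assert sc.strips == []


class TestMaximalScenario:
    def test_exclusion_by_distance(self):
        lulc, registry, labels = _toy_landscape()
        rep = report_for({1}, registry, labels.shape)
        sc = scenario_maximal(lulc, registry, labels, rep, exclusion_m=50.0)
        # field 2 is 60 m away -> strip; a field at 0 m would be excluded
        assert sorted(s.field_id for s in sc.strips) == [2, 3, 4]
        sc2 = scenario_maximal(lulc, registry, labels, rep, exclusion_m=100.0)
        assert sorted(s.field_id for s in sc2.strips) == [3, 4]

    def test_no_marginal_equals_flower_strips(self):
        lulc, registry, labels = _toy_landscape()
        rep = empty_report(labels.shape)
        a = scenario_maximal(lulc, registry, labels, rep)
        b = scenario_flower_strips(lulc, registry, labels, rep)
        assert sorted(s.field_id for s in a.strips) == sorted(
            s.field_id for s in b.strips
        )
        assert a.strips_ha == pytest.approx(b.strips_ha)


class TestScenarioInvariants:
    def test_full_synthetic_scenarios(self, default_run):
        res = default_run
        base = res.scenarios["no_restoration"]
        territory = res.bundle.lulc.territory_ha
        for name, sc in res.scenarios.items():
            assert sc.lulc.grid.shape == base.lulc.grid.shape
            assert set(sc.lulc.classes) == set(base.lulc.classes)
            assert sc.restored_fraction == pytest.approx(
                (sc.reforested_ha + sc.strips_ha) / territory
            )
            # restoration never removes natural habitat
            assert (natural_mask(sc.lulc) >= natural_mask(base.lulc)).all()

    def test_strips_avoid_marginal_fields_and_each_other(self, default_run):
        res = default_run
        marginal_polys = [
            res.bundle.registry[i].polygon for i in res.report.marginal_ids
        ]
        for name in ("flower_strips", "mixed", "maximal"):
            strips = res.scenarios[name].strips
            for s in strips:
                for p in marginal_polys:
                    assert s.polygon.intersection(p).area < 1e-6
            for i, a in enumerate(strips):
                for b in strips[i + 1 :]:
                    assert a.polygon.intersection(b.polygon).area < 1e-6

    def test_mixed_budget_respected(self, default_run):
        sc = default_run.scenarios["mixed"]
        target = 0.03 * default_run.bundle.lulc.territory_ha
        total = sc.reforested_ha + sc.strips_ha
        assert total <= target + 1e-6
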