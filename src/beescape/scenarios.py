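"""Restoration scenarios as land-cover transformations.

Five scenarios are supported:

* ``no_restoration`` — the baseline map, untouched.
* ``reforest_marginal`` — trees planted on every abandoned or degraded field.
* ``flower_strips`` — a 5-m flower strip along the longest edge of every
  crop field not identified as marginal.
* ``mixed`` — strips plus reforestation, pruned to a 3%-of-territory area
  budget by a prioritization around pollination-demand hotspots with little
  surrounding natural habitat.
* ``maximal`` — reforestation everywhere possible plus strips on all crop
  fields farther than 50 m from any marginal field.

Strips are true 5-m vector geometries.  The raster burn (cells whose box
intersects a strip polygon take the flower-strip class) over-represents
strips at 30-m cells, so all area accounting — the ledger, the 3% budget —
uses the vector areas, never cell counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .grid import FieldRegistry, LandscapeGrid, LULCMap, reclassify
from .marginal import MarginalLandReport

__all__ = [
    "FlowerStrip",
    "Scenario",
    "longest_edge",
    "build_flower_strip",
    "build_all_strips",
    "cells_intersecting",
    "scenario_no_restoration",
    "scenario_reforest_marginal",
    "scenario_flower_strips",
    "scenario_mixed",
    "scenario_maximal",
]


@dataclass
class FlowerStrip:
    """A 5-m-wide sown floral strip along one field edge, vector-exact."""

    field_id: int
    base_segment: LineString
    polygon: Polygon
    area_ha: float


@dataclass
class Scenario:
    """A named LULC transformation plus its restored-area ledger.

    Ledger areas are vector-accounted hectares; ``restored_fraction`` is
    relative to the reported territory (buffer excluded).
    """

    name: str
    lulc: LULCMap
    strips: list[FlowerStrip] = dc_field(default_factory=list)
    reforested_ha: float = 0.0
    strips_ha: float = 0.0
    restored_fraction: float = 0.0
    reforested_ids: list[int] = dc_field(default_factory=list)
    notes: list[str] = dc_field(default_factory=list)


def _class_id(lulc: LULCMap, name: str) -> int:
    for cid, cls in lulc.classes.items():
        if cls.name == name:
            return cid
    raise KeyError(f"class {name!r} not in the class table")


def longest_edge(polygon: Polygon) -> LineString:
    """Longest straight segment between consecutive exterior-ring vertices.

    Ties break by first occurrence in ring order from the ring's canonical
    start (the polygon is normalized first so the start vertex is stable).
    """
    poly = shapely.normalize(polygon)
    coords = list(poly.exterior.coords)
    if len(coords) < 4 or poly.area <= 0:
        raise ValueError("degenerate polygon has no edges")
    best, best_len = None, -1.0
    for a, b in zip(coords[:-1], coords[1:]):
        d = math.dist(a, b)
        if d > best_len + 1e-9:
            best, best_len = (a, b), d
    return LineString(best)


def build_flower_strip(
    polygon: Polygon, field_id: int, width_m: float = 5.0
) -> FlowerStrip:
    """Strip = longest edge buffered by ``width_m`` clipped to the field."""
    edge = longest_edge(polygon)
    strip = edge.buffer(width_m, cap_style="flat").intersection(polygon)
    area_ha = strip.area / 10_000.0
    expected = width_m * edge.length / 10_000.0
    if area_ha < expected / 10.0:
        warnings.warn(
            f"field {field_id}: strip area {area_ha:.4f} ha is a sliver "
            f"(expected ~{expected:.4f} ha)",
            stacklevel=2,
        )
    return FlowerStrip(
        field_id=field_id, base_segment=edge, polygon=strip, area_ha=area_ha
    )


def build_all_strips(
    registry: FieldRegistry, exclude_ids: set[int] | frozenset[int] = frozenset(),
    width_m: float = 5.0,
) -> dict[int, FlowerStrip]:
    return {
        f.field_id: build_flower_strip(f.polygon, f.field_id, width_m)
        for f in registry
        if f.field_id not in exclude_ids
    }


def cells_intersecting(grid: LandscapeGrid, geom) -> np.ndarray:
    """Boolean raster of cells whose square interior intersects ``geom``."""
    out = np.zeros(grid.shape, dtype=bool)
    if geom.is_empty:
        return out
    gminx, _, _, gmaxy = grid.bounds()
    res = grid.resolution
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(0, int(math.floor((minx - gminx) / res)))
    c1 = min(grid.n_cols - 1, int(math.floor((maxx - gminx) / res + 1)))
    r0 = max(0, int(math.floor((gmaxy - maxy) / res)))
    r1 = min(grid.n_rows - 1, int(math.floor((gmaxy - miny) / res + 1)))
    if c1 < c0 or r1 < r0:
        return out
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    boxes = shapely.box(
        gminx + cc.ravel() * res,
        gmaxy - (rr.ravel() + 1) * res,
        gminx + (cc.ravel() + 1) * res,
        gmaxy - rr.ravel() * res,
    )
    hit = shapely.intersects(geom, boxes) & ~shapely.touches(geom, boxes)
    out[rr.ravel()[hit], cc.ravel()[hit]] = True
    return out


def _burn_strips(
    lulc: LULCMap, strips: list[FlowerStrip], strip_class: int
) -> np.ndarray:
    sel = np.zeros(lulc.grid.shape, dtype=bool)
    for s in strips:
        sel |= cells_intersecting(lulc.grid, s.polygon)
    return sel


def _finalize(
    name: str,
    baseline: LULCMap,
    marginal_ids: list[int],
    registry: FieldRegistry,
    labels: np.ndarray,
    strips: list[FlowerStrip],
    notes: list[str] | None = None,
) -> Scenario:
    forest = _class_id(baseline, "forest")
    strip_cls = _class_id(baseline, "flower_strip")
    changes = []
    if marginal_ids:
        changes.append((np.isin(labels, marginal_ids), forest))
    if strips:
        changes.append((_burn_strips(baseline, strips, strip_cls), strip_cls))
    lulc = reclassify(baseline, changes) if changes else baseline.copy()
    reforested = sum(registry[i].area_ha for i in marginal_ids)
    strips_ha = sum(s.area_ha for s in strips)
    return Scenario(
        name=name,
        lulc=lulc,
        strips=strips,
        reforested_ha=reforested,
        strips_ha=strips_ha,
        restored_fraction=(reforested + strips_ha) / baseline.territory_ha,
        reforested_ids=sorted(marginal_ids),
        notes=notes or [],
    )


def scenario_no_restoration(baseline: LULCMap) -> Scenario:
    """The untouched baseline with an empty ledger."""
    return Scenario(name="no_restoration", lulc=baseline.copy())


def scenario_reforest_marginal(
    baseline: LULCMap,
    registry: FieldRegistry,
    labels: np.ndarray,
    report: MarginalLandReport,
) -> Scenario:
    """Trees planted in every abandoned or degraded field."""
    return _finalize(
        "reforest_marginal", baseline, report.marginal_ids, registry, labels, []
    )


def scenario_flower_strips(
    baseline: LULCMap,
    registry: FieldRegistry,
    labels: np.ndarray,
    report: MarginalLandReport,
    width_m: float = 5.0,
) -> Scenario:
    """A strip along the longest edge of every non-marginal crop field."""
    strips = build_all_strips(registry, set(report.marginal_ids), width_m)
    return _finalize(
        "flower_strips", baseline, [], registry, labels, list(strips.values())
    )


def scenario_mixed(
    baseline: LULCMap,
    registry: FieldRegistry,
    labels: np.ndarray,
    report: MarginalLandReport,
    hotspot_ids: list[int],
    field_covers,
    target_fraction: float = 0.03,
    cover_max_pct: float = 5.0,
    radius_m: float = 1000.0,
    width_m: float = 5.0,
) -> Scenario:
    """Budgeted mix of reforestation and strips around priority hotspots.

    Priority fields are demand hotspots with mean 1-km natural cover below
    ``cover_max_pct``.  Candidate interventions (marginal fields, potential
    strips) must intersect the union of 1-km buffers around the priority
    fields' centroids; all candidate marginal fields are reforested, then
    candidate strips are dropped closest-to-reforested-field first (a strip
    beside a future forest patch is redundant) until the total restored area
    fits within ``target_fraction`` of the territory.
    """
    notes: list[str] = []
    priority = [
        fid for fid in hotspot_ids if float(field_covers[fid]) < cover_max_pct
    ]
    if not priority:
        warnings.warn("mixed scenario: no priority fields; nothing to restore",
                      stacklevel=2)
        sc = scenario_no_restoration(baseline)
        sc.name = "mixed"
        sc.notes = ["no priority fields"]
        return sc

    buffer_union = shapely.unary_union(
        [shapely.Point(registry[fid].centroid).buffer(radius_m) for fid in priority]
    )
    cand_marginal = [
        fid
        for fid in report.marginal_ids
        if registry[fid].polygon.intersects(buffer_union)
    ]
    all_strips = build_all_strips(registry, set(report.marginal_ids), width_m)
    cand_strips = [
        s for s in all_strips.values() if s.polygon.intersects(buffer_union)
    ]

    reforested_ha = sum(registry[i].area_ha for i in cand_marginal)
    target_ha = target_fraction * baseline.territory_ha
    marg_polys = [registry[i].polygon for i in (cand_marginal or report.marginal_ids)]

    def dist_to_marginal(s: FlowerStrip) -> float:
        if not marg_polys:
            return float(s.field_id)  # stable fallback order when no marginal exists
        return min(s.polygon.distance(p) for p in marg_polys)

    cand_strips.sort(key=lambda s: (dist_to_marginal(s), s.field_id))
    total = reforested_ha + sum(s.area_ha for s in cand_strips)
    while cand_strips and total > target_ha:
        removed = cand_strips.pop(0)  # closest to a reforested patch goes first
        total -= removed.area_ha
    if total > target_ha:
        warnings.warn(
            "mixed scenario: reforestation alone exceeds the area target; "
            "all strips removed",
            stacklevel=2,
        )
        notes.append("target below reforested area; all strips removed")

    return _finalize(
        "mixed", baseline, cand_marginal, registry, labels, cand_strips, notes
    )


def scenario_maximal(
    baseline: LULCMap,
    registry: FieldRegistry,
    labels: np.ndarray,
    report: MarginalLandReport,
    exclusion_m: float = 50.0,
    width_m: float = 5.0,
) -> Scenario:
    """Reforest all marginal fields; strips on every crop field farther than
    ``exclusion_m`` from all marginal fields."""
    marginal = set(report.marginal_ids)
    marg_polys = [registry[i].polygon for i in report.marginal_ids]
    strips = []
    for f in registry:
        if f.field_id in marginal:
            continue
        if marg_polys and min(f.polygon.distance(p) for p in marg_polys) <= exclusion_m:
            continue
        strips.append(build_flower_strip(f.polygon, f.field_id, width_m))
    return _finalize(
        "maximal", baseline, sorted(marginal), registry, labels, strips
    )
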