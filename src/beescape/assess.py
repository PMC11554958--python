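"""Evaluation layers: normalization, tertile bivariate classification and
hotspot mapping, supply-to-demand (S/D) aggregation at 1 km**2, focal
natural-cover statistics and the restoration-priority ranking.

All reported statistics exclude the analysis buffer ring; buffer cells do
participate as neighbours in the focal windows so edge cells see their real
surroundings.  The S/D ratio compares min-max-scaled supply and demand and is
a relative, between-scenario comparator only, never an absolute measure of
pollination deficit or surplus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import signal

from .grid import LandscapeGrid, LULCMap

__all__ = [
    "BivariateResult",
    "SDGrid",
    "PriorityRanking",
    "minmax_scale",
    "tertile_classify",
    "bivariate_matrix",
    "natural_cover_pct",
    "field_natural_cover",
    "priority_ranking",
    "sd_ratio",
    "aggregate_sd",
    "compare_scenarios",
]

TERTILE_LABELS = ("low", "intermediate", "high")

#: priority categories and their natural-cover boundaries (percent):
#: high < 5 <= intermediate < 10 <= low < 20 <= none
PRIORITY_BOUNDS = (5.0, 10.0, 20.0)
PRIORITY_LABELS = ("high", "intermediate", "low", "none")


def minmax_scale(raster: np.ndarray, region_mask: np.ndarray) -> np.ndarray:
    """Linear rescaling to [0, 1] using the min/max over ``region_mask``.

    A constant raster maps to all zeros by convention.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    vals = raster[region_mask]
    vmin, vmax = float(np.nanmin(vals)), float(np.nanmax(vals))
    if vmax <= vmin:
        return np.zeros_like(np.asarray(raster, dtype=float))
    return (np.asarray(raster, dtype=float) - vmin) / (vmax - vmin)


def tertile_classify(values: np.ndarray) -> np.ndarray:
    """Three-way rank split at the 1/3 and 2/3 sample quantiles.

    Linear-interpolation quantile convention; ties assigned by inclusive
    breakpoints (v <= q1 -> low, v <= q2 -> intermediate, else high).
    Returns integer codes 0/1/2 indexing :data:`TERTILE_LABELS`.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("tertile classification needs at least 3 values")
    if np.unique(values).size < 3:
        warnings.warn(
            "fewer than 3 distinct values: tertile classes are degenerate",
            stacklevel=2,
        )
    q1, q2 = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    out = np.full(values.shape, 2, dtype=int)
    out[values <= q2] = 1
    out[values <= q1] = 0
    return out


@dataclass
class BivariateResult:
    """Field-scale supply x demand tertile cross-classification."""

    supply_tertile: pd.Series
    demand_tertile: pd.Series
    matrix_pct: np.ndarray  # [demand tertile, supply tertile] % of cultivated area
    hotspot_ids: list[int]


def bivariate_matrix(
    supply_by_field: pd.Series,
    demand_by_field: pd.Series,
    areas_ha: pd.Series,
) -> BivariateResult:
    """Cross-classify crop fields by supply and demand tertiles.

    The 3x3 matrix holds the percentage of total cultivated area in each
    (demand, supply) combination; hotspots for pollination demand are fields
    with intermediate-to-high demand and low supply.
    """
    idx = supply_by_field.index
    if not (idx.equals(demand_by_field.index) and idx.equals(areas_ha.index)):
        raise ValueError("supply, demand and area series must share the field index")
    s_t = pd.Series(tertile_classify(supply_by_field.to_numpy()), index=idx)
    d_t = pd.Series(tertile_classify(demand_by_field.to_numpy()), index=idx)
    total = float(areas_ha.sum())
    matrix = np.zeros((3, 3))
    for fid in idx:
        matrix[d_t[fid], s_t[fid]] += areas_ha[fid]
    matrix = matrix / total * 100.0
    hotspots = sorted(idx[(d_t >= 1) & (s_t == 0)])
    return BivariateResult(
        supply_tertile=s_t, demand_tertile=d_t, matrix_pct=matrix, hotspot_ids=hotspots
    )


# ---------------------------------------------------------------------------
# Focal natural-cover statistics


def _circular_footprint(radius_m: float, resolution_m: float) -> np.ndarray:
    r = int(np.floor(radius_m / resolution_m))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (np.hypot(dy, dx) * resolution_m <= radius_m + 1e-9).astype(float)


def natural_cover_pct(
    mask: np.ndarray, grid: LandscapeGrid, radius_m: float = 1000.0
) -> np.ndarray:
    """Per-cell percentage of natural cells within a circular window.

    Window membership is by cell-center distance <= radius; the denominator
    counts only in-extent cells, so edge cells use their truncated window.
    """
    foot = _circular_footprint(radius_m, grid.resolution)
    m = np.asarray(mask, dtype=float)
    num = signal.convolve(m, foot, mode="same", method="auto")
    den = signal.convolve(np.ones_like(m), foot, mode="same", method="auto")
    return np.clip(100.0 * num / den, 0.0, 100.0)


def field_natural_cover(
    cover: np.ndarray,
    grid: LandscapeGrid,
    centroid: tuple[float, float],
    radius_m: float = 1000.0,
) -> float:
    """Mean of the per-cell cover raster within ``radius_m`` of a centroid.

    This is the second stage of the two-stage smoothing: the per-cell cover
    is itself already a 1-km focal percentage.
    """
    cx, cy = centroid
    xs = grid.x_centers()
    ys = grid.y_centers()
    c_sel = np.nonzero(np.abs(xs - cx) <= radius_m)[0]
    r_sel = np.nonzero(np.abs(ys - cy) <= radius_m)[0]
    if c_sel.size == 0 or r_sel.size == 0:
        raise ValueError(f"centroid {centroid} outside the grid extent")
    dx = xs[c_sel] - cx
    dy = ys[r_sel] - cy
    within = (dy[:, None] ** 2 + dx[None, :] ** 2) <= radius_m**2 + 1e-9
    sub = cover[np.ix_(r_sel, c_sel)]
    return float(sub[within].mean())


@dataclass
class PriorityRanking:
    """Four-class restoration priority by surrounding natural cover."""

    category: pd.Series  # field_id -> label in PRIORITY_LABELS
    summary: pd.DataFrame  # rows: category; columns: area_ha, pct_of_ag_zone

    def pct(self, label: str) -> float:
        return float(self.summary.loc[label, "pct_of_ag_zone"])


def priority_ranking(
    field_covers: pd.Series, areas_ha: pd.Series, ag_zone_ha: float
) -> PriorityRanking:
    """Categorize fields by natural-cover deficit and sum areas per class.

    high: cover < 5%;  intermediate: 5 <= cover < 10;  low: 10 <= cover < 20;
    none: cover >= 20 (the lower-threshold target reached).
    """
    b1, b2, b3 = PRIORITY_BOUNDS
    cov = field_covers.to_numpy(dtype=float)
    codes = np.digitize(cov, [b1, b2, b3], right=False)  # 0..3
    labels = pd.Series(
        [PRIORITY_LABELS[i] for i in codes], index=field_covers.index, name="priority"
    )
    rows = []
    for lab in PRIORITY_LABELS:
        area = float(areas_ha[labels == lab].sum())
        rows.append({"area_ha": area, "pct_of_ag_zone": 100.0 * area / ag_zone_ha})
    summary = pd.DataFrame(rows, index=list(PRIORITY_LABELS))
    return PriorityRanking(category=labels, summary=summary)


# ---------------------------------------------------------------------------
# S/D ratio and 1-km**2 aggregation


def sd_ratio(
    scaled_supply: np.ndarray,
    scaled_demand: np.ndarray,
    raw_demand: np.ndarray,
) -> np.ndarray:
    """Ratio of scaled supply to scaled demand where raw demand is positive.

    Cells without demand are NaN (undefined, excluded downstream).
    """
    out = np.full(scaled_supply.shape, np.nan)
    has_demand = np.asarray(raw_demand) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.divide(scaled_supply, scaled_demand)
    out[has_demand] = ratio[has_demand]
    return out


@dataclass
class SDGrid:
    """Mean S/D aggregated over 1-km**2 tiles of the reported region."""

    cells: pd.DataFrame  # block_row, block_col, n_cells, ag_fraction, mean_sd, retained
    fraction_ge1: float
    n_retained: int
    n_no_data: int = 0

    @property
    def pct_ge1(self) -> float:
        return 100.0 * self.fraction_ge1


def aggregate_sd(
    sd: np.ndarray,
    lulc: LULCMap,
    ag_mask: np.ndarray,
    cell_km: float = 1.0,
    min_overlap: float = 0.25,
) -> SDGrid:
    """Tile the non-buffer extent into ``cell_km``-km squares and average S/D.

    Tiles are anchored at the reported region's origin; a tile is retained if
    at least ``min_overlap`` of its cells are agricultural.  Retained tiles
    with no defined S/D cells are excluded from the >= 1 percentage's
    denominator (and counted in ``n_no_data``).
    """
    grid = lulc.grid
    core = lulc.core_mask
    b = lulc.buffer_cells
    size_m = cell_km * 1000.0
    rows = np.arange(grid.n_rows) - b
    cols = np.arange(grid.n_cols) - b
    # block index of each core cell, by cell-center offset from the core origin
    br = np.floor(((rows + 0.5) * grid.resolution) / size_m).astype(int)
    bc = np.floor(((cols + 0.5) * grid.resolution) / size_m).astype(int)
    BR, BC = np.meshgrid(br, bc, indexing="ij")
    nbr = br[core.any(axis=1)].max() + 1
    nbc = bc[core.any(axis=0)].max() + 1
    flat = (BR * nbc + BC)[core]
    nblocks = nbr * nbc

    n_cells = np.bincount(flat, minlength=nblocks)
    n_ag = np.bincount(flat, weights=np.asarray(ag_mask, dtype=float)[core], minlength=nblocks)
    sd_core = sd[core]
    defined = np.isfinite(sd_core)
    n_def = np.bincount(flat[defined], minlength=nblocks)
    sum_sd = np.bincount(flat[defined], weights=sd_core[defined], minlength=nblocks)

    with np.errstate(invalid="ignore", divide="ignore"):
        ag_fraction = np.where(n_cells > 0, n_ag / np.maximum(n_cells, 1), 0.0)
        mean_sd = np.where(n_def > 0, sum_sd / np.maximum(n_def, 1), np.nan)

    occupied = n_cells > 0
    retained = occupied & (ag_fraction >= min_overlap)
    if not retained.any():
        raise ValueError("no 1-km cells overlap the agricultural region enough")
    with_data = retained & (n_def > 0)
    n_no_data = int(retained.sum() - with_data.sum())
    if with_data.sum() == 0:
        raise ValueError("no retained 1-km cells contain defined S/D values")
    frac = float((mean_sd[with_data] >= 1.0).sum() / with_data.sum())

    idx = np.nonzero(occupied)[0]
    cells = pd.DataFrame(
        {
            "block_row": idx // nbc,
            "block_col": idx % nbc,
            "n_cells": n_cells[idx],
            "ag_fraction": ag_fraction[idx],
            "mean_sd": mean_sd[idx],
            "retained": retained[idx],
        }
    )
    return SDGrid(
        cells=cells,
        fraction_ge1=frac,
        n_retained=int(retained.sum()),
        n_no_data=n_no_data,
    )


# ---------------------------------------------------------------------------
# Scenario comparison


@dataclass
class ScenarioAssessment:
    """Per-scenario evaluation summary used by :func:`compare_scenarios`."""

    name: str
    sd_pct_ge1: float
    priority: PriorityRanking
    reforested_ha: float = 0.0
    strips_ha: float = 0.0
    restored_fraction: float = 0.0


def compare_scenarios(
    assessments: list[ScenarioAssessment], baseline_name: str = "no_restoration"
) -> pd.DataFrame:
    """Summary table: S/D >= 1 percentage, delta vs. baseline, priority mix.

    The demand map is shared across scenarios by construction, so differences
    are attributable to the supply side and to natural-cover gains.
    """
    by_name = {a.name: a for a in assessments}
    if baseline_name not in by_name:
        raise ValueError(f"baseline scenario {baseline_name!r} missing")
    base = by_name[baseline_name]
    rows = []
    for a in assessments:
        row = {
            "scenario": a.name,
            "reforested_ha": round(a.reforested_ha, 3),
            "strips_ha": round(a.strips_ha, 3),
            "restored_pct_territory": round(100.0 * a.restored_fraction, 3),
            "sd_pct_ge1": round(a.sd_pct_ge1, 3),
            "delta_sd_pct_ge1": round(a.sd_pct_ge1 - base.sd_pct_ge1, 3),
        }
        for lab in PRIORITY_LABELS:
            row[f"pct_{lab}_priority"] = round(a.priority.pct(lab), 3)
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")
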