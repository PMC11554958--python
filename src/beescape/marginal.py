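"""Identification of marginal agricultural land.

Two filters define marginal fields:

* **Abandoned** — no declared cultivation in each of the final five years of
  the field's history (a five-year cut-off avoids flagging ordinary fallow).
  Fields already mapped as old field / shrubland are excluded, since those
  are considered regenerating habitat rather than restorable cropland.
* **Degraded** — a pixel-wise ordinary-least-squares regression of annual
  NDVI on year, over a multi-decade stack, flags pixels with a significant
  (p <= 0.05) negative trend; edge pixels (one 30-m ring, ~25 m) are removed
  along field borders, surviving patches smaller than 0.15 ha are dropped,
  and a field whose remaining flagged patches cover >= 30% of its full area
  is classed as degraded in its entirety.

No multiple-testing correction is applied to the per-pixel p-values; the
trend filter is a screening rule, not an inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, stats

from .grid import FieldRegistry, LULCMap

__all__ = [
    "TrendResult",
    "MarginalLandReport",
    "detect_abandoned",
    "fit_ndvi_trend",
    "degraded_pixel_mask",
    "filter_patches",
    "classify_degraded_fields",
    "find_marginal_lands",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class TrendResult:
    """Per-cell OLS trend of NDVI on year index.

    ``slope``/``p_value`` are NaN outside the fitted mask or where fewer than
    3 years were available; ``n_years`` counts the years used per cell.
    """

    slope: np.ndarray
    p_value: np.ndarray
    n_years: np.ndarray
    n_undefined: int = 0


@dataclass
class MarginalLandReport:
    """Outcome of the marginal-land screening."""

    abandoned_ids: list[int]
    degraded_ids: list[int]
    degraded_pixel_mask: np.ndarray
    total_abandoned_ha: float
    total_degraded_ha: float
    excluded_old_field_ids: list[int] = dc_field(default_factory=list)

    @property
    def marginal_ids(self) -> list[int]:
        return sorted(set(self.abandoned_ids) | set(self.degraded_ids))


def detect_abandoned(
    registry: FieldRegistry,
    window: int = 5,
    excluded_ids: frozenset[int] | set[int] = frozenset(),
) -> set[int]:
    """Fields uncultivated in each of the final ``window`` years.

    The rule only looks at the terminal window: a field cultivated in the
    most recent year is never abandoned regardless of earlier gaps.
    ``excluded_ids`` removes fields already mapped as old field / shrubland.
    """
    if not len(registry):
        return set()
    last = max(registry.years)
    target_years = list(range(last - window + 1, last + 1))
    out: set[int] = set()
    for f in registry:
        missing = [y for y in target_years if y not in f.history]
        if missing:
            raise ValueError(
                f"field {f.field_id}: history missing years {missing} in the "
                f"final {window}-year window"
            )
        if f.field_id in excluded_ids:
            continue
        if all(not f.history[y][0] for y in target_years):
            out.add(f.field_id)
    return out


def fit_ndvi_trend(ndvi: np.ndarray, mask: np.ndarray | None = None) -> TrendResult:
    """Pixel-wise OLS of NDVI versus year index with a two-sided t-test.

    ``ndvi`` is (n_years, n_rows, n_cols); NaN entries are treated as missing
    years.  The p-value comes from the slope t statistic on n-2 degrees of
    freedom.  A perfectly constant series gets slope 0 and p = 1 (a
    residual-free zero-slope fit carries no evidence of decline); a perfect
    non-constant line gets p = 0.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    n_years_total, n_rows, n_cols = ndvi.shape
    if mask is None:
        mask = np.ones((n_rows, n_cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    t = np.arange(n_years_total, dtype=float)[:, None, None]
    valid = ~np.isnan(ndvi)
    n = valid.sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        tw = np.where(valid, t, 0.0)
        yw = np.where(valid, ndvi, 0.0)
        t_mean = tw.sum(axis=0) / n
        y_mean = yw.sum(axis=0) / n
        t_dev = np.where(valid, t - t_mean, 0.0)
        sxx = (t_dev**2).sum(axis=0)
        sxy = (t_dev * (yw - np.where(valid, y_mean, 0.0))).sum(axis=0)
        slope = sxy / sxx
        intercept = y_mean - slope * t_mean
        resid = np.where(valid, ndvi - (intercept + slope * t), 0.0)
        sse = (resid**2).sum(axis=0)
        dof = n - 2
        se = np.sqrt(sse / dof / sxx)
        tstat = slope / se
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(dof, 1))
    # degenerate residual-free fits: flat series carry no evidence (p = 1),
    # a perfect sloped line is maximal evidence (p = 0)
    zero_resid = se == 0
    p = np.where(zero_resid & (slope == 0), 1.0, p)
    p = np.where(zero_resid & (slope != 0), 0.0, p)

    defined = mask & (n >= 3) & (sxx > 0)
    n_undefined = int((mask & ~defined).sum())
    if n_undefined:
        warnings.warn(
            f"{n_undefined} cells had fewer than 3 NDVI years and were left undefined",
            stacklevel=2,
        )
    slope = np.where(defined, slope, np.nan)
    p = np.where(defined, p, np.nan)
    return TrendResult(
        slope=slope,
        p_value=np.clip(p, 0.0, 1.0),
        n_years=np.where(mask, n, 0).astype(int),
        n_undefined=n_undefined,
    )


def _field_interior(labels: np.ndarray) -> np.ndarray:
    """Cells whose full 3x3 neighbourhood lies in the same field (one-ring
    erosion from field borders; at 30-m cells this removes the ~25-m edge)."""
    return (
        (ndimage.minimum_filter(labels, size=3, mode="constant", cval=0) == labels)
        & (ndimage.maximum_filter(labels, size=3, mode="constant", cval=0) == labels)
        & (labels > 0)
    )


def degraded_pixel_mask(
    trend: TrendResult,
    labels: np.ndarray,
    p_max: float = 0.05,
    erosion_cells: int = 1,
) -> np.ndarray:
    """Binary raster of significant negative-trend pixels inside field cores.

    A pixel is flagged iff slope < 0, p <= ``p_max`` and it survives an
    ``erosion_cells``-ring erosion inward from its field's boundary.
    """
    with np.errstate(invalid="ignore"):
        flagged = (trend.slope < 0) & (trend.p_value <= p_max)
    interior = labels > 0
    for _ in range(erosion_cells):
        interior = _field_interior(np.where(interior, labels, 0))
    return (flagged & interior).astype(np.uint8)


def filter_patches(
    mask: np.ndarray,
    cell_area_ha: float,
    min_area_ha: float = 0.15,
    connectivity: int = 8,
) -> np.ndarray:
    """Remove connected patches smaller than ``min_area_ha``.

    8-neighbour connectivity by default (diagonal-touching cells form one
    patch); patches of area >= the threshold pass through untouched.
    """
    structure = _EIGHT if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    lab, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    if n == 0:
        return np.zeros_like(lab, dtype=np.uint8)
    sizes = np.bincount(lab.ravel())
    keep = sizes * cell_area_ha >= min_area_ha - 1e-12
    keep[0] = False
    return keep[lab].astype(np.uint8)


def classify_degraded_fields(
    filtered_mask: np.ndarray,
    labels: np.ndarray,
    registry: FieldRegistry,
    cell_area_ha: float,
    fraction: float = 0.30,
) -> set[int]:
    """Fields whose flagged patches cover at least ``fraction`` of the field.

    The fraction is computed against the full (pre-erosion) field area; the
    30% boundary is inclusive.
    """
    n = int(labels.max(initial=0)) + 1
    flagged = np.bincount(labels[np.asarray(filtered_mask, dtype=bool)], minlength=n)
    out: set[int] = set()
    for f in registry:
        if f.field_id >= n:
            continue
        ratio = flagged[f.field_id] * cell_area_ha / f.area_ha
        if ratio >= fraction - 1e-9:
            out.add(f.field_id)
    return out


def find_marginal_lands(
    lulc: LULCMap,
    registry: FieldRegistry,
    labels: np.ndarray,
    ndvi: np.ndarray,
    window: int = 5,
    p_max: float = 0.05,
    min_patch_ha: float = 0.15,
    degraded_fraction: float = 0.30,
    connectivity: int = 8,
) -> MarginalLandReport:
    """Run the full abandoned + degraded screening on one landscape.

    Fields whose modal land-cover class is old field / shrubland are excluded
    from the abandonment rule (already regenerating habitat).
    """
    old_field = {
        cid for cid, cls in lulc.classes.items() if cls.name == "old_field_shrubland"
    }
    excluded: set[int] = set()
    if old_field:
        for f in registry:
            cells = lulc.codes[labels == f.field_id]
            if cells.size and np.isin(cells, list(old_field)).mean() > 0.5:
                excluded.add(f.field_id)

    abandoned = detect_abandoned(registry, window=window, excluded_ids=excluded)

    ag_mask = labels > 0
    trend = fit_ndvi_trend(ndvi, ag_mask)
    raw = degraded_pixel_mask(trend, labels, p_max=p_max)
    cell_ha = lulc.grid.cell_area_ha
    filtered = filter_patches(
        raw, cell_ha, min_area_ha=min_patch_ha, connectivity=connectivity
    )
    degraded = classify_degraded_fields(
        filtered, labels, registry, cell_ha, fraction=degraded_fraction
    )
    # pixels of fields that failed the 30% rule contribute nothing downstream
    keep = np.isin(labels, sorted(degraded)) if degraded else np.zeros_like(ag_mask)
    final_mask = (filtered.astype(bool) & keep).astype(np.uint8)

    return MarginalLandReport(
        abandoned_ids=sorted(abandoned),
        degraded_ids=sorted(degraded),
        degraded_pixel_mask=final_mask,
        total_abandoned_ha=sum(registry[i].area_ha for i in abandoned),
        total_degraded_ha=sum(registry[i].area_ha for i in degraded),
        excluded_old_field_ids=sorted(excluded),
    )
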