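"""Synthetic-landscape generator with known ground truth.

Emulates an intensive northeastern-American agricultural county: ~60% of the
territory in cultivation, long narrow fields (rang-style parcels averaging
6.2 +/- 7.1 ha), a corn/soy-dominated crop mix with a minority of
pollinator-dependent crops, clustered abandoned fields with >=5 trailing
uncultivated years, and a multi-decade annual NDVI stack in which planted
"degraded" fields carry a linear decline while all other farmland is
trend-free noise.

Every stochastic choice flows from ``SynthConfig.seed`` through independent
``numpy`` substreams keyed by (seed, component, field_id), so regenerating a
bundle is deterministic and per-field draws are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter, minimum_filter
from shapely.geometry import box

from .grid import (
    FieldRecord,
    FieldRegistry,
    LandscapeGrid,
    LULCMap,
    default_class_table,
)

__all__ = ["SynthConfig", "LandscapeBundle", "generate_landscape", "generate_ndvi_series"]

#: crop_code -> (sampling frequency, pollination-dependency class)
DEFAULT_CROP_MIX: dict[str, tuple[float, str]] = {
    "corn": (0.40, "none"),
    "soy": (0.30, "none"),
    "cereal": (0.10, "none"),
    "hay": (0.05, "none"),
    "canola": (0.04, "great"),
    "vegetables": (0.05, "modest"),
    "berries": (0.03, "great"),
    "orchard": (0.03, "essential"),
}

#: typical growing-season NDVI baseline per land-cover class name
_NDVI_BASELINE = {
    "crop_no_resources": 0.75,
    "crop_with_resources": 0.75,
    "ag_non_cultivated": 0.7,
    "forest": 0.85,
    "wetland": 0.7,
    "old_field_shrubland": 0.8,
    "flower_strip": 0.8,
    "impervious": 0.25,
    "urban_vegetation": 0.6,
    "open_water": 0.05,
    "bare_ground": 0.15,
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the generated study region.

    Cover fractions refer to the reported (non-buffer) territory; the
    remainder after all listed fractions becomes open water / bare ground.
    ``ndvi_decline_per_year`` is the slope planted in degraded fields
    (negative, NDVI units per year).
    """

    seed: int = 0
    extent_km: tuple[float, float] = (6.0, 6.0)
    resolution: float = 30.0
    analysis_buffer_m: float = 2000.0
    fraction_agricultural: float = 0.60
    fraction_forest: float = 0.17
    fraction_wetland: float = 0.02
    fraction_builtup: float = 0.15
    fraction_old_field: float = 0.03
    field_area_mean_ha: float = 6.2
    field_area_sd_ha: float = 7.1
    crop_mix: Mapping[str, tuple[float, str]] = dc_field(
        default_factory=lambda: dict(DEFAULT_CROP_MIX)
    )
    n_years_history: int = 10
    history_end_year: int = 2021
    n_years_ndvi: int = 22
    ndvi_end_year: int = 2021
    n_abandoned_fields: int = 15
    n_degraded_fields: int = 5
    abandoned_area_cap_fraction: float = 0.024
    degraded_area_cap_fraction: float = 0.009
    ndvi_decline_per_year: float = -0.01
    ndvi_noise_sd: float = 0.02
    noise_sigma_cells: float = 30.0

    def __post_init__(self) -> None:
        fr = (
            self.fraction_agricultural
            + self.fraction_forest
            + self.fraction_wetland
            + self.fraction_builtup
            + self.fraction_old_field
        )
        if min(
            self.fraction_agricultural,
            self.fraction_forest,
            self.fraction_wetland,
            self.fraction_builtup,
            self.fraction_old_field,
        ) < 0 or fr > 1 + 1e-9:
            raise ValueError("cover fractions must be >= 0 and sum to <= 1")
        if self.n_years_ndvi < 3:
            raise ValueError("NDVI trend regression needs at least 3 years")
        if self.ndvi_noise_sd < 0:
            raise ValueError("ndvi_noise_sd must be non-negative")


@dataclass
class LandscapeBundle:
    """A generated landscape plus the planted ground truth."""

    lulc: LULCMap
    registry: FieldRegistry
    labels: np.ndarray  # field_id per cell, 0 outside fields
    ndvi: np.ndarray  # (n_years, n_rows, n_cols)
    ndvi_years: list[int]
    truth_abandoned: list[int]
    truth_degraded: list[int]


def generate_ndvi_series(
    n_years: int, baseline: float, slope: float, noise_sd: float, seed: int
) -> np.ndarray:
    """Annual NDVI values ``baseline + slope * t + N(0, noise_sd)``."""
    if n_years < 3:
        raise ValueError("need at least 3 years")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years, dtype=float)
    series = baseline + slope * t
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, n_years)
    return series


def _split_bands(n_rows: int, n_cols: int, rng: np.random.Generator, cfg: SynthConfig):
    """Tile the core extent into grid-aligned rectangular parcels.

    Vertical bands 3-5 cells (90-150 m) wide are cut lengthwise into parcels
    whose target areas are drawn from a log-normal matched to the configured
    field-size mean and SD; cut lines snap to cell edges so parcel polygons
    rasterize exactly.
    """
    mean, sd = cfg.field_area_mean_ha, cfg.field_area_sd_ha
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    cell_ha = cfg.resolution**2 / 10_000.0
    rects = []  # (r0, r1, c0, c1) half-open cell index ranges
    c = 0
    while c < n_cols:
        w = min(int(rng.integers(3, 6)), n_cols - c)
        r = 0
        while r < n_rows:
            target_ha = float(np.clip(rng.lognormal(mu, np.sqrt(sigma2)), 0.7, 40.0))
            length = max(2, int(round(target_ha / (w * cell_ha))))
            length = min(length, n_rows - r)
            if n_rows - (r + length) < 2:  # avoid sliver remainders
                length = n_rows - r
            rects.append((r, r + length, c, c + w))
            r += length
        c += w
    return rects


def _interior_counts(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-field cell counts (total, surviving a 1-cell erosion), indexed by id."""
    interior = (
        (minimum_filter(labels, size=3, mode="constant", cval=0) == labels)
        & (maximum_filter(labels, size=3, mode="constant", cval=0) == labels)
        & (labels > 0)
    )
    n = int(labels.max(initial=0)) + 1
    total = np.bincount(labels.ravel(), minlength=n)
    inner = np.bincount(labels[interior].ravel(), minlength=n)
    return total, inner


def generate_landscape(config: SynthConfig) -> LandscapeBundle:
    """Build a full landscape bundle with planted ground truth.

    Deterministic per seed.  Parcels tile the agricultural zone; the realized
    agricultural fraction of the territory is within a parcel of the target
    (assignment is by cumulative area along a smoothed spatial gradient, so
    the error is at most one parcel).
    """
    cfg = config
    res = cfg.resolution
    n_core_r = int(round(cfg.extent_km[1] * 1000.0 / res))
    n_core_c = int(round(cfg.extent_km[0] * 1000.0 / res))
    b = int(round(cfg.analysis_buffer_m / res))
    n_rows, n_cols = n_core_r + 2 * b, n_core_c + 2 * b
    grid = LandscapeGrid(
        origin_x=0.0,
        origin_y=n_rows * res,
        n_rows=n_rows,
        n_cols=n_cols,
        resolution=res,
        crs_tag="synthetic-metric",
    )
    classes = default_class_table()
    by_name = {c.name: c.class_id for c in classes}

    rng_land = np.random.default_rng([cfg.seed, 0])
    # smoothed spatial gradient controlling where each cover type clusters
    noise = gaussian_filter(
        rng_land.standard_normal((n_rows, n_cols)), sigma=cfg.noise_sigma_cells
    )

    rects = _split_bands(n_core_r, n_core_c, rng_land, cfg)
    cell_ha = grid.cell_area_ha
    rect_area = np.array([(r1 - r0) * (c1 - c0) * cell_ha for r0, r1, c0, c1 in rects])
    rect_noise = np.array(
        [noise[b + (r0 + r1) // 2, b + (c0 + c1) // 2] for r0, r1, c0, c1 in rects]
    )
    order = np.argsort(rect_noise, kind="stable")
    core_ha = n_core_r * n_core_c * cell_ha
    # cover types in ascending order along the gradient: built-up at one end,
    # the natural cluster (wetland / old field / forest) at the other
    budget = [
        ("impervious", cfg.fraction_builtup * core_ha),
        ("crop", cfg.fraction_agricultural * core_ha),
        ("wetland", cfg.fraction_wetland * core_ha),
        ("old_field_shrubland", cfg.fraction_old_field * core_ha),
        ("forest", cfg.fraction_forest * core_ha),
    ]
    assignment = np.empty(len(rects), dtype=object)
    bi, acc = 0, 0.0
    for idx in order:
        while bi < len(budget) - 1 and acc >= budget[bi][1] - 1e-9:
            acc = 0.0
            bi += 1
        assignment[idx] = budget[bi][0]
        acc += rect_area[idx]
    # whatever the last budget leaves over becomes open water
    if acc > budget[-1][1]:
        extra = [i for i in order[::-1] if assignment[i] == budget[-1][0]]
        spill = acc - budget[-1][1]
        for i in extra:
            if spill <= 1e-9:
                break
            assignment[i] = "open_water"
            spill -= rect_area[i]

    codes = np.zeros((n_rows, n_cols), dtype=np.int32)
    labels = np.zeros((n_rows, n_cols), dtype=np.int32)

    # buffer ring: same gradient logic, collapsed to crop / forest / old field
    buf_mask = np.ones((n_rows, n_cols), dtype=bool)
    buf_mask[b : b + n_core_r, b : b + n_core_c] = False
    # the ring mirrors the core composition: non-natural matrix (cropland
    # stand-in) below the natural share, forest above it
    bvals = noise[buf_mask]
    f_nat = cfg.fraction_forest + cfg.fraction_wetland + cfg.fraction_old_field
    q_nat = np.quantile(bvals, 1.0 - f_nat)
    buf_codes = np.full(bvals.shape, by_name["crop_no_resources"], dtype=np.int32)
    buf_codes[bvals > q_nat] = by_name["forest"]
    codes[buf_mask] = buf_codes

    # fields and their cultivation histories
    fields: list[FieldRecord] = []
    crop_codes = list(cfg.crop_mix)
    crop_freq = np.array([cfg.crop_mix[c][0] for c in crop_codes], dtype=float)
    crop_freq = crop_freq / crop_freq.sum()
    dependent = {c for c in crop_codes if cfg.crop_mix[c][1] != "none"}
    years = list(
        range(cfg.history_end_year - cfg.n_years_history + 1, cfg.history_end_year + 1)
    )
    fid = 0
    for i, (r0, r1, c0, c1) in enumerate(rects):
        rr0, rr1, cc0, cc1 = r0 + b, r1 + b, c0 + b, c1 + b
        kind = assignment[i]
        if kind != "crop":
            codes[rr0:rr1, cc0:cc1] = by_name[kind]
            continue
        fid += 1
        rng_f = np.random.default_rng([cfg.seed, 1, fid])
        hist = {
            y: (True, crop_codes[int(rng_f.choice(len(crop_codes), p=crop_freq))])
            for y in years
        }
        main = max(
            (c for c in crop_codes),
            key=lambda c: sum(1 for y in years if hist[y][1] == c),
        )
        cid = by_name["crop_with_resources" if main in dependent else "crop_no_resources"]
        codes[rr0:rr1, cc0:cc1] = cid
        labels[rr0:rr1, cc0:cc1] = fid
        minx, maxy = grid.origin_x + cc0 * res, grid.origin_y - rr0 * res
        maxx, miny = grid.origin_x + cc1 * res, grid.origin_y - rr1 * res
        poly = box(minx, miny, maxx, maxy)
        fields.append(
            FieldRecord(
                field_id=fid,
                polygon=poly,
                area_ha=poly.area / 10_000.0,
                history=hist,
            )
        )

    n_fields = len(fields)
    if cfg.n_abandoned_fields + cfg.n_degraded_fields > n_fields:
        raise ValueError(
            f"cannot plant {cfg.n_abandoned_fields} abandoned + "
            f"{cfg.n_degraded_fields} degraded fields among {n_fields} fields"
        )

    rng_truth = np.random.default_rng([cfg.seed, 2])
    by_id = {f.field_id: f for f in fields}

    # abandoned fields: a spatial cluster around a randomly drawn seed field,
    # grown until the configured count or the territory-share cap is reached
    # (abandoned land is a small, clustered share of such regions)
    territory_ha = core_ha
    truth_abandoned: list[int] = []
    if cfg.n_abandoned_fields > 0:
        seed_fid = int(rng_truth.choice([f.field_id for f in fields]))
        cx, cy = by_id[seed_fid].centroid
        ranked = sorted(
            fields,
            key=lambda f: (f.centroid[0] - cx) ** 2 + (f.centroid[1] - cy) ** 2,
        )
        cap = cfg.abandoned_area_cap_fraction * territory_ha
        picked, acc_ha = [], 0.0
        for f in ranked:
            if len(picked) >= cfg.n_abandoned_fields:
                break
            if picked and acc_ha + f.area_ha > cap:
                continue
            picked.append(f.field_id)
            acc_ha += f.area_ha
        truth_abandoned = sorted(picked)
        for fi in truth_abandoned:
            f = by_id[fi]
            for y in years[-5:]:
                f.history[y] = (False, "")
            f.abandoned = True

    # degraded fields: enough eroded interior that >=30% of the field area
    # can carry a detectable declining patch
    truth_degraded: list[int] = []
    if cfg.n_degraded_fields > 0:
        total, inner = _interior_counts(labels)
        eligible = [
            f.field_id
            for f in fields
            if f.field_id not in truth_abandoned
            and inner[f.field_id] / total[f.field_id] >= 0.35
            and inner[f.field_id] * cell_ha >= 0.15
        ]
        if len(eligible) < cfg.n_degraded_fields:
            raise ValueError(
                f"only {len(eligible)} fields are large enough to plant "
                f"{cfg.n_degraded_fields} degraded fields"
            )
        shuffled = rng_truth.permutation(eligible)
        cap = cfg.degraded_area_cap_fraction * territory_ha
        picked, acc_ha = [], 0.0
        for fi in shuffled:
            if len(picked) >= cfg.n_degraded_fields:
                break
            f = by_id[int(fi)]
            if picked and acc_ha + f.area_ha > cap:
                continue
            picked.append(int(fi))
            acc_ha += f.area_ha
        truth_degraded = sorted(picked)
        for fi in truth_degraded:
            by_id[fi].degraded = True

    lulc = LULCMap(grid, codes, classes, analysis_buffer_m=cfg.analysis_buffer_m)

    # NDVI stack: class-dependent baseline, planted slope in degraded fields,
    # i.i.d. Gaussian year-to-year noise everywhere
    name_of = {c.class_id: c.name for c in classes}
    baseline = np.vectorize(lambda cid: _NDVI_BASELINE[name_of[cid]])(codes).astype(float)
    slope = np.zeros_like(baseline)
    for fi in truth_degraded:
        slope[labels == fi] = cfg.ndvi_decline_per_year
    t = np.arange(cfg.n_years_ndvi, dtype=float)
    rng_ndvi = np.random.default_rng([cfg.seed, 3])
    ndvi = baseline[None, :, :] + slope[None, :, :] * t[:, None, None]
    if cfg.ndvi_noise_sd > 0:
        ndvi = ndvi + rng_ndvi.normal(0.0, cfg.ndvi_noise_sd, ndvi.shape)
    ndvi_years = list(
        range(cfg.ndvi_end_year - cfg.n_years_ndvi + 1, cfg.ndvi_end_year + 1)
    )

    return LandscapeBundle(
        lulc=lulc,
        registry=FieldRegistry(fields),
        labels=labels,
        ndvi=ndvi,
        ndvi_years=ndvi_years,
        truth_abandoned=truth_abandoned,
        truth_degraded=truth_degraded,
    )
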