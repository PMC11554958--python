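"""Pollination demand: dependency-weighted crop area per field.

A field's demand is its area (ha) times the mean, over the ten-year crop
rotation, of the pollination-dependency weight of that year's main crop.
Dependency classes follow the Klein-style categories (essential / great /
modest / little / none); default weights are the class midpoints.  Years
without cultivation contribute weight zero (fallow land demands no
pollination), and fields flagged abandoned or degraded have demand zero.

The rasterized demand spreads each field's mean annual weight times the cell
area over its cells, so that summing a field's cells recovers the field
total (up to rasterization error); demand depends only on crop histories and
marginal flags, never on the land-cover edits a scenario makes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grid import FieldRecord, FieldRegistry, LandscapeGrid

__all__ = [
    "DEFAULT_CLASS_WEIGHTS",
    "CropDependency",
    "DemandMap",
    "dependency_weight",
    "field_demand",
    "demand_raster",
    "dependency_table_from_crop_mix",
    "read_dependency_table",
    "write_dependency_table",
]

#: class-midpoint weights for the dependency categories
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "essential": 0.95,
    "great": 0.65,
    "modest": 0.25,
    "little": 0.05,
    "none": 0.0,
}


@dataclass(frozen=True)
class CropDependency:
    """Pollination dependency of one crop type."""

    crop_code: str
    dependency_class: str
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.dependency_class not in DEFAULT_CLASS_WEIGHTS:
            raise ValueError(
                f"{self.crop_code}: unknown dependency class {self.dependency_class!r}"
            )
        if self.weight is not None and not 0 <= self.weight <= 1:
            raise ValueError(f"{self.crop_code}: weight outside [0, 1]")

    @property
    def effective_weight(self) -> float:
        if self.weight is not None:
            return self.weight
        return DEFAULT_CLASS_WEIGHTS[self.dependency_class]


@dataclass
class DemandMap:
    """Per-field demand values and their rasterization."""

    field_values: pd.Series  # index: field_id, value: demand (ha-weighted)
    raster: np.ndarray
    mean_weights: pd.Series = dc_field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def total(self) -> float:
        return float(self.field_values.sum())


def dependency_weight(crop_code: str, table: Mapping[str, CropDependency]) -> float:
    """Weight of one crop; uncultivated years pass the empty string -> 0."""
    if crop_code == "":
        return 0.0
    if crop_code not in table:
        raise KeyError(f"crop code {crop_code!r} not in the dependency table")
    return table[crop_code].effective_weight


def field_demand(
    field: FieldRecord,
    table: Mapping[str, CropDependency],
    marginal_ids: Iterable[int] = (),
) -> float:
    """Mean annual dependency weight over the rotation, times field area.

    Returns 0 for abandoned/degraded fields (no pollination need for food
    production is assumed there).
    """
    if field.field_id in set(marginal_ids):
        return 0.0
    if not field.history:
        return 0.0
    weights = [
        dependency_weight(crop if cultivated else "", table)
        for cultivated, crop in field.history.values()
    ]
    return field.area_ha * float(np.mean(weights))


def demand_raster(
    registry: FieldRegistry,
    grid: LandscapeGrid,
    labels: np.ndarray,
    table: Mapping[str, CropDependency],
    marginal_ids: Iterable[int] = (),
) -> DemandMap:
    """Rasterize per-field demand: cell value = mean annual weight x cell area."""
    marginal = set(marginal_ids)
    cell_ha = grid.cell_area_ha
    values, weights = {}, {}
    max_id = int(labels.max(initial=0))
    lut = np.zeros(max_id + 1, dtype=float)
    for f in registry:
        d = field_demand(f, table, marginal)
        values[f.field_id] = d
        w = d / f.area_ha if f.area_ha > 0 else 0.0
        weights[f.field_id] = w
        if f.field_id <= max_id:
            lut[f.field_id] = w * cell_ha
    raster = lut[np.clip(labels, 0, max_id)]
    return DemandMap(
        field_values=pd.Series(values, name="demand").sort_index(),
        raster=raster,
        mean_weights=pd.Series(weights, name="mean_weight").sort_index(),
    )


def dependency_table_from_crop_mix(
    crop_mix: Mapping[str, tuple[float, str]],
) -> dict[str, CropDependency]:
    """Build a dependency table from a synthetic crop mix specification."""
    return {
        code: CropDependency(code, dep_class)
        for code, (_freq, dep_class) in crop_mix.items()
    }


def write_dependency_table(
    table: Mapping[str, CropDependency], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["crop_code", "class", "weight"])
        for dep in table.values():
            w.writerow([dep.crop_code, dep.dependency_class, dep.effective_weight])


def read_dependency_table(path: str | Path) -> dict[str, CropDependency]:
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["crop_code"]] = CropDependency(
                row["crop_code"], row["class"], float(row["weight"])
            )
    return out
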