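"""Core spatial data model: analysis grid, categorical land-cover raster with
class semantics, crop-field registry, rasterization and plain-text I/O.

The grid is a north-up regular raster in a projected (metric) coordinate
system.  Row 0 is the northernmost row; the cell (r, c) has its center at
``(origin_x + (c + 0.5) * res, origin_y - (r + 0.5) * res)`` where
``(origin_x, origin_y)`` is the upper-left corner of the raster.

Rasters are exchanged as ESRI ASCII grids (.asc), class tables and field
histories as CSV, and field polygons as GeoJSON.  All area accounting is in
hectares; at the default 30-m resolution one cell is 0.09 ha.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, shape, mapping

__all__ = [
    "LandscapeGrid",
    "LULCClass",
    "LULCMap",
    "FieldRecord",
    "FieldRegistry",
    "SUITABILITY_LEVELS",
    "rasterize_fields",
    "reclassify",
    "natural_mask",
    "default_class_table",
    "read_class_table",
    "write_class_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_lulc",
    "read_lulc",
    "write_registry",
    "read_registry",
]

#: Discrete relative-suitability levels used for nesting and floral scores.
SUITABILITY_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class LandscapeGrid:
    """Regular north-up raster grid in a projected metric CRS."""

    origin_x: float
    origin_y: float
    n_rows: int
    n_cols: int
    resolution: float = 30.0
    crs_tag: str = "local-metric"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_ha(self) -> float:
        return self.resolution**2 / 10_000.0

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        res = self.resolution
        return (self.origin_x + (c + 0.5) * res, self.origin_y - (r + 0.5) * res)

    def x_centers(self) -> np.ndarray:
        res = self.resolution
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * res

    def y_centers(self) -> np.ndarray:
        res = self.resolution
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * res

    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the raster extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.resolution,
            self.origin_x + self.n_cols * self.resolution,
            self.origin_y,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y); half-open cells."""
        c = int(math.floor((x - self.origin_x) / self.resolution))
        r = int(math.floor((self.origin_y - y) / self.resolution))
        return r, c


@dataclass(frozen=True)
class LULCClass:
    """One land-use/land-cover class with its semantics for the analysis.

    ``nesting_suitability`` maps nesting substrate (e.g. ``ground``,
    ``cavity``, ``stem``) to a discrete suitability level, and
    ``floral_availability`` maps season (``spring``, ``summer``) likewise.
    """

    class_id: int
    name: str
    is_natural: bool = False
    is_agricultural: bool = False
    is_cultivated: bool = False
    nesting_suitability: Mapping[str, float] = field(default_factory=dict)
    floral_availability: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.nesting_suitability, self.floral_availability):
            for key, v in table.items():
                if not any(abs(v - lv) < 1e-12 for lv in SUITABILITY_LEVELS):
                    raise ValueError(
                        f"class {self.class_id!r}: suitability {key}={v} not in "
                        f"{SUITABILITY_LEVELS}"
                    )


class LULCMap:
    """Categorical land-cover raster plus its class table.

    A border ring of ``analysis_buffer_m`` meters participates in kernel and
    focal computations but is excluded from reported areas and statistics;
    :attr:`core_mask` flags the interior (reported) region.
    """

    def __init__(
        self,
        grid: LandscapeGrid,
        codes: np.ndarray,
        class_table: Iterable[LULCClass],
        analysis_buffer_m: float = 2000.0,
    ) -> None:
        codes = np.asarray(codes, dtype=np.int32)
        if codes.shape != grid.shape:
            raise ValueError(f"codes shape {codes.shape} != grid shape {grid.shape}")
        self.grid = grid
        self.codes = codes
        self.classes: dict[int, LULCClass] = {c.class_id: c for c in class_table}
        self.analysis_buffer_m = float(analysis_buffer_m)
        unknown = set(np.unique(codes).tolist()) - set(self.classes)
        if unknown:
            raise ValueError(f"codes {sorted(unknown)} missing from class table")

    @property
    def buffer_cells(self) -> int:
        return int(round(self.analysis_buffer_m / self.grid.resolution))

    @property
    def core_mask(self) -> np.ndarray:
        """Boolean raster, True inside the reported (non-buffer) region."""
        b = self.buffer_cells
        m = np.zeros(self.grid.shape, dtype=bool)
        if 2 * b >= min(self.grid.n_rows, self.grid.n_cols):
            raise ValueError("analysis buffer swallows the whole grid")
        m[b : self.grid.n_rows - b, b : self.grid.n_cols - b] = True
        return m

    @property
    def territory_ha(self) -> float:
        """Area of the reported region (buffer excluded)."""
        return float(self.core_mask.sum()) * self.grid.cell_area_ha

    def class_lookup(self, fn) -> np.ndarray:
        """Map ``fn(LULCClass) -> float`` over the raster via the class table."""
        max_code = int(self.codes.max(initial=0))
        lut = np.zeros(max_code + 1, dtype=float)
        for cid, cls in self.classes.items():
            if cid <= max_code:
                lut[cid] = fn(cls)
        return lut[self.codes]

    def copy(self) -> "LULCMap":
        return LULCMap(
            self.grid, self.codes.copy(), self.classes.values(), self.analysis_buffer_m
        )

    def area_ha(self, predicate) -> float:
        """Total core area of cells whose class satisfies ``predicate``."""
        sel = self.class_lookup(lambda c: 1.0 if predicate(c) else 0.0) > 0
        return float((sel & self.core_mask).sum()) * self.grid.cell_area_ha


@dataclass
class FieldRecord:
    """One crop field: polygon, area and 10-year cultivation history.

    ``history`` maps year -> (cultivated, crop_code); ``crop_code`` is the
    main crop declared that year (empty string when uncultivated).
    """

    field_id: int
    polygon: Polygon
    area_ha: float
    history: dict[int, tuple[bool, str]] = field(default_factory=dict)
    abandoned: bool = False
    degraded: bool = False

    def __post_init__(self) -> None:
        if self.field_id <= 0:
            raise ValueError("field_id must be a positive integer")
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError(f"field {self.field_id}: invalid polygon")
        geom_ha = self.polygon.area / 10_000.0
        if geom_ha > 0 and abs(self.area_ha - geom_ha) > 0.001 * geom_ha:
            raise ValueError(
                f"field {self.field_id}: area_ha={self.area_ha:.4f} differs from "
                f"polygon area {geom_ha:.4f} by more than 0.1%"
            )
        if self.history:
            years = sorted(self.history)
            if years != list(range(years[0], years[-1] + 1)):
                raise ValueError(f"field {self.field_id}: history years not contiguous")

    @property
    def centroid(self) -> tuple[float, float]:
        p = self.polygon.centroid
        return (p.x, p.y)


class FieldRegistry:
    """Collection of crop fields with unique ids and non-overlapping polygons."""

    def __init__(self, fields: Iterable[FieldRecord], validate_overlap: bool = False):
        self._fields: dict[int, FieldRecord] = {}
        for f in fields:
            if f.field_id in self._fields:
                raise ValueError(f"duplicate field_id {f.field_id}")
            self._fields[f.field_id] = f
        if validate_overlap:
            self._check_overlaps()

    def _check_overlaps(self) -> None:
        recs = list(self._fields.values())
        tree = shapely.STRtree([f.polygon for f in recs])
        for i, f in enumerate(recs):
            for j in tree.query(f.polygon, predicate="intersects"):
                if j <= i:
                    continue
                inter = f.polygon.intersection(recs[j].polygon)
                if inter.area > 1e-6:
                    raise ValueError(
                        f"fields {f.field_id} and {recs[j].field_id} overlap"
                    )

    def __len__(self) -> int:
        return len(self._fields)

    def __iter__(self) -> Iterator[FieldRecord]:
        return iter(sorted(self._fields.values(), key=lambda f: f.field_id))

    def __contains__(self, field_id: int) -> bool:
        return field_id in self._fields

    def __getitem__(self, field_id: int) -> FieldRecord:
        return self._fields[field_id]

    @property
    def ids(self) -> list[int]:
        return sorted(self._fields)

    @property
    def years(self) -> list[int]:
        """Union of history years across fields (sorted)."""
        ys: set[int] = set()
        for f in self._fields.values():
            ys.update(f.history)
        return sorted(ys)

    @property
    def total_area_ha(self) -> float:
        return sum(f.area_ha for f in self._fields.values())


# ---------------------------------------------------------------------------
# Raster operations


def rasterize_fields(registry: FieldRegistry, grid: LandscapeGrid) -> np.ndarray:
    """Label raster: each cell carries the field_id whose polygon covers the
    cell center, 0 elsewhere.  Cell membership is by center containment.
    """
    labels = np.zeros(grid.shape, dtype=np.int32)
    gminx, gminy, gmaxx, gmaxy = grid.bounds()
    res = grid.resolution
    for f in registry:
        minx, miny, maxx, maxy = f.polygon.bounds
        if minx < gminx - 1e-9 or miny < gminy - 1e-9 or maxx > gmaxx + 1e-9 or maxy > gmaxy + 1e-9:
            raise ValueError(f"field {f.field_id} extends outside the grid bounds")
        c0 = max(0, int(math.floor((minx - gminx) / res)))
        c1 = min(grid.n_cols - 1, int(math.floor((maxx - gminx) / res)))
        r0 = max(0, int(math.floor((gmaxy - maxy) / res)))
        r1 = min(grid.n_rows - 1, int(math.floor((gmaxy - miny) / res)))
        if c1 < c0 or r1 < r0:
            continue
        xs = gminx + (np.arange(c0, c1 + 1) + 0.5) * res
        ys = gmaxy - (np.arange(r0, r1 + 1) + 0.5) * res
        xx, yy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(f.polygon, xx.ravel(), yy.ravel()).reshape(xx.shape)
        sub = labels[r0 : r1 + 1, c0 : c1 + 1]
        sub[inside] = f.field_id
    return labels


def reclassify(
    lulc: LULCMap, changes: Sequence[tuple[np.ndarray, int]]
) -> LULCMap:
    """Return a new map with the selected cells reassigned.

    ``changes`` is a sequence of (boolean selector raster, target class_id)
    pairs, applied in order; the class table is shared, never altered.
    """
    codes = lulc.codes.copy()
    for sel, target in changes:
        if target not in lulc.classes:
            raise KeyError(f"target class_id {target} not in class table")
        sel = np.asarray(sel, dtype=bool)
        if sel.shape != codes.shape:
            raise ValueError("selector shape does not match the raster")
        codes[sel] = target
    return LULCMap(lulc.grid, codes, lulc.classes.values(), lulc.analysis_buffer_m)


def natural_mask(lulc: LULCMap) -> np.ndarray:
    """Binary raster: 1 where the cell's class is (semi-)natural habitat."""
    return (lulc.class_lookup(lambda c: 1.0 if c.is_natural else 0.0) > 0).astype(
        np.uint8
    )


# ---------------------------------------------------------------------------
# Default class table

_NEST_SUBSTRATES = ("ground", "cavity", "stem")
_SEASONS = ("spring", "summer")


def default_class_table() -> list[LULCClass]:
    """Illustrative class table for an intensive northeastern-American
    agricultural landscape (corn/soy matrix with forest remnants).

    Natural habitat comprises forests, wetlands, old fields / shrublands and
    flower strips.  Suitability scores use the discrete relative levels
    0/0.25/0.5/0.75/1 and follow the usual pattern: forests nest-rich but
    forage-poor, flower strips forage-rich with some ground nesting.
    """

    def cls(cid, name, nat=False, ag=False, cult=False, nest=(), floral=()):
        return LULCClass(
            cid,
            name,
            is_natural=nat,
            is_agricultural=ag,
            is_cultivated=cult,
            nesting_suitability=dict(zip(_NEST_SUBSTRATES, nest or (0, 0, 0))),
            floral_availability=dict(zip(_SEASONS, floral or (0, 0))),
        )

    return [
        cls(10, "crop_no_resources", ag=True, cult=True, nest=(0.25, 0, 0), floral=(0, 0)),
        cls(11, "crop_with_resources", ag=True, cult=True, nest=(0.25, 0, 0), floral=(0.25, 0.5)),
        cls(12, "ag_non_cultivated", ag=True, nest=(0.5, 0.25, 0.25), floral=(0.5, 0.5)),
        cls(20, "forest", nat=True, nest=(0.75, 1.0, 0.75), floral=(0.75, 0.25)),
        cls(21, "wetland", nat=True, nest=(0.5, 0.5, 0.75), floral=(0.5, 0.5)),
        cls(22, "old_field_shrubland", nat=True, nest=(0.75, 0.5, 1.0), floral=(0.75, 0.75)),
        cls(23, "flower_strip", nat=True, nest=(0.5, 0, 0.5), floral=(1.0, 1.0)),
        cls(30, "impervious", floral=(0, 0)),
        cls(31, "urban_vegetation", nest=(0.5, 0.5, 0.5), floral=(0.75, 0.75)),
        cls(40, "open_water"),
        cls(41, "bare_ground", nest=(0.25, 0, 0)),
    ]


FOREST_CLASS_ID = 20
OLD_FIELD_CLASS_ID = 22
FLOWER_STRIP_CLASS_ID = 23


# ---------------------------------------------------------------------------
# I/O: class table CSV


def write_class_table(classes: Iterable[LULCClass], path: str | Path) -> None:
    classes = list(classes)
    substrates = sorted({s for c in classes for s in c.nesting_suitability})
    seasons = sorted({s for c in classes for s in c.floral_availability})
    cols = (
        ["class_id", "name", "is_natural", "is_agricultural", "is_cultivated"]
        + [f"nest_{s}" for s in substrates]
        + [f"floral_{s}" for s in seasons]
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for c in sorted(classes, key=lambda c: c.class_id):
            row = [c.class_id, c.name, int(c.is_natural), int(c.is_agricultural), int(c.is_cultivated)]
            row += [c.nesting_suitability.get(s, 0.0) for s in substrates]
            row += [c.floral_availability.get(s, 0.0) for s in seasons]
            w.writerow(row)


def read_class_table(path: str | Path) -> list[LULCClass]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            nest = {
                k[len("nest_") :]: float(v)
                for k, v in row.items()
                if k.startswith("nest_")
            }
            floral = {
                k[len("floral_") :]: float(v)
                for k, v in row.items()
                if k.startswith("floral_")
            }
            out.append(
                LULCClass(
                    class_id=int(row["class_id"]),
                    name=row["name"],
                    is_natural=bool(int(row["is_natural"])),
                    is_agricultural=bool(int(row["is_agricultural"])),
                    is_cultivated=bool(int(row["is_cultivated"])),
                    nesting_suitability=nest,
                    floral_availability=floral,
                )
            )
    return out


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grids


def write_ascii_grid(
    array: np.ndarray, grid: LandscapeGrid, path: str | Path, fmt: str = "%.6g"
) -> None:
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x:.6f}\n"
        f"yllcorner {grid.origin_y - grid.n_rows * grid.resolution:.6f}\n"
        f"cellsize {grid.resolution:.6f}\n"
        f"NODATA_value -9999\n"
    )
    arr = np.asarray(array, dtype=float)
    arr = np.where(np.isnan(arr), -9999.0, arr)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)


def read_ascii_grid(path: str | Path, crs_tag: str = "local-metric"):
    """Read an ESRI ASCII grid; returns (array, LandscapeGrid)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nodata = header.get("nodata_value", -9999.0)
    arr = np.where(arr == nodata, np.nan, arr)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    grid = LandscapeGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
        resolution=header["cellsize"],
        crs_tag=crs_tag,
    )
    return arr, grid


# ---------------------------------------------------------------------------
# I/O: whole objects


def write_lulc(lulc: LULCMap, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(lulc.codes, lulc.grid, d / "lulc.asc", fmt="%d")
    write_class_table(lulc.classes.values(), d / "classes.csv")
    meta = {"crs_tag": lulc.grid.crs_tag, "analysis_buffer_m": lulc.analysis_buffer_m}
    (d / "lulc_meta.json").write_text(json.dumps(meta, indent=1))


def read_lulc(directory: str | Path) -> LULCMap:
    d = Path(directory)
    meta = json.loads((d / "lulc_meta.json").read_text())
    arr, grid = read_ascii_grid(d / "lulc.asc", crs_tag=meta["crs_tag"])
    codes = np.nan_to_num(arr, nan=0.0).astype(np.int32)
    classes = read_class_table(d / "classes.csv")
    return LULCMap(grid, codes, classes, analysis_buffer_m=meta["analysis_buffer_m"])


def write_registry(registry: FieldRegistry, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    feats = []
    for f in registry:
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(f.polygon),
                "properties": {
                    "field_id": f.field_id,
                    "area_ha": f.area_ha,
                    "abandoned": f.abandoned,
                    "degraded": f.degraded,
                },
            }
        )
    (d / "fields.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )
    with open(d / "history.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["field_id", "year", "cultivated", "crop_code"])
        for f in registry:
            for year in sorted(f.history):
                cult, crop = f.history[year]
                w.writerow([f.field_id, year, int(cult), crop])


def read_registry(directory: str | Path) -> FieldRegistry:
    d = Path(directory)
    gj = json.loads((d / "fields.geojson").read_text())
    hist: dict[int, dict[int, tuple[bool, str]]] = {}
    with open(d / "history.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            hist.setdefault(int(row["field_id"]), {})[int(row["year"])] = (
                bool(int(row["cultivated"])),
                row["crop_code"],
            )
    fields = []
    for feat in gj["features"]:
        props = feat["properties"]
        fid = int(props["field_id"])
        fields.append(
            FieldRecord(
                field_id=fid,
                polygon=shape(feat["geometry"]),
                area_ha=float(props["area_ha"]),
                history=hist.get(fid, {}),
                abandoned=bool(props.get("abandoned", False)),
                degraded=bool(props.get("degraded", False)),
            )
        )
    return FieldRegistry(fields)
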