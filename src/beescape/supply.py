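"""Lonsdorf-style landscape model of relative wild-bee abundance.

Each land-cover class carries a nesting suitability per substrate and a
floral availability per season, on the discrete relative scale
0/0.25/0.5/0.75/1.  For a taxon with foraging distance ``alpha_m``:

* nesting score  ``HN(x) = max_j [ class_nest(l(x), j) * pref_j ]``
* floral score   ``HF(x, s) = class_floral(l(x), s)``
* source score   ``P(x) = HN(x) * <HF>_alpha(x)``
* abundance      ``A(o) = <P>_alpha(o) * activity_s``

where ``<.>_alpha`` is a distance-weighted mean over the landscape with
exponential decay ``w(d) = exp(-d / alpha_m)``, truncated where the relative
weight drops below a cutoff and normalized per cell over the in-extent
window.  The guild supply index is the unweighted mean over taxa; outputs are
relative, not absolute, abundances.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

from .grid import LULCMap

__all__ = [
    "PollinatorTaxon",
    "SupplyMap",
    "pixel_nesting_suitability",
    "pixel_floral_value",
    "exponential_kernel",
    "foraging_average",
    "taxon_abundance",
    "supply_index",
    "default_guild",
    "read_guild_table",
    "write_guild_table",
]


@dataclass(frozen=True)
class PollinatorTaxon:
    """Foraging and nesting parameters for one bee taxon (genus level)."""

    name: str
    alpha_m: float
    nesting_preference: Mapping[str, float]
    season_activity: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.alpha_m <= 0:
            raise ValueError(f"{self.name}: alpha_m must be positive")
        if not any(v > 0 for v in self.nesting_preference.values()):
            raise ValueError(f"{self.name}: at least one nesting weight must be > 0")
        for k, v in {**self.nesting_preference, **self.season_activity}.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{self.name}: weight {k}={v} outside [0, 1]")
        s = sum(self.season_activity.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: season activity sums to {s}, expected 1")


@dataclass
class SupplyMap:
    """Relative bee-abundance rasters for one season.

    ``index`` is the unweighted mean over taxa; ``normalized`` its min-max
    rescaling over the non-buffer region (recorded in ``norm_min``/``norm_max``).
    """

    season: str
    index: np.ndarray
    normalized: np.ndarray
    norm_min: float
    norm_max: float
    per_taxon: dict[str, np.ndarray] = dc_field(default_factory=dict)


def pixel_nesting_suitability(lulc: LULCMap, taxon: PollinatorTaxon) -> np.ndarray:
    """HN raster: best available substrate for the taxon in each cell."""

    def hn(cls):
        best = 0.0
        for substrate, pref in taxon.nesting_preference.items():
            if pref > 0 and substrate not in cls.nesting_suitability:
                raise KeyError(
                    f"class {cls.name!r} lacks nesting substrate {substrate!r}"
                )
            best = max(best, cls.nesting_suitability.get(substrate, 0.0) * pref)
        return best

    return lulc.class_lookup(hn)


def pixel_floral_value(lulc: LULCMap, season: str) -> np.ndarray:
    """HF raster: floral availability of each cell's class for the season."""
    seasons = {s for c in lulc.classes.values() for s in c.floral_availability}
    if season not in seasons:
        raise KeyError(f"season {season!r} not in class table (has {sorted(seasons)})")
    return lulc.class_lookup(lambda c: c.floral_availability.get(season, 0.0))


def exponential_kernel(
    alpha_m: float, resolution_m: float, cutoff: float = 1e-3
) -> np.ndarray:
    """Radially symmetric exponential-decay kernel ``exp(-d / alpha_m)``.

    ``d`` is the center-to-center Euclidean distance; weights below
    ``cutoff`` (relative to the unit center weight) are truncated to zero.
    The kernel is unnormalized: per-cell window normalization happens in
    :func:`foraging_average`.
    """
    if alpha_m <= 0:
        raise ValueError("alpha_m must be positive")
    if alpha_m < resolution_m / 10.0:
        raise ValueError(
            f"alpha_m={alpha_m} m is undersampled at {resolution_m}-m resolution"
        )
    radius_m = alpha_m * math.log(1.0 / cutoff)
    r = int(math.ceil(radius_m / resolution_m))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d = np.hypot(dy, dx) * resolution_m
    w = np.exp(-d / alpha_m)
    w[w < cutoff] = 0.0
    return w


def foraging_average(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Distance-weighted mean of ``values`` under ``kernel``.

    ``out(x) = sum_m v(m) w(d(x, m)) / sum_m w(d(x, m))`` with both sums over
    in-extent cells within the kernel support, so cells near the raster edge
    are normalized only over what exists.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values raster must be finite")
    if kernel.sum() <= 0:
        raise ValueError("kernel has empty support")
    num = signal.convolve(values, kernel, mode="same", method="auto")
    den = signal.convolve(np.ones_like(values), kernel, mode="same", method="auto")
    return np.maximum(num / den, 0.0)


def taxon_abundance(
    lulc: LULCMap,
    taxon: PollinatorTaxon,
    season: str = "summer",
    cutoff: float = 1e-3,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Relative abundance of one taxon visiting each cell in a season."""
    if kernel is None:
        kernel = exponential_kernel(taxon.alpha_m, lulc.grid.resolution, cutoff)
    hn = pixel_nesting_suitability(lulc, taxon)
    hf = pixel_floral_value(lulc, season)
    source = hn * foraging_average(hf, kernel)
    activity = taxon.season_activity.get(season, 0.0)
    return foraging_average(source, kernel) * activity


def supply_index(
    lulc: LULCMap,
    guild: Sequence[PollinatorTaxon],
    season: str = "summer",
    cutoff: float = 1e-3,
    keep_per_taxon: bool = False,
) -> SupplyMap:
    """Guild-level pollination supply: unweighted mean of taxon abundances.

    The normalized variant rescales to [0, 1] by the min/max over the
    non-buffer region (constant rasters map to zero).
    """
    if not guild:
        raise ValueError("guild must contain at least one taxon")
    total = np.zeros(lulc.grid.shape, dtype=float)
    per_taxon: dict[str, np.ndarray] = {}
    for taxon in guild:
        a = taxon_abundance(lulc, taxon, season=season, cutoff=cutoff)
        total += a
        if keep_per_taxon:
            per_taxon[taxon.name] = a
    index = total / len(guild)
    core = lulc.core_mask
    vmin = float(index[core].min())
    vmax = float(index[core].max())
    if vmax > vmin:
        normalized = (index - vmin) / (vmax - vmin)
    else:
        normalized = np.zeros_like(index)
    return SupplyMap(
        season=season,
        index=index,
        normalized=normalized,
        norm_min=vmin,
        norm_max=vmax,
        per_taxon=per_taxon,
    )


# ---------------------------------------------------------------------------
# Default guild

def default_guild() -> list[PollinatorTaxon]:
    """Illustrative ten-genus guild of common northeastern-American wild bees.

    Foraging distances (100-1,500 m) and substrate preferences are
    literature-informed order-of-magnitude values, not a calibrated fit:
    large-bodied Bombus and Melissodes range farthest; small sweat bees
    (Lasioglossum, Halictus) and Ceratina stay near the nest.  Activity
    weights split the season between spring and summer and sum to one.
    """

    def t(name, alpha, ground, cavity, stem, spring):
        return PollinatorTaxon(
            name,
            alpha_m=alpha,
            nesting_preference={"ground": ground, "cavity": cavity, "stem": stem},
            season_activity={"spring": spring, "summer": round(1.0 - spring, 10)},
        )

    return [
        t("Bombus", 1500.0, 0.5, 1.0, 0.0, 0.4),
        t("Lasioglossum", 200.0, 1.0, 0.0, 0.25, 0.5),
        t("Andrena", 500.0, 1.0, 0.0, 0.0, 0.7),
        t("Halictus", 300.0, 1.0, 0.0, 0.0, 0.5),
        t("Megachile", 600.0, 0.25, 1.0, 0.5, 0.3),
        t("Ceratina", 150.0, 0.0, 0.25, 1.0, 0.5),
        t("Hylaeus", 200.0, 0.0, 0.5, 1.0, 0.4),
        t("Osmia", 400.0, 0.25, 1.0, 0.5, 0.8),
        t("Agapostemon", 400.0, 1.0, 0.0, 0.0, 0.5),
        t("Melissodes", 800.0, 1.0, 0.0, 0.0, 0.2),
    ]


def write_guild_table(guild: Iterable[PollinatorTaxon], path: str | Path) -> None:
    guild = list(guild)
    substrates = sorted({s for t in guild for s in t.nesting_preference})
    seasons = sorted({s for t in guild for s in t.season_activity})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["taxon", "alpha_m"]
            + [f"nest_{s}" for s in substrates]
            + [f"activity_{s}" for s in seasons]
        )
        for t in guild:
            w.writerow(
                [t.name, t.alpha_m]
                + [t.nesting_preference.get(s, 0.0) for s in substrates]
                + [t.season_activity.get(s, 0.0) for s in seasons]
            )


def read_guild_table(path: str | Path) -> list[PollinatorTaxon]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PollinatorTaxon(
                    name=row["taxon"],
                    alpha_m=float(row["alpha_m"]),
                    nesting_preference={
                        k[len("nest_") :]: float(v)
                        for k, v in row.items()
                        if k.startswith("nest_")
                    },
                    season_activity={
                        k[len("activity_") :]: float(v)
                        for k, v in row.items()
                        if k.startswith("activity_")
                    },
                )
            )
    return out
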