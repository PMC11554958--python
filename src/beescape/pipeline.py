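"""End-to-end orchestration: generate or load a landscape, screen marginal
lands, map supply and demand, build the restoration scenarios and evaluate
them against the lower-threshold targets.

``run_pipeline`` is deterministic per configuration: the same ``RunConfig``
(including its seed) yields bit-identical comparison tables.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assess
from .assess import ScenarioAssessment
from .demand import DemandMap, demand_raster, dependency_table_from_crop_mix
from .grid import (
    FieldRegistry,
    LULCMap,
    natural_mask,
    rasterize_fields,
    read_ascii_grid,
    read_lulc,
    read_registry,
    write_ascii_grid,
    write_lulc,
    write_registry,
)
from .marginal import MarginalLandReport, find_marginal_lands
from .scenarios import (
    Scenario,
    scenario_flower_strips,
    scenario_maximal,
    scenario_mixed,
    scenario_no_restoration,
    scenario_reforest_marginal,
)
from .supply import default_guild, supply_index
from .synth import LandscapeBundle, SynthConfig, generate_landscape

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_bundle", "read_bundle"]

logger = logging.getLogger("beescape")

ALL_SCENARIOS = (
    "no_restoration",
    "reforest_marginal",
    "flower_strips",
    "mixed",
    "maximal",
)


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with field-standard defaults.

    Defaults: 5-year abandonment window; NDVI trend screen at p <= 0.05 with
    0.15-ha minimum patches and the 30% field rule; 5-m strips; 3%-of-
    territory mixed budget; 50-m exclusion around marginal fields; 1-km focal
    radius; 1-km**2 S/D tiles retained at >= 25% agricultural overlap.
    """

    seed: int = 0
    synth: SynthConfig = dc_field(default_factory=SynthConfig)
    abandonment_window: int = 5
    p_max: float = 0.05
    min_patch_ha: float = 0.15
    degraded_fraction: float = 0.30
    strip_width_m: float = 5.0
    target_fraction: float = 0.03
    exclusion_m: float = 50.0
    radius_m: float = 1000.0
    kernel_cutoff: float = 1e-3
    season: str = "summer"
    sd_cell_km: float = 1.0
    sd_min_overlap: float = 0.25
    hotspot_cover_max_pct: float = 5.0
    scenarios: tuple[str, ...] = ALL_SCENARIOS
    out_dir: str | None = None
    write_rasters: bool = False

    def __post_init__(self) -> None:
        if self.seed != self.synth.seed:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)
        unknown = set(self.scenarios) - set(ALL_SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(self.scenarios)
        d["synth"]["extent_km"] = list(self.synth.extent_km)
        d["synth"]["crop_mix"] = {
            k: [v[0], v[1]] for k, v in self.synth.crop_mix.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        if synth:
            synth = dict(synth)
            if "extent_km" in synth:
                synth["extent_km"] = tuple(synth["extent_km"])
            if "crop_mix" in synth:
                synth["crop_mix"] = {
                    k: (float(v[0]), str(v[1])) for k, v in synth["crop_mix"].items()
                }
            d["synth"] = SynthConfig(**synth)
        if "scenarios" in d:
            d["scenarios"] = tuple(d["scenarios"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    """Everything one run produced, in memory."""

    config: RunConfig
    bundle: LandscapeBundle
    report: MarginalLandReport
    demand: DemandMap
    baseline_bivariate: assess.BivariateResult
    baseline_field_covers: pd.Series
    scenarios: dict[str, Scenario]
    assessments: dict[str, ScenarioAssessment]
    comparison: pd.DataFrame
    timings: dict[str, float] = dc_field(default_factory=dict)


def _field_means(raster: np.ndarray, labels: np.ndarray, ids: list[int]) -> pd.Series:
    n = int(labels.max(initial=0)) + 1
    sums = np.bincount(labels.ravel(), weights=raster.ravel(), minlength=n)
    counts = np.bincount(labels.ravel(), minlength=n)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return pd.Series({i: means[i] for i in ids})


def _assess_one(
    sc: Scenario,
    cfg: RunConfig,
    demand: DemandMap,
    ag_mask: np.ndarray,
    guild,
    registry: FieldRegistry,
) -> tuple[ScenarioAssessment, dict]:
    core = sc.lulc.core_mask
    sup = supply_index(sc.lulc, guild, season=cfg.season, cutoff=cfg.kernel_cutoff)
    scaled_demand = assess.minmax_scale(demand.raster, core)
    sd = assess.sd_ratio(sup.normalized, scaled_demand, demand.raster)
    sd_grid = assess.aggregate_sd(
        sd, sc.lulc, ag_mask, cell_km=cfg.sd_cell_km, min_overlap=cfg.sd_min_overlap
    )
    nat = natural_mask(sc.lulc)
    cover = assess.natural_cover_pct(nat, sc.lulc.grid, radius_m=cfg.radius_m)
    covers = pd.Series(
        {
            f.field_id: assess.field_natural_cover(
                cover, sc.lulc.grid, f.centroid, radius_m=cfg.radius_m
            )
            for f in registry
        }
    )
    areas = pd.Series({f.field_id: f.area_ha for f in registry})
    ranking = assess.priority_ranking(covers, areas, ag_zone_ha=float(areas.sum()))
    a = ScenarioAssessment(
        name=sc.name,
        sd_pct_ge1=sd_grid.pct_ge1,
        priority=ranking,
        reforested_ha=sc.reforested_ha,
        strips_ha=sc.strips_ha,
        restored_fraction=sc.restored_fraction,
    )
    extras = {"supply": sup, "sd_grid": sd_grid, "field_covers": covers, "cover": cover}
    return a, extras


def run_pipeline(
    config: RunConfig, bundle: LandscapeBundle | None = None
) -> PipelineResult:
    """Execute the full assessment and return (and optionally write) results.

    With ``bundle`` given the generation stage is skipped and the provided
    landscape is assessed instead.
    """
    cfg = config
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    s = stage("generate")
    if bundle is None:
        bundle = generate_landscape(cfg.synth)
    done(s)
    lulc, registry, labels = bundle.lulc, bundle.registry, bundle.labels

    s = stage("marginal_detection")
    report = find_marginal_lands(
        lulc,
        registry,
        labels,
        bundle.ndvi,
        window=cfg.abandonment_window,
        p_max=cfg.p_max,
        min_patch_ha=cfg.min_patch_ha,
        degraded_fraction=cfg.degraded_fraction,
    )
    done(s)

    s = stage("demand")
    dep_table = dependency_table_from_crop_mix(cfg.synth.crop_mix)
    demand = demand_raster(registry, lulc.grid, labels, dep_table, report.marginal_ids)
    done(s)

    guild = default_guild()
    ag_mask = lulc.class_lookup(lambda c: 1.0 if c.is_agricultural else 0.0) > 0

    s = stage("baseline_assessment")
    baseline_sc = scenario_no_restoration(lulc)
    base_assess, base_extras = _assess_one(
        baseline_sc, cfg, demand, ag_mask, guild, registry
    )
    # field-scale bivariate classification over non-marginal crop fields
    crop_ids = [i for i in registry.ids if i not in set(report.marginal_ids)]
    sup_by_field = _field_means(base_extras["supply"].index, labels, crop_ids)
    dem_by_field = demand.field_values.loc[crop_ids]
    areas = pd.Series({i: registry[i].area_ha for i in crop_ids})
    bivar = assess.bivariate_matrix(sup_by_field, dem_by_field, areas)
    covers = base_extras["field_covers"]
    done(s)

    s = stage("scenarios")
    built: dict[str, Scenario] = {}
    for name in cfg.scenarios:
        if name == "no_restoration":
            built[name] = baseline_sc
        elif name == "reforest_marginal":
            built[name] = scenario_reforest_marginal(lulc, registry, labels, report)
        elif name == "flower_strips":
            built[name] = scenario_flower_strips(
                lulc, registry, labels, report, width_m=cfg.strip_width_m
            )
        elif name == "mixed":
            built[name] = scenario_mixed(
                lulc,
                registry,
                labels,
                report,
                hotspot_ids=bivar.hotspot_ids,
                field_covers=covers,
                target_fraction=cfg.target_fraction,
                cover_max_pct=cfg.hotspot_cover_max_pct,
                radius_m=cfg.radius_m,
                width_m=cfg.strip_width_m,
            )
        elif name == "maximal":
            built[name] = scenario_maximal(
                lulc,
                registry,
                labels,
                report,
                exclusion_m=cfg.exclusion_m,
                width_m=cfg.strip_width_m,
            )
    done(s)

    s = stage("scenario_assessment")
    assessments: dict[str, ScenarioAssessment] = {}
    for name, sc in built.items():
        if name == "no_restoration":
            assessments[name] = base_assess
        else:
            assessments[name], _ = _assess_one(
                sc, cfg, demand, ag_mask, guild, registry
            )
    done(s)

    baseline_name = (
        "no_restoration" if "no_restoration" in assessments else cfg.scenarios[0]
    )
    comparison = assess.compare_scenarios(
        [assessments[n] for n in cfg.scenarios], baseline_name=baseline_name
    )

    result = PipelineResult(
        config=cfg,
        bundle=bundle,
        report=report,
        demand=demand,
        baseline_bivariate=bivar,
        baseline_field_covers=covers,
        scenarios=built,
        assessments=assessments,
        comparison=comparison,
        timings=timings,
    )
    if cfg.out_dir is not None:
        write_outputs(result, cfg.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write the run directory: comparison table, marginal report, manifest."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    result.comparison.to_csv(d / "comparison.csv")

    rep = result.report
    with open(d / "marginal_report.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["field_id", "abandoned", "degraded", "area_ha"])
        for fid in rep.marginal_ids:
            f = result.bundle.registry[fid]
            w.writerow(
                [fid, int(fid in rep.abandoned_ids), int(fid in rep.degraded_ids),
                 f"{f.area_ha:.4f}"]
            )

    np.savetxt(
        d / "bivariate_matrix_pct.csv",
        result.baseline_bivariate.matrix_pct,
        delimiter=",",
        fmt="%.4f",
        header="rows: demand tertile (low,intermediate,high); "
        "cols: supply tertile (low,intermediate,high)",
    )

    manifest = {
        "config": result.config.to_dict(),
        "n_fields": len(result.bundle.registry),
        "n_scenarios": len(result.scenarios),
        "scenario_names": list(result.scenarios),
        "timings_s": result.timings,
        "total_abandoned_ha": round(rep.total_abandoned_ha, 4),
        "total_degraded_ha": round(rep.total_degraded_ha, 4),
        "n_hotspots": len(result.baseline_bivariate.hotspot_ids),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    if result.config.write_rasters:
        grid = result.bundle.lulc.grid
        write_ascii_grid(result.demand.raster, grid, d / "demand.asc")
        for name, sc in result.scenarios.items():
            write_ascii_grid(sc.lulc.codes, grid, d / f"lulc_{name}.asc", fmt="%d")
    return d


# ---------------------------------------------------------------------------
# Bundle persistence (text formats only)


def write_bundle(bundle: LandscapeBundle, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_lulc(bundle.lulc, d)
    write_registry(bundle.registry, d)
    grid = bundle.lulc.grid
    for year, arr in zip(bundle.ndvi_years, bundle.ndvi):
        write_ascii_grid(arr, grid, d / f"ndvi_{year}.asc", fmt="%.5f")
    meta = {
        "ndvi_years": bundle.ndvi_years,
        "truth_abandoned": bundle.truth_abandoned,
        "truth_degraded": bundle.truth_degraded,
    }
    (d / "bundle_meta.json").write_text(json.dumps(meta, indent=1))


def read_bundle(directory: str | Path) -> LandscapeBundle:
    d = Path(directory)
    lulc = read_lulc(d)
    registry = read_registry(d)
    meta = json.loads((d / "bundle_meta.json").read_text())
    stack = [read_ascii_grid(d / f"ndvi_{y}.asc")[0] for y in meta["ndvi_years"]]
    return LandscapeBundle(
        lulc=lulc,
        registry=registry,
        labels=rasterize_fields(registry, lulc.grid),
        ndvi=np.stack(stack),
        ndvi_years=list(meta["ndvi_years"]),
        truth_abandoned=list(meta["truth_abandoned"]),
        truth_degraded=list(meta["truth_degraded"]),
    )
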