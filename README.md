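# beescape

Intensive agricultural landscapes keep most of their land in commodity
production, and wild-bee pollination suffers for it: dependent crops need
nesting habitat and floral resources within the bees' foraging range, yet
natural habitat may cover only a few percent of the land around a field.
*Marginal* agricultural land — abandoned fields, fields with degrading
soils, and field edges — is land that could be restored without meaningfully
reducing crop production. `beescape` is a tested, reusable pipeline for
asking how much such restoration can enhance pollination provision and
natural-habitat coverage, and where it should happen first.

It is aimed at landscape ecologists and restoration planners who want to run
scenario analyses on a land-cover raster plus a crop-field registry, and at
methodologists who want every stage testable against synthetic landscapes
with known ground truth.

## What it computes

1. **Marginal-land screening** — abandoned fields (no cultivation in the
   final 5 years of a 10-year registry) and degraded fields (pixel-wise OLS
   of a 22-year annual NDVI stack: slope < 0, p ≤ 0.05, edge pixels eroded,
   patches < 0.15 ha dropped, field degraded when flagged patches cover
   ≥ 30% of its area).
2. **Pollination supply** — a Lonsdorf-style model: per-taxon nesting score
   `HN(x) = max_j s_j(l(x))·pref_j`, floral score averaged under an
   exponential foraging kernel `w(d) = e^{−d/α}`, source score
   `P = HN·⟨HF⟩_α`, abundance `A = ⟨P⟩_α`, averaged over a ten-genus guild.
3. **Pollination demand** — field area × mean Klein-class dependency weight
   of the rotation's main crops; zero for marginal fields.
4. **Scenarios** — no restoration; reforesting marginal fields; 5-m flower
   strips on longest field edges; a mixed strategy prioritized around demand
   hotspots and budgeted to 3% of the territory; and maximal restoration
   (both, with a 50-m exclusion). Strip areas are vector-exact.
5. **Assessment** — tertile bivariate supply×demand maps and hotspot fields;
   the min-max-scaled supply-to-demand ratio S/D averaged on a 1-km² grid
   (% of tiles with mean S/D ≥ 1); two-stage 1-km focal natural-cover
   statistics; and a four-class restoration-priority ranking
   (<5%, 5–10%, 10–20%, ≥20% surrounding natural cover).

S/D is a *relative* comparator between scenarios — it is never an absolute
measure of pollination deficit or surplus. See `docs/methods.md` for models,
assumptions and limitations.

## Worked example

```python
from beescape.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1))   # 6x6-km synthetic landscape
print(result.comparison[["restored_pct_territory", "sd_pct_ge1",
                         "delta_sd_pct_ge1", "pct_high_priority"]])
```

```
                   restored_pct_territory  sd_pct_ge1  delta_sd_pct_ge1  pct_high_priority
scenario
no_restoration                      0.000      18.519             0.000             28.343
reforest_marginal                   3.163      25.926             7.407             19.541
flower_strips                       2.628      66.667            48.148              0.000
mixed                               2.970      51.852            33.333              0.000
maximal                             5.320      66.667            48.148              0.000
```

On this landscape (397 fields, 3,600-ha territory) the screening finds
86.4 ha of abandoned and 27.5 ha of degraded fields (~3.2% of the territory)
and 82 demand-hotspot fields. In the baseline, 18.5% of the 1-km² tiles have
mean S/D ≥ 1 and 28.3% of the agricultural zone has under 5% natural cover
within 1 km (high restoration priority). Reforesting marginal fields alone
helps least — abandoned fields are spatially clustered, so their benefit is
local — while scenarios that add flower strips spread floral resources
across the whole cultivated matrix, raise the S/D ≥ 1 share the most, and
eliminate the high-priority deficit class.

The same run is available from the shell:

```
beescape run-all --seed 1 --out runs/demo
beescape generate --seed 1 --out bundles/demo     # write a landscape bundle
beescape detect --bundle bundles/demo --out report.json
```

All file formats are plain text: ESRI ASCII grids for rasters, GeoJSON for
field polygons, CSV for class/guild/dependency tables and histories.

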