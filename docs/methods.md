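# Methods

`beescape` implements a spatial assessment of how much restoring *marginal
agricultural land* — abandoned fields, soil-degraded fields, and field edges —
can enhance wild-bee pollination provision and natural-habitat coverage in an
intensive agricultural landscape. This note documents the models, their
assumptions, the tunable parameters, and the limits of what the synthetic
test landscapes can show.

## Spatial data model

The analysis runs on a north-up 30-m categorical land-use/land-cover (LULC)
raster in a projected metric CRS; one cell is 0.09 ha. A configurable border
ring (default 2 km) surrounds the reported territory: it participates in every
kernel and focal computation (so edge cells see realistic surroundings) but is
excluded from all reported areas and statistics. Crop fields are vector
polygons with a ten-year cultivation history (per-year cultivated flag and
main crop). Field membership of a cell is decided by cell-center containment —
exact, deterministic, and easy to check against a point-in-polygon oracle.
Natural habitat comprises four classes: forest, wetland, old field /
shrubland, and flower strips (the strip class exists in the baseline table
with zero extent, so scenarios never invent class codes).

## Marginal-land screening

**Abandonment.** A field is abandoned when it was not cultivated in any of the
final five years of its history. Five years avoids false positives from
ordinary fallow rotation. Fields whose modal LULC class is old field /
shrubland are excluded: they are already regenerating habitat, not restorable
cropland. The rule is deterministic and ignores everything before the
terminal window.

**Degradation.** Per agricultural pixel, an ordinary-least-squares regression
of annual NDVI on year over a 22-year stack; the two-sided p-value comes from
the slope t statistic on n−2 degrees of freedom. Pixels with slope < 0 and
p ≤ 0.05 are flagged, after removing one 30-m ring of edge pixels inside each
field boundary (the ~25-m edge zone is contaminated by ditches, roads and
neighbouring cover). Flagged patches smaller than 0.15 ha (8-neighbour
connectivity) are dropped as impractical to restore; a field whose surviving
patches cover ≥ 30% of its *full* (pre-erosion) area is classed degraded in
its entirety, and the flagged pixels of fields failing the rule contribute
nothing downstream. Degenerate zero-variance series get p = 1 (a flat series
is no evidence of decline); a perfect non-constant line gets p = 0. No
multiple-testing correction is applied — the screen is a per-pixel filter,
not an inference — and no attribution of decline causes is attempted.

## Pollination supply (Lonsdorf-style model)

Each LULC class carries nesting suitability per substrate (ground, cavity,
stem) and floral availability per season (spring, summer) on the discrete
relative scale {0, 0.25, 0.5, 0.75, 1}. For a taxon with typical foraging
distance α (m):

- nesting score `HN(x) = max_j class_nest(l(x), j) · pref_j`
- floral score `HF(x, s) = class_floral(l(x), s)`
- source score `P(x) = HN(x) · ⟨HF⟩_α(x)`
- abundance `A(o) = ⟨P⟩_α(o) · activity_s`

where `⟨·⟩_α` is the distance-weighted mean with exponential decay
`w(d) = exp(−d/α)` over cell-center distances, truncated where the relative
weight falls below 10⁻³ (radius ≈ 6.91 α; configurable), and normalized per
cell over the in-extent window. The guild index is the unweighted mean over
taxa; whether taxa should instead be weighted by relative abundance is
unresolved in the literature this follows, so equal weights are the default
and the aggregation is a plain mean the caller can replace. Outputs are
*relative* abundances: they support between-scenario comparison, never
absolute pollination accounting. Only the summer map feeds the assessment;
spring machinery exists but is untested against any reference.

The ten-genus default guild (Bombus, Lasioglossum, Andrena, Halictus,
Megachile, Ceratina, Hylaeus, Osmia, Agapostemon, Melissodes; α from 100 to
1,500 m) is explicitly illustrative: literature-informed order-of-magnitude
parameters, not a calibrated fit. Convolutions use `scipy.signal.convolve`
(FFT for large kernels); on ≤ 21×21 toy rasters the implementation agrees
with a brute-force double loop to 10⁻⁹.

## Pollination demand

A field's demand is its area (ha) times the mean over the ten history years
of the dependency weight of that year's main crop. Dependency classes follow
the Klein-style categories with class-midpoint default weights (essential
0.95, great 0.65, modest 0.25, little 0.05, none 0); the table is data and
can be overridden. Uncultivated years contribute weight zero (fallow land
demands no pollination that year) — a design choice, exposed through the
history semantics rather than a flag. Abandoned and degraded fields have
demand zero. Rasterized demand spreads mean annual weight × cell area over
the field's cells so cell sums reproduce field totals; because the headline
S/D statistic min-max-normalizes demand, it is invariant to any positive
rescaling of the class weights (covered by a test).

## Restoration scenarios

All scenarios reclassify the baseline raster; class tables and grid extent
never change. Area accounting is **vector-based**: 5-m strips are true
polygons (longest exterior edge, buffered 5 m into the field, clipped to the
field), and the ledger records their geometric areas. The raster burn (cells
whose square intersects a strip polygon become flower-strip class)
over-represents strips at 30-m resolution; this is accepted because the
supply model needs the strips visible on the grid, while every reported
hectare and the 3% budget use vector areas.

- *no_restoration*: baseline.
- *reforest_marginal*: all abandoned ∪ degraded fields become forest (the
  deciduous-forest class's suitabilities, with no succession lag).
- *flower_strips*: a strip on every non-marginal crop field.
- *mixed*: priority fields are demand hotspots (see below) with < 5% mean
  natural cover within 1 km; candidate interventions are marginal fields and
  strips intersecting the union of 1-km buffers around priority-field
  centroids. All candidate marginal fields are reforested; candidate strips
  are then removed one at a time, *closest to a reforested field first* (a
  strip beside a future forest patch is redundant), until total restored
  area fits 3% of the territory. If reforestation alone exceeds the budget,
  all strips are removed and a warning is raised.
- *maximal*: reforest all marginal fields; strips on every crop field whose
  polygon lies more than 50 m from every marginal field.

Geometry-to-geometry distance is the minimum Euclidean distance between
polygon boundaries. Longest-edge ties break by first occurrence in the
normalized ring order, making strip placement deterministic.

## Assessment

- **Min-max scaling** over the non-buffer region, per scenario map (a
  constant raster maps to zeros). Scaling per scenario means ranges are not
  strictly comparable across scenarios; the S/D statistic is interpreted
  only ordinally.
- **Tertiles** at the 1/3 and 2/3 sample quantiles (linear interpolation,
  inclusive upper breakpoints). Field-scale supply (mean over field cells)
  and demand are classified independently over crop fields; *hotspots for
  pollination demand* are fields with intermediate-to-high demand and low
  supply. Being rank-based, hotspots are invariant under monotone transforms
  of either axis.
- **Natural cover** is two-stage: per-cell percentage of natural cells
  within a 1-km circular window (center-distance membership, in-extent
  denominator), then the mean of that raster within 1 km of each field
  centroid.
- **Priority ranking**: high < 5% ≤ intermediate < 10% ≤ low < 20% ≤ none.
  Percentages are of the full field-registry area, so they always sum
  to 100.
- **S/D**: scaled supply over scaled demand where raw demand > 0, averaged
  over 1-km² tiles anchored at the reported region's origin; tiles with
  < 25% agricultural cells are dropped, retained tiles without defined S/D
  cells are excluded from the denominator, and the headline statistic is
  the percentage of retained tiles with mean S/D ≥ 1.

## Synthetic landscapes

The generator emulates an intensive northeastern-American agricultural
county: ~60% cultivated territory, long narrow parcels (vertical bands 90–150
m wide cut into lengths drawn from a log-normal matched to 6.2 ± 7.1 ha),
corn/soy-dominant rotations with a minority of pollinator-dependent crops,
and cover types assigned along a Gaussian-smoothed spatial gradient
(correlation length ~900 m) so forest, wetland and shrubland cluster away
from the most open cropland — leaving, as in real intensive landscapes, a
substantial share of fields with < 5% natural cover within 1 km. Abandoned
fields are planted as a spatial cluster (abandonment is spatially contagious
in such regions) with five trailing uncultivated years, capped at ~2.4% of
the territory; degraded fields get a linear NDVI decline (default −0.01/yr
against noise SD 0.02 over 22 annual composites), capped at ~0.9%, together
matching the ~3%-of-territory marginal share typical of such regions. Cut
lines snap to the 30-m grid, so vector and raster field areas agree exactly
and the demand mass-balance is exact rather than approximate. All randomness
flows from a single seed through named substreams keyed by (seed, component,
field id), so bundles are bit-reproducible and per-field draws are
order-independent.

What the generator does **not** emulate: cloud-masked satellite compositing
(NDVI is drawn directly as annual values — the stand-in for a June–September
median composite), roads and riparian corridors, hedgerows, irregular parcel
shapes, within-field crop mixtures, spatially correlated NDVI noise, and
year-to-year field-boundary changes. Passing tests therefore demonstrate the
*method* is implemented correctly and behaves sensibly under known ground
truth — not that its outputs are accurate for any real county.

## Numerical choices and problem sizes

Default test and demonstration runs use a 6×6-km territory with a 2-km
buffer (334×334 cells, ~380–400 fields); a full five-scenario run takes a
few seconds on one CPU. Kernel truncation at 10⁻³ relative weight bounds the
error of the foraging average at ~0.1% of the center weight. The erosion
step uses exactly one cell ring (25 m < one 30-m cell). The 30% degradation
boundary and 5% / 10% / 20% cover boundaries are inclusive as documented
above; ties in tertile classification use ≤-breakpoints. Oracle agreement
tolerances are 10⁻⁹ (kernel model, focal statistics) and 10⁻¹⁰ (trend
regression versus an independent OLS).

## Known limitations

- Relative supply only; no absolute pollination deficit can be inferred, and
  S/D ≥ 1 is a comparative device, not a sufficiency claim.
- Equal-weight taxon aggregation and the illustrative guild table are
  placeholders for expert-elicited, region-specific parameters.
- The per-scenario min-max scaling makes cross-scenario S/D comparisons
  ordinal, not cardinal.
- The NDVI screen cannot distinguish soil degradation from other causes of
  yield decline (drought, pests, management).
- Managed honey-bee colonies, pesticide exposure, economic and legal aspects
  of restoration, and habitat-establishment time lags are out of scope.
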