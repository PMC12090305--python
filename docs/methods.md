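# Methods

This note documents the models behind `firepas`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## Scope and design

The package computes a multi-criteria fire predisposition score for
forest stands. It deliberately keeps every indicator structurally simple
and uncoupled — each component is computed independently, normalized onto
[0, 1], and combined by a compensatory additive aggregation — so that the
contribution of each component to the final score remains inspectable.
It does **not** simulate fire behaviour (no spread, no dynamic fireline
intensity), and the forest dynamics it consumes are an input (tree lists
per stand and scenario), not something it models.

The scoring core is fit/transform shaped and implemented as an sklearn
transformer: `fit` pools the observed raw indicator values of a run
(all stands × timesteps × managements × climates) and derives the
normalization thresholds; `transform` maps raw values to scores and
aggregates pFire. Pooling across the whole run is intentional: scores are
then comparable across scenarios and timesteps of that run, at the price
of being relative to it. The recomputation scope can be narrowed by
passing fixed thresholds.

## Normalization

Indicators without an inherent 0–1 scale are rescaled linearly between a
lower and an upper threshold, clamped outside, with a positive
(lower→0, upper→1) or negative (lower→1, upper→0) direction. Thresholds
default to the 1st and 99th percentiles of the pooled observed values,
which blunts outliers. Percentiles use linear interpolation between order
statistics (the type-7 convention); the choice matters only at small n
and is documented here because conventions differ across software.

Degenerate pools (fewer than two distinct values, or coinciding
percentiles) raise an error instead of silently emitting 0 or 1 — small
study areas genuinely lack the spread to support run-derived thresholds,
and the caller must then supply fixed ones. Every resolved threshold is
exported with the run (`thresholds.csv` / `AssessmentResult.thresholds`).

## Terrain

A quadratic surface z = ax² + by² + cxy + dx + ey + f is fitted by
ordinary least squares in a square moving window around each cell
(Evans–Wood geomorphometry). Because the design matrix is fixed per
window geometry, each coefficient is a linear filter of the window
values, evaluated with a precomputed pseudo-inverse. Border cells without
a complete window, and windows containing nodata, are nodata.

* **Slope** = atan(√(d² + e²)); **aspect** = compass azimuth of the
  downslope direction, atan2(−d, −e) measured clockwise from north.
  Both are evaluated at the cell containing the stand centroid, on a
  coarse DEM with a 7×7 window (175 m at 25 m cells). Cells with gradient
  magnitude < 1e-9 are flat: aspect is undefined and classed as N
  (score 0), the most conservative choice.
* **Planform curvature** (contour-direction curvature)
  k = −(z_xx·e² − 2·z_xy·d·e + z_yy·d²)/(d² + e²)^{3/2}, computed on a
  fine DEM with a 9×9 window (18 m at 2 m cells). Negative = concave
  (canyon-like), positive = ridges; the convention is pinned by tests
  against a tilted synthetic valley/ridge pair and a closed-form bowl
  (contours are circles of radius r, curvature −1/r). A parabolic trench
  with straight contours has zero planform curvature — correctly so.
  Sub-1e-12/m magnitudes are snapped to zero: they are least-squares
  noise, far below any meaningful terrain curvature.
* **Stand curvature score**: per stand, convex cells are clipped to 0 and
  the mean over cells whose centers fall in the polygon is rescaled
  negatively between the 1st percentile of the observed concave means and
  0 — so stands on flat or convex ground score exactly 0 and the most
  strongly concave stands score 1.
* **Slope/aspect class scores** are 5-level categorical lookups from an
  Alpine fire danger classification: slope <10° or ≥50° → 0, then 0.25
  per 10° band up to 1.0 at 40–50°; aspect sectors N → 0, E/W/NE/NW →
  0.25, SE → 0.5, SW → 0.75, S → 1.0, with 45° sectors centered on the
  compass points (boundaries at ±22.5°, a convention the classification
  itself does not fix).

Window sizes are configurable; the defaults match the resolutions above.
Slope and aspect use the window centered on the centroid cell (not a
resampled product), the simplest reading of "at the stand centroid".

## Climate

The drought index contrasts growing-season evapotranspiration supply with
demand: FCDI = 1 − (ΣE_m)/(ΣD_m) over months with mean temperature
≥ 5.5 °C, clamped to [0, 1]. The ratio-of-sums form is used (rather than
a sum of monthly ratios): it keeps the index in [0, 1] and matches the
water-balance tradition the index descends from; the defining texts are
ambiguous at the typographical level. FCDI = 0 means supply meets demand;
values above 0.5 represent extreme drought, rare in European forests —
hence the score map pf.clim = min(2·FCDI, 1), linear between 0 and 0.5
and saturating there. Precomputed per-stand FCDI values (e.g. from a
forest gap model) bypass the monthly computation.

## Wildland–urban interface

Planar Euclidean distances from the stand centroid to the nearest feature
of four layers, computed with an STR-tree: buildings (polygon footprints
filtered to ≥ 75 m², edge distance; points pass unfiltered), all roads
and paths, drivable roads, and waterbodies (rivers merged with water
extraction points into one layer). Buildings and roads are ignition
sources, so their scores fall with distance (P1 → 1, P99 → 0); drivable
roads and waterbodies carry extinction capacity, so their scores rise
with distance (P1 → 0, P99 → 1). No terrain correction and no network
routing — straight-line distance only.

## Stand components

Tree lists are cohort-based (species, dbh in cm, height in m, stems/ha),
matching gap-model output. Per-tree formulas are evaluated per cohort;
aggregation weights are stems where counting matters (CV of height) and
basal area where the stand-level estimate is defined that way (mortality,
resilience, conifer share).

* **Fuel load**: basal area Σ stems·π·(dbh/200)², m²/ha; P1/P99 positive.
* **Conifer share**: conifer basal area / total basal area, used directly
  as the score. Basal-area weighting (configurable to stem share) was
  chosen for consistency with the other basal-area-weighted components.
* **Vertical fuel connectivity**: CV_h = sd_h/mean_h with stems-weighted
  population standard deviation (a single cohort has no variation → 0);
  sample vs. population is configurable via `ddof`. P1/P99 positive.
* **Horizontal fuel connectivity**: Reineke SDI = N·(dg/25)^1.605 with
  dg = √(Σ stems·dbh²/Σ stems) in cm. P1/P99 positive.
* **Lack of resistance**: per cohort, bark thickness bt (mm) feeds the
  cambium-kill time t_c = 3.36·bt²; tree height, crown length and the
  scorch height h_k feed the scorched crown volume fraction
  C_k = (h_k − h_t + cl)(h_t − h_k + cl)/cl², clamped to [0, 1] with
  C_k = 1 when h_k ≥ h_t and 0 when the scorch line stays below the
  crown base. Mortality is P_m = C_k^(t_c/t_f − 0.5); trees whose cambium
  fails within half the exposure time (t_c < 0.5·t_f) die outright. The
  stand score is the basal-area-weighted mean P_m.
* **Lack of long-term resilience**: a six-level species classification of
  long-term fire sensitivity (0.0, 0.2, …, 1.0; e.g. Pinus sylvestris
  0.2, Larix decidua 0.4, Picea abies and Fagus sylvatica 0.6, Abies
  alba 1.0), aggregated as the basal-area-weighted mean. Monocultures
  return the species score exactly.

### Fire exposure defaults

t_f = 300 s (typical peak heat exposure of a surface fire),
FLI = 630 kW/m (upper bound of medium-intensity fires), MFWS = 1.8 m/s,
T_a = 15 °C, T_c = 60 °C (lethal tissue temperature). These give a scorch
height of 19.04 m. h_k is computed once and shared across all stands and
timesteps: holding exposure constant is what makes the component a
measure of *stand-inherent* resistance rather than of fire weather.

### Allometries

Crown base height uses h_cb = h_t·(1 − e^{l0 + l1·(h_t/dbh) + l2·dbh})
with published species coefficients for Picea abies, Abies alba, Pinus
sylvestris, Fagus sylvatica and Quercus petraea; other species map to the
closest parametrized group (conifers → Picea abies, broadleaves → Fagus
sylvatica unless a closer match exists), a mapping carried in the species
traits and overridable via YAML. The exponent is negative over the
coefficients' validity range, so h_cb ∈ (0, h_t); h_cb is clamped to
[0, h_t) against pathological inputs. The model is advisory outside
height/dbh ratios of 0.15–1.25 m/cm; no hard rejection is applied.

Bark thickness is a pluggable per-species allometry. The shipped default
is affine, bt = b0 + b1·dbh (mm), floored at 0.1 mm, with
synthetic-but-plausible coefficients (thick-barked larch and pines,
thin-barked beech and spruce). These are *not* a published
parametrization — the original taper-based bark model is an external
package — and any callable `(traits, dbh, height) → mm` can replace the
default. This is the one acknowledged fidelity gap in the mortality
chain; relative species orderings are preserved, absolute P_m values
depend on the chosen allometry.

### Empty stands

Freshly clear-cut stands (no living cohort) score 0 on all six
stand-related components and are flagged `empty_stand`. No fuel and no
crowns means nothing to burn at the stand scale; the flag keeps the
convention explicit and filterable.

## Weighting and aggregation

Expert weights enter as a two-level hierarchy: sub-group weights
(site: terrain 0.40, climate 0.30, WUI 0.30; stand: fuel group 0.50,
resistance/resilience group 0.50) times within-group component weights,
each level summing to 1 (checked to 1e-9, violations name the offending
group). Final weights therefore sum to 1 per side; for reporting they are
additionally rescaled by the side maximum (λ̂ = λ/max λ, rounded to 2 dp;
internal arithmetic keeps full precision).

`aggregate_pfire` accepts *any* non-negative weight vector (hierarchy
output, scenario ratio vectors, random draws) and renormalizes per side
before the 0.5/0.5 combination, so pFire is always a convex combination
of the component scores. Missing components are a hard error by default;
an explicit `allow_missing` mode renormalizes over the available ones for
exploratory runs.

Preset scenarios: `eq_weights` (all components equal),
`eq_weights_group` (sub-groups share weight equally; the stand side is
one sub-group — the fuel/resistance split exists only for structured
expert judgement — so its six components are equal), `expert_weights`
(the hierarchical composition above), and `random_weights` (one fixed
random ratio vector). Two expert variants are shipped because the
published sources disagree on the site side — one lists normalized
slope/aspect/curvature as 0.53/0.53/0.27, the other as 0.53/0.27/0.53 —
`expert_weights_table6` (hierarchically composed; the alias
`expert_weights` points here) and `expert_weights_table8` (aspect and
curvature swapped). No silent reconciliation is attempted.

## Sensitivity machinery

* Spearman rank correlations between scenario pFire vectors over an
  identical state set (average ranks on ties; a constant vector raises —
  an undefined correlation must not be reported as 0).
* Random-weight ensembles: each component weight drawn uniformly from
  {0, 0.1, …, 1.0}; draws with an all-zero site or stand side are
  rejected and redrawn. One master seed spawns one child stream per
  scenario, so ensembles are reproducible and extensible (the first n
  scenarios of a larger ensemble equal the smaller one).
* Score distributions in left-closed 0.05 bins ([0, 0.05) … [0.95, 1.0],
  the last bin closed), counts conserving n.
* `ensemble_summary` places each predefined scenario's mean pFire within
  the random ensemble (rank and quantile).

## Synthetic data

The generators emulate the *shapes* of the real inputs, not their
ecology:

* **Landscape**: an analytic DEM (plane, tilted parabolic valley or
  ridge, or smoothed random field) at a coarse and a fine resolution,
  extended 100 m beyond the stand map so every stand lies in the
  window-complete interior; a jittered-grid tiling into convex
  rectangular stand polygons (chosen over Voronoi for cross-platform
  reproducibility); clustered-plus-scattered building footprints
  (100–576 m², above the 75 m² filter), wiggly road and river polylines,
  a drivable-road subset, and scattered extraction points.
* **Trajectories**: per-stand initial cohorts (3–6 cohorts, lognormal
  dbh around 28 cm, basal areas in the tens of m²/ha), decadal steps with
  climate-modified dbh growth (2.5 cm/decade baseline, ±20 % noise),
  5 %/decade background stem mortality, management removals (0 % for NO
  up to 30 %/decade for CNF-HIGH), periodic clearcuts observed as bare
  stands followed by dense regeneration, occasional regeneration pulses
  (Abies alba under the climate-adapted strategy), and a per-stand
  drought-index base (0.02–0.14) drifting upward under climate change
  (+0.006/decade moderate, +0.015/decade severe, the latter also eroding
  conifer stems by 8 %/decade).

All stochastic mechanisms draw from named child streams of a single seed
(index-derived, never `hash()`-derived, so runs are stable across
processes). Directional test assertions — fuel builds up without
management, the severe scenario is drier, clearcut steps are empty — are
statements about these generator rules, **not** evidence about any real
forest simulator or landscape. Passing them shows the pipeline transmits
such signals; it does not validate the indicators ecologically.

The default acceptance-scale run (56 stands, 2 managements × 2 climates
× 3 decadal timesteps, 1 km² at 2 m fine resolution) was sized to
exercise every code path — concave and convex terrain, empty stands,
both normalization directions — while staying comfortable on a laptop;
the full assessment completes in a few seconds.

## Known limitations

* Indicators are uncoupled; interactions (e.g. vertical connectivity
  mattering more at high conifer share) are not modelled.
* Linear normalization only; the architecture accepts fixed thresholds
  but not non-linear ramps.
* The bark allometry default is synthetic (see above).
* Run-derived thresholds make pFire relative to the assessed run;
  cross-run comparisons require shared fixed thresholds.
* Planar distances and planar curvature assume a projected metric CRS;
  nothing reprojects, mixed CRS tags are rejected.
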