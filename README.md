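# firepas

Fire predisposition assessment for mountain forest stands.

`firepas` rates how conducive a forest stand and its surroundings are to
fire ignition, spread and extinction, and how resistant and resilient the
stand would be if a fire occurred. It is aimed at strategic forest
planning: foresters and decision-support-system builders who need a
transparent, component-wise fire risk indicator that works on forest
simulator output (cohort tree lists per stand and scenario) plus standard
GIS layers (a DEM, a stand map, infrastructure features).

## The score

Fourteen indicator components are computed per stand and scenario state,
normalized onto [0, 1], and aggregated into the overall predisposition

    pFire(t, m, c) = 0.5 · Σ_s λ_s · ST_s(t, m, c) + 0.5 · Σ_i λ_i · SI_i(t, m, c)

over stand-related components ST (s ∈ S) and site-related components SI
(i ∈ I), for timestep *t*, management strategy *m* and climate scenario
*c*, with per-side weights summing to 1.

**Site-related** (static per stand):

* terrain — planform curvature of a fine DEM (concave, canyon-like
  morphology favours fire spread; stand-mean of negative curvature,
  linearly rescaled between the 1st percentile and 0), slope and aspect
  class lookups at the stand centroid from a coarse DEM (categorical
  scores 0/0.25/0.5/0.75/1);
* climate — an annual drought index FCDI = 1 − ΣE_m/ΣD_m over months with
  mean temperature ≥ 5.5 °C (evapotranspiration supply E vs. soil demand
  D), scored as pf.clim = min(2·FCDI, 1);
* wildland–urban interface — Euclidean distances from the stand centroid
  to buildings, roads (ignition sources: near = predisposed) and to
  drivable roads, waterbodies (extinction capacity: far = predisposed),
  rescaled between the 1st and 99th percentile of observed distances.

**Stand-related** (per tree-list state): basal area per ha (fuel load),
conifer basal-area share, coefficient of variation of tree height
(vertical fuel connectivity), Reineke stand density index
SDI = N·(dg/25)^1.605 (horizontal fuel connectivity), and two
fire-impact components — *lack of resistance*, the basal-area-weighted
probability of post-fire tree mortality

    P_m = C_k^(t_c/t_f − 0.5),   P_m = 1 when t_c < 0.5·t_f,

with cambium-kill time t_c = 3.36·bt² (bark thickness bt in mm), scorched
crown fraction C_k from the crown scorch height
h_k = 3.94·FLI^1.17 / [(T_c − T_a)·(0.11·FLI + MFWS³)^½] (19.04 m at the
default FLI = 630 kW/m, MFWS = 1.8 m/s, T_a = 15 °C, T_c = 60 °C) and a
species-specific crown-base allometry; and *lack of long-term
resilience*, a basal-area-weighted palaeoecological fire-sensitivity
score per species (0 = extremely resilient … 1 = extremely sensitive).

Weights come from a two-level hierarchy (sub-group weights λp/λq ×
within-group weights ω, each summing to 1) or from named scenario presets
(`eq_weights`, `eq_weights_group`, `expert_weights`, `random_weights`);
the sensitivity module compares scenario rankings by Spearman
correlation, bins score distributions in 0.05 steps, and places
predefined scenarios within ensembles of random discrete weight draws.

Because several indicators are normalized against the observed value pool
of a run, pFire is a *relative* measure over that run, not an absolute
fire danger rating.

## Worked example

Everything runs offline on synthetic data: a seeded valley landscape with
56 stands and stylized decadal stand trajectories under two management
strategies and two climate scenarios.

```python
import firepas as fp
from firepas.synthetic import (LandscapeSpec, TrajectorySpec,
                               generate_landscape, generate_trajectories)

land = generate_landscape(LandscapeSpec(n_stands=56,
                                        terrain_kind="valley", seed=1))
states = generate_trajectories(TrajectorySpec(
    managements=("NO", "Clearcut"), climates=("historical", "SSP5-8.5"),
    timesteps=(2020, 2050, 2080), seed=1), land.stands)

result = fp.run_all(land, states, weights="expert_weights")
sc = result.scores
print("states scored:", len(sc))
print(sc[sc.timestep == 2080].groupby("management")["pFire"].mean().round(3))
```

prints

```
states scored: 672
management
Clearcut    0.204
NO          0.501
```

672 states = 56 stands × 2 managements × 2 climates × 3 timesteps; each
row carries the 14 component scores and pFire, all in [0, 1]. The mean
pFire of 0.50 for unmanaged stands against 0.20 under clearcutting at the
2080 horizon reflects the generator's forced fuel build-up without
management (and bare, freshly cut stands scoring 0 on all stand-related
components): the expected direction, useful as an end-to-end sanity
check. `result.thresholds` records the resolved P1/P99 normalization
thresholds of the run.

The same pipeline is scriptable from a shell:

```bash
firepas run-all --seed 1 --out runs/demo --scenario expert_weights
firepas sensitivity --in runs/demo --out runs/demo-sens --seed 1 --n-random 200
```

The scoring core is an sklearn-style transformer,
`firepas.FirePredispositionScorer`: `fit(raw_table)` learns the
percentile thresholds from the pooled observed raw indicators,
`transform(raw_table)` emits scores and pFire, so it composes with
sklearn pipelines and `clone`.

## Layout

* `src/firepas/` — `normalization`, `terrain`, `climate`, `wui`, `stand`,
  `weighting`, `sensitivity`, `synthetic`, `pipeline`, `io`, `cli`
* `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices and limitations
* `tests/` — unit, property (hypothesis) and acceptance suites
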