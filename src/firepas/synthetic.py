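"""Synthetic landscapes and forest trajectories for offline testing.

The generators stand in for the GIS layers and forest-gap-model output the
assessment normally consumes: a mountain DEM (plane / valley / ridge /
random field) at a coarse and a fine resolution, a jittered-grid stand map
of convex polygons, scattered infrastructure layers, and stylized stand
trajectories over (management x climate x decadal timestep). All
randomness flows from a single seed through named child streams, so equal
seeds give identical output and every directional property asserted in
tests is a statement about these generators, not about any real forest
simulator.

Stylized dynamics: cohorts grow in dbh (climate-modified increment with
noise), suffer background mortality, regenerate occasionally; management
removes stems (harvest intensity per strategy), Clearcut periodically
empties the stand and restarts from regeneration, and the hot-dry climate
scenario (SSP5-8.5) raises the drought index and erodes the conifer share
relative to historical climate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString, Point, Polygon, box

from .stand import DEFAULT_SPECIES_TRAITS, StandState, TreeRecord
from .terrain import DemGrid, StandGeometry
from .wui import FeatureLayer

MANAGEMENTS = ("NO", "CNF", "CNF-LOW", "CNF-HIGH", "CNF-ClimAdapt",
               "Clearcut")
CLIMATES = ("historical", "SSP2-4.5", "SSP5-8.5")

#: fraction of stems removed per decadal step
HARVEST_INTENSITY = {"NO": 0.0, "CNF": 0.20, "CNF-LOW": 0.10,
                     "CNF-HIGH": 0.30, "CNF-ClimAdapt": 0.20,
                     "Clearcut": 0.0}

#: (drought-index drift per decade, growth modifier, conifer stem decay
#: per decade) relative to historical climate
CLIMATE_EFFECTS = {
    "historical": (0.000, 1.00, 0.00),
    "SSP2-4.5": (0.006, 1.10, 0.02),
    "SSP5-8.5": (0.015, 0.95, 0.08),
}


@dataclass
class LandscapeSpec:
    """Parameters of a synthetic landscape."""

    extent: tuple[float, float] = (1000.0, 1000.0)  # m
    dem_cell_size: float = 25.0       # coarse DEM (slope/aspect)
    fine_cell_size: float = 2.0       # fine DEM (curvature)
    dem_buffer: float = 100.0         # DEM margin beyond the stand map, m
    terrain_kind: str = "valley"      # plane | valley | ridge | random_field
    base_slope: float = 0.2           # plane gradient / valley tilt, m/m
    relief: float = 120.0             # random-field relief amplitude, m
    roughness: float = 8.0            # random-field smoothing, cells
    n_stands: int = 56
    n_buildings: int = 25
    n_roads: int = 6
    n_drivable_roads: int = 3
    n_rivers: int = 2
    n_extraction_points: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.extent) <= 0 or self.n_stands < 1:
            raise ValueError("extent must be positive and n_stands >= 1")
        if self.terrain_kind not in ("plane", "valley", "ridge",
                                     "random_field"):
            raise ValueError(f"unknown terrain kind {self.terrain_kind!r}")


@dataclass
class TrajectorySpec:
    """Parameters of synthetic multi-scenario forest trajectories."""

    managements: tuple[str, ...] = ("NO", "Clearcut")
    climates: tuple[str, ...] = ("historical", "SSP5-8.5")
    timesteps: tuple[int, ...] = (2020, 2050, 2080)
    species_pool: tuple[str, ...] = ("Picea abies", "Larix decidua",
                                     "Pinus sylvestris", "Abies alba",
                                     "Fagus sylvatica")
    cohorts_per_stand: tuple[int, int] = (3, 6)
    dbh_growth_per_decade: float = 2.5   # cm
    mortality_per_decade: float = 0.05   # stem fraction
    clearcut_period: int = 3             # every k-th step
    fcdi_base_range: tuple[float, float] = (0.02, 0.14)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.managements) - set(MANAGEMENTS)
        if unknown:
            raise ValueError(f"unknown managements {sorted(unknown)}")
        unknown = set(self.climates) - set(CLIMATES)
        if unknown:
            raise ValueError(f"unknown climates {sorted(unknown)}")


@dataclass
class Landscape:
    dem_coarse: DemGrid
    dem_fine: DemGrid
    stands: list[StandGeometry]
    layers: dict[str, FeatureLayer]
    spec: LandscapeSpec = field(repr=False, default=None)


def _height_from_dbh(dbh: float) -> float:
    """Simple concave height-diameter curve keeping h/dbh within the
    0.15-1.25 m/cm band typical of the mortality model's validity range."""
    return float(1.3 + 0.55 * dbh ** 0.92)


def _surface(kind: str, xs, ys, spec: LandscapeSpec, rng) -> np.ndarray:
    w, h = spec.extent
    xx, yy = np.meshgrid(xs, ys)
    if kind == "plane":
        return 1500.0 + spec.base_slope * xx
    if kind in ("valley", "ridge"):
        # parabolic cross-section around the mid-line, tilted along y so
        # contours genuinely curve (a drained valley, not a flat trench)
        k = 4.0 * 80.0 / (w / 2) ** 2  # 80 m of relief at the rim
        cross = k / 4.0 * (xx - w / 2) ** 2
        if kind == "ridge":
            cross = -cross
        return 1500.0 + cross + spec.base_slope * yy
    # random_field: smoothed white noise
    from scipy.ndimage import gaussian_filter
    z = rng.standard_normal(xx.shape)
    z = gaussian_filter(z, spec.roughness, mode="reflect")
    z -= z.min()
    if z.max() > 0:
        z *= spec.relief / z.max()
    return 1200.0 + z + spec.base_slope * xx


def _make_dem(spec: LandscapeSpec, cell: float, rng) -> DemGrid:
    # the DEM extends a buffer beyond the stand map so every stand sits in
    # the window-complete interior (as a real DEM tile would)
    w, h = spec.extent
    b = spec.dem_buffer
    nc, nr = int(round((w + 2 * b) / cell)), int(round((h + 2 * b) / cell))
    xs = -b + (np.arange(nc) + 0.5) * cell
    ys = h + b - (np.arange(nr) + 0.5) * cell  # row 0 at the top (north)
    z = _surface(spec.terrain_kind, xs, ys, spec, rng)
    return DemGrid(z, cell, origin=(-b, h + b))


def _tile_stands(spec: LandscapeSpec, rng) -> list[StandGeometry]:
    """Jittered-grid tiling into convex (rectangular) stand polygons."""
    w, h = spec.extent
    nx = int(np.ceil(np.sqrt(spec.n_stands * w / h)))
    ny = int(np.ceil(spec.n_stands / nx))
    cw, ch = w / nx, h / ny
    stands = []
    for i in range(spec.n_stands):
        gx, gy = i % nx, i // nx
        jit = rng.uniform(0.04, 0.12, size=4)
        poly = box(gx * cw + jit[0] * cw, gy * ch + jit[1] * ch,
                   (gx + 1) * cw - jit[2] * cw, (gy + 1) * ch - jit[3] * ch)
        stands.append(StandGeometry(f"S{i:04d}", poly))
    return stands


def _random_polyline(rng, w, h, n_vertices=6) -> LineString:
    # a wiggly line crossing the extent roughly end to end
    if rng.random() < 0.5:
        xs = np.linspace(0, w, n_vertices)
        ys = rng.uniform(0, h, n_vertices)
    else:
        ys = np.linspace(0, h, n_vertices)
        xs = rng.uniform(0, w, n_vertices)
    return LineString(np.column_stack([xs, ys]))


def _make_layers(spec: LandscapeSpec, rng) -> dict[str, FeatureLayer]:
    w, h = spec.extent
    if min(spec.n_buildings, spec.n_roads, spec.n_drivable_roads,
           spec.n_rivers + spec.n_extraction_points) < 1:
        raise ValueError("every feature layer needs at least one feature")
    # buildings cluster near one corner (a village) with a scattered rest
    n_village = spec.n_buildings // 2
    pts = np.vstack([
        rng.uniform([0, 0], [0.25 * w, 0.25 * h], size=(n_village, 2)),
        rng.uniform([0, 0], [w, h],
                    size=(spec.n_buildings - n_village, 2)),
    ])
    buildings = []
    for x, y in pts:
        half = rng.uniform(5.0, 12.0)  # footprints 100-576 m2, >= 75 m2
        buildings.append(box(x - half, y - half, x + half, y + half))
    roads = [_random_polyline(rng, w, h) for _ in range(spec.n_roads)]
    drivable = roads[:spec.n_drivable_roads] or roads[:1]
    rivers = [_random_polyline(rng, w, h) for _ in range(spec.n_rivers)]
    extraction = [Point(xy) for xy in
                  rng.uniform([0, 0], [w, h],
                              size=(spec.n_extraction_points, 2))]
    return {
        "buildings": FeatureLayer("buildings", buildings, min_area_m2=75.0),
        "roads_all": FeatureLayer("roads_all", list(roads)),
        "roads_drivable": FeatureLayer("roads_drivable", list(drivable)),
        "waterbodies": FeatureLayer("waterbodies",
                                    list(rivers) + list(extraction)),
    }


def generate_landscape(spec: LandscapeSpec) -> Landscape:
    """Deterministic synthetic landscape for the given spec/seed."""
    ss = np.random.SeedSequence(spec.seed)
    rng_dem, rng_stands, rng_feat = (np.random.default_rng(c)
                                     for c in ss.spawn(3))
    dem_coarse = _make_dem(spec, spec.dem_cell_size, rng_dem)
    # fine DEM re-uses the same analytic surface (same rng state not
    # required for plane/valley/ridge; random_field uses its own draw)
    dem_fine = _make_dem(spec, spec.fine_cell_size,
                         np.random.default_rng(ss.spawn(1)[0]))
    stands = _tile_stands(spec, rng_stands)
    layers = _make_layers(spec, rng_feat)
    return Landscape(dem_coarse, dem_fine, stands, layers, spec)


# ----------------------------------------------------------- trajectories

def _initial_cohorts(rng, spec: TrajectorySpec) -> list[TreeRecord]:
    n = rng.integers(spec.cohorts_per_stand[0],
                     spec.cohorts_per_stand[1] + 1)
    pool = list(spec.species_pool)
    cohorts = []
    for _ in range(n):
        species = pool[rng.integers(len(pool))]
        dbh = float(np.clip(rng.lognormal(np.log(28), 0.35), 8.0, 80.0))
        stems = float(rng.uniform(60, 260))
        cohorts.append(TreeRecord(species, dbh, _height_from_dbh(dbh),
                                  stems))
    return cohorts


def _step_cohorts(cohorts, rng, spec, management, climate,
                  clearcut_now, regen_after_cut):
    _, growth_mod, conifer_decay = CLIMATE_EFFECTS[climate]
    traits = DEFAULT_SPECIES_TRAITS
    if clearcut_now:
        # observed as the bare, freshly cut stand
        return []
    out = []
    for t in cohorts:
        incr = max(0.0, spec.dbh_growth_per_decade * growth_mod
                   * (1 + 0.2 * rng.standard_normal()))
        dbh = t.dbh + incr
        stems = t.stems * (1 - spec.mortality_per_decade)
        stems *= (1 - HARVEST_INTENSITY[management])
        if traits[t.species].is_conifer:
            stems *= (1 - conifer_decay)
        if stems > 1.0:
            out.append(TreeRecord(t.species, dbh, _height_from_dbh(dbh),
                                  stems))
    # regeneration: dense restart after a clearcut, occasional pulses
    # under active management; ClimAdapt plants Abies alba
    if regen_after_cut or (management not in ("NO", "Clearcut")
                           and rng.random() < 0.5):
        species = ("Abies alba" if management == "CNF-ClimAdapt"
                   else spec.species_pool[rng.integers(
                       len(spec.species_pool))])
        dbh = float(rng.uniform(8.0, 14.0))
        stems = (float(rng.uniform(300, 700)) if regen_after_cut
                 else float(rng.uniform(40, 120)))
        out.append(TreeRecord(species, dbh, _height_from_dbh(dbh), stems))
    return out


def generate_trajectories(spec: TrajectorySpec,
                          stands: list[StandGeometry] | list[str]
                          ) -> list[StandState]:
    """Stand states over (stand x timestep x management x climate).

    Each (stand, management, climate) combination evolves its own cohort
    list from a shared per-stand initial state; the drought index starts
    from a per-stand base and drifts per climate scenario.
    """
    stand_ids = [s.stand_id if isinstance(s, StandGeometry) else str(s)
                 for s in stands]
    ss = np.random.SeedSequence(spec.seed)
    states: list[StandState] = []
    period = spec.clearcut_period
    for i_stand, (sid, child) in enumerate(
            zip(stand_ids, ss.spawn(len(stand_ids)))):
        rng_init = np.random.default_rng(child)
        initial = _initial_cohorts(rng_init, spec)
        fcdi_base = float(rng_init.uniform(*spec.fcdi_base_range))
        for i_m, management in enumerate(spec.managements):
            for i_c, climate in enumerate(spec.climates):
                drift, _, _ = CLIMATE_EFFECTS[climate]
                # independent, reproducible stream per trajectory (index
                # tuples, not hashes, so runs are stable across processes)
                rng = np.random.default_rng(np.random.SeedSequence(
                    (spec.seed, i_stand, i_m, i_c)))
                cohorts = [replace(c) for c in initial]
                for k, year in enumerate(spec.timesteps):
                    if k > 0:
                        is_cut = (management == "Clearcut"
                                  and k % period == period - 1)
                        after_cut = (management == "Clearcut" and k > 1
                                     and (k - 1) % period == period - 1)
                        cohorts = _step_cohorts(cohorts, rng, spec,
                                                management, climate,
                                                is_cut, after_cut)
                    fcdi = float(np.clip(
                        fcdi_base + drift * k
                        + 0.01 * rng.standard_normal(), 0.0, 1.0))
                    states.append(StandState(
                        sid, list(cohorts), fcdi=fcdi, timestep=year,
                        management=management, climate=climate))
    return states
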