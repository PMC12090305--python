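"""Wildland-urban interface components: nearest-feature distances.

Proximity to buildings and to roads of any kind raises ignition
probability (negative normalization: near = predisposed), while proximity
to drivable roads and to waterbodies (rivers + extraction points) raises
extinction capacity (positive normalization: far = predisposed). Distances
are planar Euclidean from the stand centroid to the nearest feature in a
projected metric CRS; a centroid inside a polygon feature has distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

#: layer kind -> normalization direction of its component score
LAYER_DIRECTIONS = {
    "buildings": "negative",
    "roads_all": "negative",
    "roads_drivable": "positive",
    "waterbodies": "positive",
}

LAYER_COMPONENTS = {
    "buildings": "pf.wui_build",
    "roads_all": "pf.wui_road",
    "roads_drivable": "pf.wui_road_drv",
    "waterbodies": "pf.wui_waterbody",
}

LAYER_RAW_COLUMNS = {
    "buildings": "dist_build",
    "roads_all": "dist_road",
    "roads_drivable": "dist_road_drv",
    "waterbodies": "dist_waterbody",
}


class EmptyLayerError(ValueError):
    pass


@dataclass
class FeatureLayer:
    """Infrastructure features of one kind, in the run CRS.

    ``min_area_m2`` filters polygon features by footprint area at
    construction (points/lines pass unfiltered) — used for the buildings
    layer, where only substantial buildings count as ignition sources.
    """

    kind: str
    geometries: list[BaseGeometry] = field(default_factory=list)
    min_area_m2: float = 0.0
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        if self.kind not in LAYER_DIRECTIONS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.min_area_m2 > 0:
            self.geometries = [
                g for g in self.geometries
                if g.geom_type not in ("Polygon", "MultiPolygon")
                or g.area >= self.min_area_m2
            ]

    def __len__(self) -> int:
        return len(self.geometries)


def nearest_distance(centroid: tuple[float, float],
                     layer: FeatureLayer) -> float:
    """Minimum Euclidean distance (m) from ``centroid`` to any feature in
    the layer; 0 if the centroid lies on/inside a feature."""
    if len(layer) == 0:
        raise EmptyLayerError(f"feature layer {layer.kind!r} is empty")
    pt = Point(centroid)
    tree = STRtree(layer.geometries)
    idx = tree.nearest(pt)
    return float(pt.distance(layer.geometries[idx]))


def distances_table(stands, layers: dict[str, FeatureLayer]) -> pd.DataFrame:
    """Per-stand nearest distance to each configured layer, indexed by
    stand_id, columns per LAYER_RAW_COLUMNS."""
    for kind, layer in layers.items():
        if len(layer) == 0:
            raise EmptyLayerError(f"feature layer {kind!r} is empty")
    trees = {k: STRtree(v.geometries) for k, v in layers.items()}
    rows = []
    for stand in stands:
        pt = Point(stand.centroid)
        row = {"stand_id": stand.stand_id}
        for kind, layer in layers.items():
            idx = trees[kind].nearest(pt)
            row[LAYER_RAW_COLUMNS[kind]] = float(
                pt.distance(layer.geometries[idx]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("stand_id")


def score_wui(distances, kind: str,
              thresholds: tuple[float, float] | None = None) -> np.ndarray:
    """Component score for one WUI layer from a pool of distances.

    P1/P99 linear normalization in the layer's direction; ``thresholds``
    overrides the percentile-derived pair (required for degenerate pools).
    """
    from .normalization import (NormalizationSpec, normalize_linear,
                                percentile_thresholds)
    direction = LAYER_DIRECTIONS[kind]
    arr = np.asarray(distances, dtype=float)
    if thresholds is None:
        lo, hi = percentile_thresholds(arr, name=LAYER_COMPONENTS[kind])
    else:
        lo, hi = thresholds
    spec = NormalizationSpec(direction, lo, hi)
    return normalize_linear(arr, spec)
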