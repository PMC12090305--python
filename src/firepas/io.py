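"""File formats: ESRI ASCII grid rasters, GeoJSON vectors, YAML configs.

All geometry lives in one projected metric CRS carried as an opaque tag;
readers reject mixed tags rather than reprojecting. Rasters use the ESRI
ASCII grid text format (upper-left origin, row-major); vectors use GeoJSON
FeatureCollections with a ``stand_id`` property for stands and a ``kind``
property for infrastructure layers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import mapping, shape

from .stand import (CROWN_COEFFS, RESILIENCE_SCORES, SpeciesTraits)
from .terrain import DemGrid, StandGeometry
from .wui import FeatureLayer


class CrsMismatchError(ValueError):
    pass


# ------------------------------------------------------------- rasters

def write_ascii_grid(path, dem: DemGrid, nodata: float = -9999.0) -> None:
    """Write a DEM as an ESRI ASCII grid (.asc)."""
    nr, nc = dem.shape
    x0, y_top = dem.origin
    yll = y_top - nr * dem.cell_size
    vals = np.where(np.isfinite(dem.values), dem.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\nnrows {nr}\n"
                 f"xllcorner {x0:.6f}\nyllcorner {yll:.6f}\n"
                 f"cellsize {dem.cell_size:.6f}\n"
                 f"NODATA_value {nodata:.1f}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


def read_ascii_grid(path, crs: str = "local-metric") -> DemGrid:
    header, rows = {}, []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    nc, nr = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    vals = np.array(rows, dtype=float)
    if vals.shape != (nr, nc):
        raise ValueError(f"grid body {vals.shape} != header ({nr}, {nc})")
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    origin = (header["xllcorner"], header["yllcorner"] + nr * cell)
    return DemGrid(vals, cell, origin=origin, crs=crs)


# ------------------------------------------------------------- vectors

def write_stands_geojson(path, stands: list[StandGeometry],
                         crs: str = "local-metric") -> None:
    fc = {"type": "FeatureCollection", "crs_tag": crs, "features": [
        {"type": "Feature",
         "properties": {"stand_id": s.stand_id,
                        "centroid": list(s.centroid)},
         "geometry": mapping(s.polygon)}
        for s in stands]}
    Path(path).write_text(json.dumps(fc))


def read_stands_geojson(path, expect_crs: str | None = None
                        ) -> list[StandGeometry]:
    fc = json.loads(Path(path).read_text())
    if expect_crs and fc.get("crs_tag", expect_crs) != expect_crs:
        raise CrsMismatchError(
            f"stands CRS {fc.get('crs_tag')!r} != run CRS {expect_crs!r}")
    out = []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        centroid = props.get("centroid")
        out.append(StandGeometry(str(props["stand_id"]),
                                 shape(feat["geometry"]),
                                 tuple(centroid) if centroid else None))
    return out


def write_layers_geojson(path, layers: dict[str, FeatureLayer],
                         crs: str = "local-metric") -> None:
    features = []
    for kind, layer in layers.items():
        for geom in layer.geometries:
            features.append({"type": "Feature",
                             "properties": {"kind": kind},
                             "geometry": mapping(geom)})
    fc = {"type": "FeatureCollection", "crs_tag": crs, "features": features}
    Path(path).write_text(json.dumps(fc))


def read_layers_geojson(path, expect_crs: str | None = None
                        ) -> dict[str, FeatureLayer]:
    fc = json.loads(Path(path).read_text())
    if expect_crs and fc.get("crs_tag", expect_crs) != expect_crs:
        raise CrsMismatchError(
            f"layer CRS {fc.get('crs_tag')!r} != run CRS {expect_crs!r}")
    geoms: dict[str, list] = {}
    for feat in fc["features"]:
        geoms.setdefault(feat["properties"]["kind"], []).append(
            shape(feat["geometry"]))
    return {kind: FeatureLayer(kind, gs) for kind, gs in geoms.items()}


# ----------------------------------------------------------- tree lists

def states_to_frame(states) -> "pd.DataFrame":
    """Tidy tree-list table (one row per cohort; empty stands keep a row
    with zero stems) plus the drought index."""
    import pandas as pd
    rows = []
    for st in states:
        base = {"stand_id": st.stand_id, "timestep": st.timestep,
                "management": st.management, "climate": st.climate,
                "fcdi": st.fcdi}
        if not st.trees:
            rows.append({**base, "species": "", "dbh_cm": np.nan,
                         "height_m": np.nan, "stems_per_ha": 0.0})
        for t in st.trees:
            rows.append({**base, "species": t.species, "dbh_cm": t.dbh,
                         "height_m": t.height, "stems_per_ha": t.stems})
    return pd.DataFrame(rows)


def frame_to_states(frame) -> list:
    """Inverse of :func:`states_to_frame`."""
    from .stand import StandState, TreeRecord
    states = []
    keys = ["stand_id", "timestep", "management", "climate"]
    for key, grp in frame.groupby(keys, sort=False):
        trees = [TreeRecord(r.species, r.dbh_cm, r.height_m, r.stems_per_ha)
                 for r in grp.itertuples()
                 if r.species and r.stems_per_ha > 0]
        states.append(StandState(key[0], trees,
                                 fcdi=float(grp["fcdi"].iloc[0]),
                                 timestep=key[1], management=key[2],
                                 climate=key[3]))
    return states


# -------------------------------------------------------------- configs

def species_traits_to_yaml(path, traits: dict[str, SpeciesTraits]) -> None:
    doc = {sp: {"is_conifer": t.is_conifer,
                "allometry_group": t.allometry_group,
                "bark_coeffs": list(t.bark_coeffs),
                "resilience_score": t.resilience_score}
           for sp, t in traits.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def species_traits_from_yaml(path) -> dict[str, SpeciesTraits]:
    doc = yaml.safe_load(Path(path).read_text())
    return {sp: SpeciesTraits(sp, d["is_conifer"], d["allometry_group"],
                              tuple(d["bark_coeffs"]),
                              float(d["resilience_score"]))
            for sp, d in doc.items()}


def write_run_manifest(path, *, seed: int, config: dict,
                       thresholds=None) -> None:
    """Plain-text record of a run: seed, configuration, resolved
    normalization thresholds."""
    import firepas
    doc = {"firepas_version": firepas.__version__, "seed": seed,
           "config": config}
    if thresholds is not None:
        doc["thresholds"] = thresholds.to_dict(orient="records")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
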