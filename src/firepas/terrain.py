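"""DEM geomorphometry and the three terrain predisposition components.

A local quadratic surface z = a·x² + b·y² + c·xy + d·x + e·y + f is fitted
by ordinary least squares in a moving window around every cell
(Evans-Wood style). Slope and aspect follow from the gradient (d, e),
planform curvature from the second-order terms. Slope and aspect are
evaluated at the stand centroid cell on a coarse DEM (7×7 window on 25 m
cells ≈ 175 m); planform curvature is computed on a fine DEM (9×9 window on
2 m cells = 18 m), clipped to its concave part and averaged over each stand
polygon.

Sign convention: planform (contour-direction) curvature is negative for
concave, canyon-like morphology and positive on ridges; the synthetic
valley/ridge tests pin this convention down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .normalization import NormalizationSpec, normalize_linear

#: slope bands (deg) -> categorical predisposition, Austrian Alps fire
#: danger classification: <10 or >=50 very low, then 0.25 steps per 10 deg
SLOPE_BINS = ((10.0, 20.0, 0.25), (20.0, 30.0, 0.50),
              (30.0, 40.0, 0.75), (40.0, 50.0, 1.00))

#: 8-sector compass class -> categorical predisposition (south-facing
#: slopes are driest and most fire-prone)
ASPECT_SCORES = {"N": 0.00, "NE": 0.25, "E": 0.25, "SE": 0.50,
                 "S": 1.00, "SW": 0.75, "W": 0.25, "NW": 0.25}

_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

FLAT_GRADIENT_TOL = 1e-9


@dataclass
class DemGrid:
    """Single-band elevation raster in a projected metric CRS.

    ``values`` is row-major with the first row at the top (north);
    ``origin`` is the (x, y) of the upper-left cell *corner*.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = float("nan")
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DEM must be a 2-D grid")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size,
                y0 - (row + 0.5) * self.cell_size)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y); half-open cell intervals."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise ValueError(f"point ({x}, {y}) outside DEM extent")
        return row, col


@dataclass
class StandGeometry:
    """A stand polygon with its (geometric, unless supplied) centroid."""

    stand_id: str
    polygon: Polygon
    centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ValueError(f"stand {self.stand_id}: invalid polygon")
        if self.centroid is None:
            c = self.polygon.centroid
            self.centroid = (c.x, c.y)


@dataclass
class SurfaceFit:
    """Per-cell quadratic coefficients (a, b, c, d, e, f); nodata = NaN
    where the window was incomplete."""

    coeffs: np.ndarray  # (nrow, ncol, 6)
    cell_size: float

    def __getitem__(self, key):  # coeffs[row, col] -> (6,) vector
        return self.coeffs[key]


def fit_local_surface(dem: DemGrid, window_cells: int) -> SurfaceFit:
    """OLS fit of the local quadratic in a ``window_cells``² moving window.

    Window coordinates are centered on the target cell and expressed in
    metres (x east, y north), so d and e are the metric partial derivatives
    at the cell. Border cells without a complete window are NaN.
    """
    if window_cells < 3 or window_cells % 2 == 0:
        raise ValueError("window_cells must be odd and >= 3")
    nr, nc = dem.shape
    if window_cells > min(nr, nc):
        raise ValueError("window larger than grid")
    half = window_cells // 2
    offs = (np.arange(window_cells) - half) * dem.cell_size
    # rows increase southwards -> y decreases with row offset
    xx, yy = np.meshgrid(offs, -offs)  # yy[i] north offset of window row i
    X = np.column_stack([
        xx.ravel() ** 2, yy.ravel() ** 2, (xx * yy).ravel(),
        xx.ravel(), yy.ravel(), np.ones(window_cells ** 2),
    ])
    # fixed design matrix -> solve via precomputed pseudo-inverse;
    # each coefficient is then a linear filter of the window values
    pinv = np.linalg.pinv(X)  # (6, w*w)
    win = np.lib.stride_tricks.sliding_window_view(
        dem.values, (window_cells, window_cells))
    flat = win.reshape(win.shape[0], win.shape[1], -1)
    inner = np.tensordot(flat, pinv.T, axes=([2], [0]))  # (nr-2h, nc-2h, 6)
    coeffs = np.full((nr, nc, 6), np.nan)
    coeffs[half:nr - half, half:nc - half] = inner
    # propagate nodata: any non-finite cell in the window voids the fit
    bad = ~np.isfinite(flat).all(axis=2)
    coeffs[half:nr - half, half:nc - half][bad] = np.nan
    return SurfaceFit(coeffs, dem.cell_size)


def slope_deg(fit: SurfaceFit) -> np.ndarray:
    """Slope in degrees from the fitted gradient: atan(√(d² + e²))."""
    d, e = fit.coeffs[..., 3], fit.coeffs[..., 4]
    return np.degrees(np.arctan(np.hypot(d, e)))


def aspect_deg(fit: SurfaceFit) -> np.ndarray:
    """Downslope compass direction in degrees clockwise from north,
    NaN where the gradient magnitude is below the flat tolerance."""
    d, e = fit.coeffs[..., 3], fit.coeffs[..., 4]
    grad = np.hypot(d, e)
    # steepest descent points along -(d, e); azimuth measured from north
    asp = np.degrees(np.arctan2(-d, -e)) % 360.0
    return np.where(grad < FLAT_GRADIENT_TOL, np.nan, asp)


def planar_curvature(fit: SurfaceFit) -> np.ndarray:
    """Planform (contour-direction) curvature, 1/m.

    For z with gradient (d, e) and second derivatives z_xx = 2a,
    z_yy = 2b, z_xy = c, the curvature of the level contour is

        k = −(z_xx·e² − 2·z_xy·d·e + z_yy·d²) / (d² + e²)^{3/2}

    negative in concave (canyon-like) terrain, positive on ridges, and 0 on
    flat cells (where the contour direction is undefined).
    """
    a, b, c = fit.coeffs[..., 0], fit.coeffs[..., 1], fit.coeffs[..., 2]
    d, e = fit.coeffs[..., 3], fit.coeffs[..., 4]
    g2 = d * d + e * e
    with np.errstate(invalid="ignore", divide="ignore"):
        num = -(2 * a * e * e - 2 * c * d * e + 2 * b * d * d)
        curv = num / np.power(g2, 1.5)
    curv = np.where(g2 < FLAT_GRADIENT_TOL ** 2, 0.0, curv)
    # snap least-squares noise on planar surfaces to exactly zero
    # (meaningful terrain curvature is orders of magnitude above 1e-12/m)
    curv = np.where(np.abs(curv) < 1e-12, 0.0, curv)
    curv[~np.isfinite(fit.coeffs[..., 0])] = np.nan
    return curv


def stand_mean_negative_curvature(curv: np.ndarray, dem: DemGrid,
                                  stands: list[StandGeometry]) -> pd.Series:
    """Per-stand mean of min(curvature, 0) over cells whose centers fall
    inside the stand polygon. Stands with only flat/convex cells score 0;
    stands covering no valid cell are NaN (flagged upstream).
    """
    clipped = np.minimum(curv, 0.0)
    nr, nc = dem.shape
    x0, y0 = dem.origin
    cs = dem.cell_size
    out = {}
    for stand in stands:
        minx, miny, maxx, maxy = stand.polygon.bounds
        c0 = max(0, int(np.floor((minx - x0) / cs)))
        c1 = min(nc - 1, int(np.floor((maxx - x0) / cs)))
        r0 = max(0, int(np.floor((y0 - maxy) / cs)))
        r1 = min(nr - 1, int(np.floor((y0 - miny) / cs)))
        prepared = prep(stand.polygon)
        vals = []
        for r in range(r0, r1 + 1):
            cy = y0 - (r + 0.5) * cs
            for ccol in range(c0, c1 + 1):
                cx = x0 + (ccol + 0.5) * cs
                if prepared.contains(Point(cx, cy)):
                    v = clipped[r, ccol]
                    if np.isfinite(v):
                        vals.append(v)
        out[stand.stand_id] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, name="mean_neg_curv")


def score_curvature(mean_neg_curv, p1_threshold: float):
    """pf.ter_curv: linear negative map, 0 at curvature ≥ 0 and 1 at the
    P1 (most strongly concave) threshold."""
    if not np.isfinite(p1_threshold) or p1_threshold >= 0:
        raise ValueError("curvature P1 threshold must be finite and < 0")
    spec = NormalizationSpec("negative", p1_threshold, 0.0, "fixed")
    return normalize_linear(mean_neg_curv, spec)


def score_slope(slope: float) -> float:
    """pf.ter_slp: categorical slope predisposition (5-level lookup)."""
    if not np.isfinite(slope) or not (0.0 <= slope <= 90.0):
        raise ValueError(f"slope {slope!r} outside [0, 90] degrees")
    for lo, hi, score in SLOPE_BINS:
        if lo <= slope < hi:
            return score
    return 0.0  # < 10 deg or >= 50 deg


def aspect_sector(aspect: float) -> str:
    """8-sector compass class; boundaries 22.5° either side of each point."""
    idx = int(np.floor(((aspect + 22.5) % 360.0) / 45.0))
    return _SECTORS[idx]


def score_aspect(aspect: float | None) -> float:
    """pf.ter_asp: categorical aspect predisposition; flat (undefined
    aspect) maps to the N class, score 0."""
    if aspect is None or not np.isfinite(aspect):
        return 0.0
    if not (0.0 <= aspect < 360.0):
        aspect = aspect % 360.0
    return ASPECT_SCORES[aspect_sector(aspect)]


@dataclass
class TerrainResult:
    """Per-stand raw terrain measures + scores, and the resolved
    curvature threshold."""

    table: pd.DataFrame
    curvature_p1: float | None = None
    flags: dict = field(default_factory=dict)


def assess_terrain(dem_coarse: DemGrid, dem_fine: DemGrid,
                   stands: list[StandGeometry],
                   window_coarse: int = 7, window_fine: int = 9,
                   curvature_p1: float | None = None) -> TerrainResult:
    """Full terrain stage: slope/aspect at stand centroids from the coarse
    DEM, polygon-aggregated concave planform curvature from the fine DEM,
    then the three component scores.

    ``curvature_p1`` fixes the curvature threshold; if None it is the 1st
    percentile of the observed per-stand means (falling back to score 0
    everywhere when no stand is concave).
    """
    fit_c = fit_local_surface(dem_coarse, window_coarse)
    slp = slope_deg(fit_c)
    asp = aspect_deg(fit_c)
    fit_f = fit_local_surface(dem_fine, window_fine)
    curv = planar_curvature(fit_f)
    mean_curv = stand_mean_negative_curvature(curv, dem_fine, stands)

    rows, flags = [], {}
    for stand in stands:
        r, c = dem_coarse.cell_of(*stand.centroid)
        s, a = slp[r, c], asp[r, c]
        if not np.isfinite(s):  # centroid too close to the border
            flags[stand.stand_id] = "incomplete-window-at-centroid"
        rows.append({"stand_id": stand.stand_id, "slope_deg": s,
                     "aspect_deg": a,
                     "mean_neg_curv": mean_curv[stand.stand_id]})
    table = pd.DataFrame(rows).set_index("stand_id")

    p1 = curvature_p1
    if p1 is None:
        observed = table["mean_neg_curv"].to_numpy()
        observed = observed[np.isfinite(observed)]
        neg = observed[observed < 0]
        p1 = float(np.percentile(neg, 1)) if neg.size else None

    table["pf.ter_slp"] = [score_slope(s) if np.isfinite(s) else np.nan
                           for s in table["slope_deg"]]
    table["pf.ter_asp"] = [score_aspect(a) for a in table["aspect_deg"]]
    if p1 is not None:
        table["pf.ter_curv"] = [
            score_curvature(v, p1) if np.isfinite(v) else np.nan
            for v in table["mean_neg_curv"]]
    else:  # nothing concave anywhere: all-zero by the >= 0 rule
        table["pf.ter_curv"] = np.where(
            np.isfinite(table["mean_neg_curv"]), 0.0, np.nan)
    return TerrainResult(table, p1, flags)
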