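"""Geomorphometry against analytic surfaces and the categorical lookups."""

import numpy as np
import pytest
from shapely.geometry import box

from firepas.terrain import (DemGrid, StandGeometry, aspect_deg,
                             assess_terrain, fit_local_surface,
                             planar_curvature, score_aspect,
                             score_curvature, score_slope, slope_deg,
                             stand_mean_negative_curvature)


def make_dem(fn, n=21, cell=1.0):
    xs = (np.arange(n) + 0.5) * cell
    ys = n * cell - (np.arange(n) + 0.5) * cell
    xx, yy = np.meshgrid(xs, ys)
    return DemGrid(fn(xx, yy), cell, origin=(0.0, n * cell))


class TestSurfaceFit:
    def test_inclined_plane_recovers_gradient_exactly(self):
        dem = make_dem(lambda x, y: 0.2 * x)
        fit = fit_local_surface(dem, 5)
        a, b, c, d, e, _ = fit[10, 10]
        assert d == pytest.approx(0.2, abs=1e-12)
        for v in (a, b, c, e):
            assert v == pytest.approx(0.0, abs=1e-10)

    def test_constant_grid_only_intercept(self):
        dem = make_dem(lambda x, y: np.full_like(x, 7.0))
        fit = fit_local_surface(dem, 3)
        assert fit[5, 5][:5] == pytest.approx(np.zeros(5), abs=1e-10)
        assert fit[5, 5][5] == pytest.approx(7.0)

    def test_random_patch_equals_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        dem = DemGrid(rng.normal(size=(9, 9)), 2.0, origin=(0.0, 18.0))
        fit = fit_local_surface(dem, 9)
        offs = (np.arange(9) - 4) * 2.0
        xx, yy = np.meshgrid(offs, -offs)
        X = np.column_stack([xx.ravel() ** 2, yy.ravel() ** 2,
                             (xx * yy).ravel(), xx.ravel(), yy.ravel(),
                             np.ones(81)])
        beta, *_ = np.linalg.lstsq(X, dem.values.ravel(), rcond=None)
        assert fit[4, 4] == pytest.approx(beta, abs=1e-9)

    def test_window_larger_than_grid_rejected(self):
        dem = make_dem(lambda x, y: x, n=5)
        with pytest.raises(ValueError):
            fit_local_surface(dem, 7)
        with pytest.raises(ValueError):
            fit_local_surface(dem, 4)  # even window


class TestSlopeAspect:
    def test_plane_slope_and_westward_aspect(self):
        # z rises eastwards at 0.2 -> the face looks west (270 deg)
        dem = make_dem(lambda x, y: 0.2 * x)
        fit = fit_local_surface(dem, 5)
        interior = slice(4, -4)
        assert np.allclose(slope_deg(fit)[interior, interior],
                           np.degrees(np.arctan(0.2)), atol=1e-6)
        assert np.allclose(aspect_deg(fit)[interior, interior], 270.0,
                           atol=1e-6)

    def test_south_facing_plane(self):
        # z rises northwards -> downslope faces south (180 deg)
        dem = make_dem(lambda x, y: 0.1 * y)
        fit = fit_local_surface(dem, 5)
        assert aspect_deg(fit)[10, 10] == pytest.approx(180.0, abs=1e-6)

    def test_flat_plane_slope_zero_aspect_undefined(self):
        dem = make_dem(lambda x, y: np.full_like(x, 3.0))
        fit = fit_local_surface(dem, 5)
        assert slope_deg(fit)[10, 10] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(aspect_deg(fit)[10, 10])


class TestPlanarCurvature:
    def test_plane_curvature_zero(self):
        dem = make_dem(lambda x, y: 0.3 * x + 0.1 * y)
        fit = fit_local_surface(dem, 5)
        assert np.allclose(planar_curvature(fit)[4:-4, 4:-4], 0.0,
                           atol=1e-9)

    def test_tilted_valley_negative_ridge_positive(self):
        # valley along y with longitudinal fall: contours curve around
        # the axis -> concave (negative) near the axis; negated -> ridge
        k, m, n = 0.01, 0.05, 41
        dem_v = make_dem(lambda x, y: k * (x - 20) ** 2 + m * y, n=n)
        dem_r = make_dem(lambda x, y: -k * (x - 20) ** 2 - m * y, n=n)
        cv = planar_curvature(fit_local_surface(dem_v, 5))
        cr = planar_curvature(fit_local_surface(dem_r, 5))
        axis = cv[10:30, 18:23]
        assert (axis < 0).all()
        assert (cr[10:30, 18:23] > 0).all()

    def test_bowl_matches_closed_form_contour_curvature(self):
        # z = k r^2: contours are circles of radius r, curvature -1/r
        k = 0.05
        dem = make_dem(lambda x, y: k * ((x - 20) ** 2 + (y - 20) ** 2),
                       n=41)
        curv = planar_curvature(fit_local_surface(dem, 3))
        r_cell, c_cell = 10, 20  # 10 m north of center -> r = 10... row 20
        # cell (row, col) = (10, 20): center (20.5, 30.5), r ~ 10.51
        x, y = dem.cell_center(10, 20)
        r = np.hypot(x - 20, y - 20)
        assert curv[10, 20] == pytest.approx(-1.0 / r, rel=1e-2)


class TestStandAggregation:
    def test_mean_negative_curvature_clips_convex_cells(self):
        curv = np.array([[-0.2, 0.3], [-0.1, 0.5]])
        dem = DemGrid(np.zeros((2, 2)), 1.0, origin=(0.0, 2.0))
        stand = StandGeometry("s1", box(0, 0, 2, 2))
        out = stand_mean_negative_curvature(curv, dem, [stand])
        assert out["s1"] == pytest.approx((-0.2 + 0 - 0.1 + 0) / 4)

    def test_convex_only_stand_scores_zero(self):
        curv = np.full((2, 2), 0.4)
        dem = DemGrid(np.zeros((2, 2)), 1.0, origin=(0.0, 2.0))
        out = stand_mean_negative_curvature(
            curv, dem, [StandGeometry("s", box(0, 0, 2, 2))])
        assert out["s"] == 0.0
        assert score_curvature(0.0, -0.5) == 0.0

    def test_stand_outside_grid_flagged_missing(self):
        curv = np.zeros((2, 2))
        dem = DemGrid(np.zeros((2, 2)), 1.0, origin=(0.0, 2.0))
        out = stand_mean_negative_curvature(
            curv, dem, [StandGeometry("far", box(10, 10, 11, 11))])
        assert np.isnan(out["far"])


class TestCategoricalScores:
    @pytest.mark.parametrize("slope, expected", [
        (0, 0.0), (9.9, 0.0), (10, 0.25), (15, 0.25), (20, 0.5),
        (30, 0.75), (35, 0.75), (40, 1.0), (49.9, 1.0), (50, 0.0),
        (55, 0.0), (90, 0.0),
    ])
    def test_slope_classes(self, slope, expected):
        assert score_slope(slope) == expected

    def test_slope_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_slope(91.0)
        with pytest.raises(ValueError):
            score_slope(-1.0)

    @pytest.mark.parametrize("aspect, expected", [
        (0, 0.0), (350, 0.0), (22.4, 0.0),      # N sector
        (45, 0.25), (90, 0.25), (270, 0.25), (315, 0.25),
        (135, 0.5), (180, 1.0), (225, 0.75),
        (None, 0.0),                             # flat: undefined aspect
    ])
    def test_aspect_classes(self, aspect, expected):
        assert score_aspect(aspect) == expected

    def test_score_sets_match_lookup_tables(self):
        slopes = {score_slope(s) for s in np.linspace(0, 89.9, 500)}
        aspects = {score_aspect(a) for a in np.linspace(0, 359.9, 500)}
        assert slopes == {0.0, 0.25, 0.5, 0.75, 1.0}
        assert aspects == {0.0, 0.25, 0.5, 0.75, 1.0}

    def test_curvature_score_linear_and_guarded(self):
        assert score_curvature(-0.5, -0.5) == pytest.approx(1.0)
        assert score_curvature(-0.25, -0.5) == pytest.approx(0.5)
        assert score_curvature(-0.9, -0.5) == pytest.approx(1.0)  # clamp
        with pytest.raises(ValueError):
            score_curvature(-0.1, 0.0)


def test_assess_terrain_full_stage(small_landscape):
    res = assess_terrain(small_landscape.dem_coarse,
                         small_landscape.dem_fine,
                         small_landscape.stands)
    t = res.table
    assert len(t) == len(small_landscape.stands)
    assert t["mean_neg_curv"].le(0).all()
    for col in ("pf.ter_slp", "pf.ter_asp", "pf.ter_curv"):
        assert t[col].between(0, 1).all()
    # valley landscape: at least one stand sits in concave terrain
    assert (t["mean_neg_curv"] < 0).any()
    assert res.curvature_p1 is not None and res.curvature_p1 < 0
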