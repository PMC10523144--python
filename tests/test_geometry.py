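import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletradius.geometry import (
    Centroid,
    DegeneratePolygonError,
    InvalidPolygonWarning,
    IsletPolygon,
    PolarPointSet,
    boundary_radius_at_angle,
    islet_summary,
    mask_to_points,
    polygon_centroid,
    relative_area,
    relative_radii,
    to_polar,
    validate_polygon,
)
from isletradius.simulate import regular_ngon

from oracles import random_convex_polygon

SQRT2 = math.sqrt(2.0)


def validated(vertices, method="vertex_mean"):
    poly = IsletPolygon(vertices)
    c = polygon_centroid(poly, method=method)
    _, v = validate_polygon(poly, c)
    return v, c


class TestCentroid:
    @pytest.mark.parametrize(
        "vertices, expected",
        [
            ([[1, 1], [-1, 1], [-1, -1], [1, -1]], (0.0, 0.0)),
            ([[0, 0], [3, 0], [0, 3]], (1.0, 1.0)),
        ],
    )
    def test_vertex_mean(self, vertices, expected):
        c = polygon_centroid(IsletPolygon(vertices))
        assert (c.cx, c.cy) == pytest.approx(expected)

    def test_cyclic_rotation_invariance(self, rng):
        verts = random_convex_polygon(rng)
        ref = polygon_centroid(IsletPolygon(verts))
        for k in range(1, len(verts)):
            c = polygon_centroid(IsletPolygon(np.roll(verts, k, axis=0)))
            assert (c.cx, c.cy) == pytest.approx((ref.cx, ref.cy), abs=1e-12)

    def test_area_centroid_square(self, unit_square):
        c = polygon_centroid(IsletPolygon(unit_square), method="area")
        assert (c.cx, c.cy) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(DegeneratePolygonError):
            IsletPolygon([[0, 0], [1, 1], [0, 0], [1, 1]])

    def test_consecutive_duplicates_removed(self):
        poly = IsletPolygon([[0, 0], [0, 0], [3, 0], [0, 3], [0, 0]])
        assert len(poly) == 3


class TestToPolar:
    @pytest.mark.parametrize(
        "point, center, expected",
        [
            ((1, 0), (0, 0), (0.0, 1.0)),
            ((0, 1), (0, 0), (math.pi / 2, 1.0)),
            ((-2, 0), (-1, 0), (math.pi, 1.0)),
        ],
    )
    def test_examples(self, point, center, expected):
        theta, r = to_polar([point], Centroid(*center))
        assert theta[0] == pytest.approx(expected[0])
        assert r[0] == pytest.approx(expected[1])

    def test_point_at_center_gets_theta_zero(self):
        theta, r = to_polar([(2.0, 3.0)], Centroid(2.0, 3.0))
        assert r[0] == 0.0 and theta[0] == 0.0

    def test_range(self, rng):
        pts = rng.normal(size=(500, 2)) * 50
        theta, r = to_polar(pts, Centroid(1.0, -2.0))
        assert np.all((theta >= 0) & (theta < 2 * np.pi))
        assert np.all(r >= 0)


class TestValidatePolygon:
    @pytest.mark.parametrize("start", range(4))
    @pytest.mark.parametrize("orientation", [1, -1])
    def test_convex_square_always_valid(self, unit_square, start, orientation):
        verts = np.roll(unit_square[::orientation], start, axis=0)
        poly = IsletPolygon(verts)
        ok, v = validate_polygon(poly, polygon_centroid(poly))
        assert ok and not v.was_invalid
        assert np.array_equal(v.vertices, poly.vertices)

    def test_scrambled_order_sorted_and_reported(self):
        # vertex angles 0, 180, 90, 270 degrees
        verts = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], float)
        poly = IsletPolygon(verts)
        with pytest.warns(InvalidPolygonWarning):
            ok, v = validate_polygon(poly, polygon_centroid(poly))
        assert not ok and v.was_invalid
        expected = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], float)
        assert np.array_equal(v.vertices, expected)

    def test_random_convex_valid_any_start(self, rng):
        for _ in range(20):
            verts = random_convex_polygon(rng)
            k = int(rng.integers(len(verts)))
            poly = IsletPolygon(np.roll(verts, k, axis=0))
            ok, _ = validate_polygon(poly, polygon_centroid(poly))
            assert ok

    def test_equal_angle_ties_sorted_by_radius(self):
        # two vertices in the same direction from the centroid-ish center
        verts = np.array([[2, 0], [0, 2], [1, 0], [0, -2], [-2, 0]], float)
        poly = IsletPolygon(verts)
        c = Centroid(0.0, 0.0)
        with pytest.warns(InvalidPolygonWarning):
            _, v = validate_polygon(poly, c)
        thetas, radii = to_polar(v.vertices, c)
        same = np.isclose(thetas, 0.0)
        assert np.all(np.diff(radii[same]) >= 0)


class TestBoundaryRadius:
    def test_square_vertex_hit(self, unit_square):
        v, c = validated(unit_square)
        assert boundary_radius_at_angle(v, c, math.pi / 4) == pytest.approx(SQRT2)

    def test_square_edge_midangle_is_interpolated_not_intersected(self, unit_square):
        # angular interpolation between two equal vertex radii gives sqrt(2);
        # the exact ray-edge intersection would give 1.0
        v, c = validated(unit_square)
        assert boundary_radius_at_angle(v, c, 0.0) == pytest.approx(SQRT2)

    def test_regular_256gon_approximates_circle(self):
        v, c = validated(regular_ngon(256, 1.0, (0.0, 0.0)))
        theta = np.linspace(0, 2 * np.pi, 999, endpoint=False)
        rb = boundary_radius_at_angle(v, c, theta)
        assert np.max(np.abs(np.asarray(rb) - 1.0)) < 1e-3

    def test_theta_outside_range_normalized(self, unit_square):
        v, c = validated(unit_square)
        a = boundary_radius_at_angle(v, c, 0.3)
        b = boundary_radius_at_angle(v, c, 0.3 + 2 * math.pi)
        d = boundary_radius_at_angle(v, c, 0.3 - 2 * math.pi)
        assert a == pytest.approx(b) == pytest.approx(d)


class TestRelativeRadii:
    def test_point_at_centroid_is_zero(self, unit_square):
        v, c = validated(unit_square)
        assert relative_radii([(0.0, 0.0)], v, c).rel_radius[0] == 0.0

    def test_point_at_vertex_is_exactly_100(self, unit_square):
        v, c = validated(unit_square)
        assert relative_radii([(1.0, 1.0)], v, c).rel_radius[0] == 100.0

    def test_square_hand_derived_interpolation_value(self, unit_square):
        v, c = validated(unit_square)
        rel = relative_radii([(0.5, 0.0)], v, c).rel_radius[0]
        assert rel == pytest.approx(100 * 0.5 / SQRT2, abs=1e-9)  # 35.3553...

    def test_output_order_matches_input(self, unit_square, rng):
        v, c = validated(unit_square)
        pts = rng.uniform(-0.5, 0.5, size=(50, 2))
        res = relative_radii(pts, v, c)
        for i in [0, 7, 49]:
            single = relative_radii(pts[i : i + 1], v, c)
            assert res.rel_radius[i] == single.rel_radius[0]

    def test_empty_input_gives_empty_result(self, unit_square):
        v, c = validated(unit_square)
        assert len(relative_radii(np.empty((0, 2)), v, c)) == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_similarity_invariance(self, seed):
        """Scaling, rotating and translating polygon and points together
        leaves every relative radius unchanged."""
        r = np.random.default_rng(seed)
        verts = random_convex_polygon(r)
        v, c = validated(verts)
        theta = r.uniform(0, 2 * np.pi, 8)
        f = r.uniform(0, 0.95, 8)
        rb = np.asarray(boundary_radius_at_angle(v, c, theta))
        pts = np.column_stack(
            (c.cx + f * rb * np.cos(theta), c.cy + f * rb * np.sin(theta))
        )
        ref = relative_radii(pts, v, c).rel_radius

        ang = r.uniform(0, 2 * np.pi)
        scale = r.uniform(0.1, 10)
        shift = r.uniform(-100, 100, 2)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        tverts = verts @ rot.T * scale + shift
        tpts = pts @ rot.T * scale + shift
        tv, tc = validated(tverts)
        got = relative_radii(tpts, tv, tc).rel_radius
        np.testing.assert_allclose(got, ref, rtol=1e-9)

    def test_monotone_in_r_for_fixed_theta(self, rng):
        verts = random_convex_polygon(rng)
        v, c = validated(verts)
        theta = 1.2345
        rb = float(boundary_radius_at_angle(v, c, theta))
        f = np.linspace(0.01, 0.99, 25)
        pts = np.column_stack(
            (c.cx + f * rb * np.cos(theta), c.cy + f * rb * np.sin(theta))
        )
        rel = relative_radii(pts, v, c).rel_radius
        assert np.all(np.diff(rel) > 0)

    def test_circle_limit(self):
        """Regular 256-gon: a point at radius fraction f has relative radius
        100 f within 0.5%."""
        v, c = validated(regular_ngon(256, 80.0, (0.0, 0.0)))
        for f in np.arange(0.1, 1.0, 0.1):
            theta = np.linspace(0, 2 * np.pi, 37, endpoint=False)
            pts = np.column_stack((f * 80 * np.cos(theta), f * 80 * np.sin(theta)))
            rel = relative_radii(pts, v, c).rel_radius
            assert np.max(np.abs(rel - 100 * f)) < 0.5


class TestIsletSummary:
    @staticmethod
    def from_rel(rel):
        rel = np.asarray(rel, float)
        z = np.zeros_like(rel)
        return PolarPointSet(z, z, np.ones_like(rel), rel)

    def test_plain_mean(self):
        s = islet_summary(self.from_rel([20, 40, 60]))
        assert s.mean_relative_radius_pct == pytest.approx(40.0)
        assert s.pct_excluded == 0.0 and s.n_excluded == 0

    def test_exclusion_of_radii_above_100(self):
        s = islet_summary(self.from_rel([20, 40, 60, 120]))
        assert s.mean_relative_radius_pct == pytest.approx(40.0)
        assert s.n_excluded == 1
        assert s.pct_excluded == pytest.approx(25.0)

    def test_exactly_100_is_included(self):
        s = islet_summary(self.from_rel([100.0, 50.0]))
        assert s.n_included == 2
        assert s.mean_relative_radius_pct == pytest.approx(75.0)

    def test_no_staining_flagged_never_zero(self):
        s = islet_summary(PolarPointSet.empty())
        assert s.excluded_no_staining
        assert math.isnan(s.mean_relative_radius_pct)
        assert s.n_cell_pixels == 0

    @given(
        st.lists(st.floats(min_value=0, max_value=200, allow_nan=False), max_size=60)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_and_bounds(self, rel):
        s = islet_summary(self.from_rel(rel))
        assert s.n_included + s.n_excluded == len(rel)
        if rel:
            assert s.pct_excluded == pytest.approx(100.0 * s.n_excluded / len(rel))
        if s.n_included > 0:
            assert 0.0 <= s.mean_relative_radius_pct <= 100.0


class TestRelativeArea:
    def rect(self, w, h):
        # covers pixel centers (x+0.5, y+0.5) for x in [0,w), y in [0,h)
        return IsletPolygon([[0, 0], [w, 0], [w, h], [0, h]])

    def test_fully_positive_is_100(self):
        mask = np.ones((10, 20), dtype=bool)
        n_cell, n_islet, pct = relative_area(mask, self.rect(20, 10))
        assert (n_cell, n_islet) == (200, 200)
        assert pct == 100.0

    def test_50_of_200_is_25(self):
        mask = np.zeros((10, 20), dtype=bool)
        mask.ravel()[:50] = True
        n_cell, n_islet, pct = relative_area(mask, self.rect(20, 10))
        assert (n_cell, n_islet) == (50, 200)
        assert pct == 25.0

    def test_degenerate_raster_polygon_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        with pytest.raises(DegeneratePolygonError):
            relative_area(mask, IsletPolygon([[50, 50], [60, 50], [55, 60]]))

    def test_mask_to_points_centers(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 1] = True
        assert np.array_equal(mask_to_points(mask), [[1.5, 2.5]])


class TestMantleCoreDiscrimination:
    def test_peripheral_points_score_higher_than_central(self, rng):
        """Cells at 85-95% of the boundary radius must yield a strictly
        higher mean relative radius than cells at 20-40%."""
        v, c = validated(random_convex_polygon(rng))
        means = {}
        for name, lo, hi in (("mantle", 0.85, 0.95), ("core", 0.2, 0.4)):
            theta = rng.uniform(0, 2 * np.pi, 200)
            f = rng.uniform(lo, hi, 200)
            rb = np.asarray(boundary_radius_at_angle(v, c, theta))
            pts = np.column_stack(
                (c.cx + f * rb * np.cos(theta), c.cy + f * rb * np.sin(theta))
            )
            means[name] = relative_radii(pts, v, c).rel_radius.mean()
        assert means["mantle"] > means["core"]
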