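import math

import numpy as np
import pytest
import shapely
from shapely.geometry import MultiPoint

from ovimorph.errors import DegenerateGeometryError, EmptyMaskError, ValidationError
from ovimorph.geometry import (bounding_rect, convex_hull, max_inscribed_rect,
                               min_area_rect, point_line_distance,
                               u_chord_curvature)
from ovimorph.mask_io import BinaryMask, Contour

from conftest import brute_force_max_rect, solid_mask


def _circle_contour(r=50.0, n=360, center=(200.0, 200.0)):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)], 1)
    return Contour(pts)


class TestConvexHull:
    def test_square_plus_center_keeps_corners(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [5, 5]], float)
        hull = convex_hull(pts)
        assert set(map(tuple, hull)) == {(0, 0), (10, 0), (10, 10), (0, 10)}

    def test_points_on_circle_all_kept(self):
        pts = _circle_contour(n=24).points
        assert len(convex_hull(pts)) == 24

    def test_interior_points_dropped(self, rng):
        tri = np.array([[0, 0], [100, 0], [50, 90]], float)
        w = rng.dirichlet(np.ones(3), size=100)
        inner = w @ tri
        hull = convex_hull(np.vstack([tri, inner * 0.999 + tri.mean(0) * 0.001]))
        assert len(hull) == 3
        assert set(map(tuple, np.round(hull))) == set(map(tuple, tri))

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            convex_hull(np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float))

    def test_hull_subset_and_contains_input(self, rng):
        pts = rng.uniform(0, 50, (40, 2))
        hull = convex_hull(pts)
        in_set = {tuple(p) for p in pts}
        assert all(tuple(v) in in_set for v in hull)
        poly = MultiPoint(pts).convex_hull
        assert all(poly.buffer(1e-9).contains(shapely.Point(*p)) for p in pts)


class TestMinAreaRect:
    def test_axis_aligned_rect(self):
        pts = np.array([[x, y] for x in np.linspace(0, 30, 16) for y in (0.0, 10.0)])
        rr = min_area_rect(pts)
        assert rr.long_side == pytest.approx(30, abs=1e-9)
        assert rr.short_side == pytest.approx(10, abs=1e-9)
        assert rr.angle_deg == pytest.approx(0, abs=1e-9)

    @pytest.mark.parametrize("theta", [15.0, -30.0, 60.0])
    def test_rotated_rect_recovers_angle(self, theta):
        base = np.array([[x, y] for x in np.linspace(0, 30, 16) for y in (0.0, 10.0)])
        t = math.radians(theta)
        R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        rr = min_area_rect(base @ R.T)
        expect = (theta + 90) % 180 - 90
        assert rr.angle_deg == pytest.approx(expect, abs=0.5)
        assert rr.area == pytest.approx(300, rel=1e-6)

    def test_unit_square_tie_break_angle_zero(self):
        rr = min_area_rect(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert rr.area == pytest.approx(1, abs=1e-9)
        assert rr.angle_deg == pytest.approx(0, abs=1e-9)

    def test_matches_shapely_oracle_area(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 100, (rng.integers(5, 30), 2))
            rr = min_area_rect(pts)
            oracle = shapely.minimum_rotated_rectangle(MultiPoint(pts))
            assert rr.area == pytest.approx(oracle.area, rel=1e-6, abs=1e-6)

    def test_area_never_exceeds_bounding_rect(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 60, (15, 2))
            rr = min_area_rect(pts)
            br = bounding_rect(pts)
            # bounding_rect is pixel-quantised; compare against exact bounds
            w = pts[:, 0].max() - pts[:, 0].min()
            h = pts[:, 1].max() - pts[:, 1].min()
            assert rr.area <= w * h + 1e-6


class TestBoundingRect:
    def test_two_points(self):
        r = bounding_rect(np.array([[2, 3], [9, 7]]))
        assert (r.x0, r.y0, r.x1, r.y1) == (2, 3, 10, 8)

    def test_single_point(self):
        r = bounding_rect(np.array([[5, 5]]))
        assert (r.x0, r.y0, r.x1, r.y1) == (5, 5, 6, 6)

    def test_random_matches_minmax_scan(self, rng):
        pts = rng.integers(0, 40, (50, 2))
        r = bounding_rect(pts)
        assert (r.x0, r.y0) == (pts[:, 0].min(), pts[:, 1].min())
        assert (r.x1, r.y1) == (pts[:, 0].max() + 1, pts[:, 1].max() + 1)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            bounding_rect(np.empty((0, 2)))


class TestMaxInscribedRect:
    def test_solid_mask_full_rect(self):
        r = max_inscribed_rect(solid_mask(12, 10, 1, 1, 11, 9))
        assert (r.x0, r.y0, r.x1, r.y1) == (1, 1, 11, 9)

    def test_single_pixel(self):
        r = max_inscribed_rect(solid_mask(5, 5, 2, 3, 3, 4))
        assert (r.x0, r.y0, r.x1, r.y1) == (2, 3, 3, 4)

    def test_l_shape_matches_brute_force(self):
        g = np.zeros((12, 12), bool)
        g[0:4, 0:10] = True   # top strip 10 wide, 4 tall
        g[0:10, 0:4] = True   # left strip 4 wide, 10 tall
        r = max_inscribed_rect(BinaryMask(g))
        assert (r.y0, r.x0, r.y1, r.x1) == brute_force_max_rect(g)

    def test_empty_rejected(self):
        with pytest.raises(EmptyMaskError):
            max_inscribed_rect(BinaryMask(np.zeros((3, 3), bool)))


class TestUChordCurvature:
    def test_straight_segment_zero(self):
        pts = np.array([[x, 3.0] for x in range(0, 40, 2)] +
                       [[x, 5.0] for x in range(38, -2, -2)])
        c = Contour(pts)
        s = u_chord_curvature(c, 5, U=6.0)
        assert s.c == 0.0 and s.s == 0

    def test_circle_matches_closed_form_at_realizable_chord(self):
        # chord spanning 12 vertices of the 360-gon is exactly attainable
        r = 50.0
        U = 2 * r * math.sin(math.radians(6.0))
        contour = _circle_contour(r=r, n=360)
        expect = math.sqrt(1 - (r * math.sin(2 * math.asin(U / (2 * r))) / U) ** 2)
        for i in (0, 90, 123):
            s = u_chord_curvature(contour, i, U)
            assert abs(s.c) == pytest.approx(expect, abs=1e-9)
            assert s.D == pytest.approx(2 * r * math.sin(math.radians(12.0)), abs=1e-9)

    def test_circle_inexact_chord_sane(self):
        # U=10 sits between realizable chords; |c| is bracketed by the
        # closed forms at the neighbouring realizable chords
        contour = _circle_contour(r=50.0, n=360)
        s = u_chord_curvature(contour, 0, U=10.0)
        assert 0.05 < abs(s.c) < 0.5

    def test_mirror_negates_sign(self):
        contour = _circle_contour(r=30.0, n=180)
        mirrored = Contour(contour.points * np.array([-1.0, 1.0]) + np.array([400.0, 0.0]))
        a = u_chord_curvature(contour, 17, U=8.0)
        b = u_chord_curvature(mirrored, 17, U=8.0)
        assert b.c == pytest.approx(-a.c, abs=1e-9)
        assert abs(b.c) == pytest.approx(abs(a.c), abs=1e-9)

    def test_invariant_under_rotation_and_translation(self):
        base = _circle_contour(r=40.0, n=240)
        ref = abs(u_chord_curvature(base, 60, U=9.0).c)
        # translation + quarter-turns: exact
        for k in range(4):
            t = math.radians(90 * k)
            R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
            moved = Contour(base.points @ R.T + np.array([13.0, -7.0]))
            assert abs(u_chord_curvature(moved, 60, U=9.0).c) == pytest.approx(
                ref, abs=1e-6)
        # arbitrary rotation of a dense contour: within 0.02
        t = math.radians(33.0)
        R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        rotated = Contour(base.points @ R.T)
        assert abs(u_chord_curvature(rotated, 60, U=9.0).c) == pytest.approx(
            ref, abs=0.02)

    def test_short_contour_rejected(self):
        with pytest.raises(ValidationError):
            u_chord_curvature(Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]])),
                              0, U=2.0)


class TestPointLineDistance:
    def test_vertical_offset(self):
        assert point_line_distance((0, 5), (-1, 0), (1, 0)) == pytest.approx(5)

    def test_point_on_line(self):
        assert point_line_distance((3, 3), (0, 0), (6, 6)) == pytest.approx(0, abs=1e-12)

    def test_random_matches_cross_product_formula(self, rng):
        for _ in range(50):
            p, a, b = rng.uniform(-10, 10, (3, 2))
            if np.allclose(a, b):
                continue
            u, v = b - a, p - a
            expect = abs(u[0] * v[1] - u[1] * v[0]) / np.linalg.norm(u)
            assert point_line_distance(p, a, b) == pytest.approx(expect, abs=1e-12)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValidationError):
            point_line_distance((0, 0), (1, 1), (1, 1))
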