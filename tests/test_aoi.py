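"""Eye-AOI construction and point-in-polygon geometry."""

import numpy as np
import pytest

from contagionkit import EyeAOI, build_eye_aoi, point_in_polygon, points_in_polygon
from contagionkit.core import GeometryError


def winding_number_inside(point, vertices, eps=1e-9):
    """Independent oracle: signed-angle winding number.

    Points within eps of an edge count as inside, matching the
    package's boundary convention.
    """
    p = np.asarray(point, dtype=float)
    v = np.asarray(vertices, dtype=float)
    a = v - p
    b = np.roll(v, -1, axis=0) - p
    # boundary check first
    for s, e in zip(v, np.roll(v, -1, axis=0)):
        d = e - s
        L2 = d @ d
        t = np.clip(((p - s) @ d) / L2 if L2 > 0 else 0.0, 0.0, 1.0)
        if np.sum((p - (s + t * d)) ** 2) <= eps**2:
            return True
    ang = np.arctan2(
        a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0], (a * b).sum(axis=1)
    )
    return bool(abs(ang.sum()) > np.pi)


def random_star_polygon(rng, n_vertices=None):
    """Random simple (star-shaped) polygon around a random center."""
    n = n_vertices or rng.integers(3, 12)
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(0.5, 3.0, n)
    center = rng.uniform(-2, 2, 2)
    pts = center + np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return EyeAOI(pts)


UNIT_SQUARE = EyeAOI(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))


class TestPointInPolygon:
    @pytest.mark.parametrize(
        "point,expected",
        [
            ((0.5, 0.5), True),
            ((2.0, 2.0), False),
            ((0.0, 0.5), True),  # boundary counts as inside
            ((1.0, 1.0), True),  # vertex counts as inside
            ((-0.01, 0.5), False),
            ((np.nan, 0.5), False),  # NaN -> missing, never inside
        ],
    )
    def test_unit_square_cases(self, point, expected):
        assert point_in_polygon(point, UNIT_SQUARE) is expected

    def test_agrees_with_winding_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            poly = random_star_polygon(rng)
            pts = rng.uniform(-4, 6, (200, 2))
            got = points_in_polygon(pts, poly)
            want = np.array([winding_number_inside(p, poly.vertices) for p in pts])
            np.testing.assert_array_equal(got, want)


class TestBuildEyeAOI:
    def test_contains_eye_centers_and_midpoint(self, symmetric_landmarks):
        aoi = build_eye_aoi(symmetric_landmarks)
        lm = symmetric_landmarks
        mid = 0.5 * (lm.eye_left + lm.eye_right)
        for p in (lm.eye_left, lm.eye_right, mid):
            assert point_in_polygon(p, aoi)

    def test_zero_ratio_degenerates_to_landmark_chain(self, symmetric_landmarks):
        flat = build_eye_aoi(symmetric_landmarks, ellipse_height_ratio=0.0)
        # upper boundary is the straight segment between the outer
        # eyebrow endpoints: the quadrilateral cheek/brow polygon
        quad = EyeAOI(
            np.array(
                [
                    symmetric_landmarks.cheek_left,
                    symmetric_landmarks.cheek_right,
                    [150, 80],  # outer right eyebrow landmark
                    [50, 80],  # outer left eyebrow landmark
                ],
                dtype=float,
            )
        )
        assert flat.area() == pytest.approx(quad.area())

    def test_area_matches_shoelace_hand_computation(self, symmetric_landmarks):
        aoi = build_eye_aoi(symmetric_landmarks, ellipse_height_ratio=0.5)
        x, y = aoi.vertices[:, 0], aoi.vertices[:, 1]
        hand = 0.5 * abs(
            sum(
                x[i] * y[(i + 1) % len(x)] - x[(i + 1) % len(x)] * y[i]
                for i in range(len(x))
            )
        )
        assert aoi.area() == pytest.approx(hand, abs=1e-9)
        assert aoi.area() > 0

    def test_half_ellipse_spans_outer_eyebrow_landmarks(self, symmetric_landmarks):
        aoi = build_eye_aoi(symmetric_landmarks, ellipse_height_ratio=0.5)
        verts = aoi.vertices
        # outer eyebrow endpoints (50,80) and (150,80): major axis length
        # 100 px, semi-minor = 0.5 * 100 = 50 px, so the arc apex sits
        # ~50 px above the axis midpoint (100, 80)
        assert verts[:, 1].min() == pytest.approx(80 - 50, abs=1.0)
        assert any(np.allclose(v, [50, 80]) for v in verts)
        assert any(np.allclose(v, [150, 80]) for v in verts)

    def test_degenerate_landmarks_raise(self, symmetric_landmarks):
        lm = symmetric_landmarks
        lm.cheek_left = np.array([50.0, 80.0])
        lm.cheek_right = np.array([150.0, 80.0])
        with pytest.raises(GeometryError):
            build_eye_aoi(lm, ellipse_height_ratio=0.0)


class TestInvariants:
    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        poly = random_star_polygon(rng)
        pts = rng.uniform(-4, 6, (300, 2))
        base = points_in_polygon(pts, poly)
        shift = np.array([12.5, -3.25])
        moved = points_in_polygon(pts + shift, poly.translated(*shift))
        np.testing.assert_array_equal(base, moved)

    def test_nested_polygons_monotone(self):
        # shrink a star polygon about its kernel point: containment is
        # guaranteed, so classification must be monotone
        rng = np.random.default_rng(3)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 10))
        radii = rng.uniform(0.5, 3.0, 10)
        center = np.array([0.5, -0.25])
        ring = np.column_stack([np.cos(angles), np.sin(angles)])
        outer = EyeAOI(center + radii[:, None] * ring)
        inner = EyeAOI(center + 0.5 * radii[:, None] * ring)
        pts = rng.uniform(-4, 6, (500, 2))
        in_outer = points_in_polygon(pts, outer)
        in_inner = points_in_polygon(pts, inner)
        assert np.all(in_outer[in_inner])  # inner implies outer
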