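"""Landmark geometry: closed-form examples and symmetry properties."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundusage.errors import (
    DegenerateGeometryError,
    InvalidLandmarksError,
    UndefinedTemporalError,
)
from fundusage.geometry import (
    LandmarkSet,
    Point2D,
    RoiConfig,
    disc_geometry,
    pmp_angle,
    roi_layout,
    temporal_direction,
    vessel_angle,
)


def circle_points(n, r, cx=100.0, cy=100.0):
    t = 2 * np.pi * np.arange(n) / n
    return np.c_[cx + r * np.cos(t), cy + r * np.sin(t)]


def make_landmarks(**kwargs) -> LandmarkSet:
    defaults = dict(
        fovea=Point2D(300.0, 105.0),
        disc_boundary=tuple(Point2D(*p) for p in circle_points(16, 40.0)),
        crossing_st_artery=Point2D(120.0, 55.0),
        crossing_it_artery=Point2D(118.0, 148.0),
        crossing_st_vein=Point2D(130.0, 60.0),
        crossing_it_vein=Point2D(128.0, 142.0),
        laterality="right",
    )
    defaults.update(kwargs)
    return LandmarkSet(**defaults)


class TestDiscGeometry:
    def test_dense_circle_is_identity_case(self):
        d = disc_geometry(circle_points(36000, 50.0))
        assert d.center.x == pytest.approx(100.0, abs=1e-9)
        assert d.center.y == pytest.approx(100.0, abs=1e-9)
        assert d.radius == pytest.approx(50.0, abs=1e-9)
        assert d.ovality == pytest.approx(1.0, abs=1e-6)

    def test_coarse_circle_polygon_bias_is_small(self):
        # a 360-point sample is a regular polygon: its exact min Feret width is
        # (1+cos(pi/n))/2 of the diameter, so ovality deviates at the 2e-5 level
        d = disc_geometry(circle_points(360, 50.0))
        assert d.ovality == pytest.approx(1.0, abs=1e-4)
        assert d.ovality >= 1.0

    def test_two_to_one_ellipse(self):
        t = 2 * np.pi * np.arange(720) / 720
        pts = np.c_[100 + 60 * np.cos(t), 100 + 30 * np.sin(t)]
        assert disc_geometry(pts).ovality == pytest.approx(2.0, abs=0.01)

    def test_square_with_midpoints(self):
        s = 10.0
        pts = np.array(
            [[0, 0], [s, 0], [s, s], [0, s], [s / 2, 0], [s, s / 2], [s / 2, s], [0, s / 2]],
            dtype=float,
        )
        assert disc_geometry(pts).ovality == pytest.approx(np.sqrt(2.0), abs=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidLandmarksError):
            disc_geometry(circle_points(7, 40.0))

    def test_collinear_boundary_degenerate(self):
        pts = np.c_[np.linspace(0, 10, 9), np.linspace(0, 5, 9)]
        with pytest.raises(DegenerateGeometryError):
            disc_geometry(pts)

    def test_ovality_rotation_invariant(self, rng):
        t = 2 * np.pi * np.arange(64) / 64
        pts = np.c_[55 * np.cos(t), 33 * np.sin(t)]
        base = disc_geometry(pts).ovality
        for ang in rng.uniform(0, np.pi, size=5):
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            rotated = pts @ R.T + 200.0
            assert disc_geometry(rotated).ovality == pytest.approx(base, abs=0.01)


class TestTemporalDirection:
    @pytest.mark.parametrize(
        "fovea,expected",
        [((160.0, 100.0), (1.0, 0.0)), ((40.0, 110.0), (-1.0, 0.0))],
    )
    def test_sides(self, fovea, expected):
        assert tuple(temporal_direction(Point2D(100, 100), Point2D(*fovea))) == expected

    def test_vertical_alignment_undefined(self):
        with pytest.raises(UndefinedTemporalError):
            temporal_direction(Point2D(100, 100), Point2D(100, 90))


class TestVesselAngle:
    T = np.array([1.0, 0.0])

    @pytest.mark.parametrize(
        "crossing,expected",
        [((150, 50), 45.0), ((150, 150), 45.0), ((50, 100), 180.0)],
    )
    def test_reference_rays(self, crossing, expected):
        assert vessel_angle(Point2D(100, 100), Point2D(*crossing), self.T) == pytest.approx(
            expected, abs=1e-9
        )

    def test_crossing_at_center_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            vessel_angle(Point2D(100, 100), Point2D(100, 100), self.T)

    def test_symmetric_about_horizontal(self, rng):
        for _ in range(20):
            x = rng.uniform(101, 200)
            dy = rng.uniform(1, 80)
            up = vessel_angle(Point2D(100, 100), Point2D(x, 100 - dy), self.T)
            down = vessel_angle(Point2D(100, 100), Point2D(x, 100 + dy), self.T)
            assert up == pytest.approx(down, abs=1e-9)


class TestPmpAngle:
    def test_horizontal_is_zero(self):
        assert pmp_angle(Point2D(100, 100), Point2D(160, 100)) == 0.0

    def test_inferior_fovea_positive(self):
        expected = np.degrees(np.arctan2(10, 60))
        assert pmp_angle(Point2D(100, 100), Point2D(160, 110)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_left_eye_mirror_superior_negative(self):
        expected = -np.degrees(np.arctan2(10, 60))
        assert pmp_angle(Point2D(100, 100), Point2D(40, 90)) == pytest.approx(
            expected, abs=1e-9
        )


class TestRoiLayout:
    def make(self, temporal_sign=1.0):
        from fundusage.geometry import DiscGeometry

        disc = DiscGeometry(center=Point2D(100, 100), radius=20.0, ovality=1.0)
        t = np.array([temporal_sign, 0.0])
        return roi_layout(disc, t, Point2D(250, 100), RoiConfig(center_dist_mult=1.7))

    def test_temporal_and_superior_centers(self):
        layout = self.make()
        centers = layout.centers
        assert centers["temporal"] == pytest.approx((134.0, 100.0), abs=1e-9)
        assert centers["superior"] == pytest.approx((100.0, 66.0), abs=1e-9)

    def test_left_eye_layout(self):
        layout = self.make(temporal_sign=-1.0)
        centers = layout.centers
        assert centers["temporal"] == pytest.approx((66.0, 100.0), abs=1e-9)
        off = 34.0 / np.sqrt(2.0)
        assert centers["supratemporal"] == pytest.approx((100 - off, 100 - off), abs=1e-6)

    def test_centers_on_common_circle_45_degrees_apart(self):
        layout = self.make()
        pts = np.array(layout.peripapillary_centers) - np.array([100.0, 100.0])
        radii = np.hypot(*pts.T)
        assert np.allclose(radii, radii[0], atol=1e-9)
        angles = np.unwrap(np.arctan2(pts[:, 1], pts[:, 0]))
        steps = np.abs(np.diff(angles))
        assert np.allclose(steps, np.deg2rad(45.0), atol=1e-9)


class TestInvariances:
    @given(
        dx=st.floats(-500, 500),
        dy=st.floats(-500, 500),
        scale=st.floats(0.1, 10.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_angles_invariant_under_translation_and_scaling(self, dx, dy, scale):
        disc = Point2D(100.0, 100.0)
        crossing = Point2D(137.0, 61.0)
        fovea = Point2D(260.0, 112.0)
        t = temporal_direction(disc, fovea)
        base_v = vessel_angle(disc, crossing, t)
        base_p = pmp_angle(disc, fovea, t)
        move = lambda p: Point2D((p.x + dx) * scale, (p.y + dy) * scale)  # noqa: E731
        t2 = temporal_direction(move(disc), move(fovea))
        assert vessel_angle(move(disc), move(crossing), t2) == pytest.approx(base_v, abs=1e-9)
        assert pmp_angle(move(disc), move(fovea), t2) == pytest.approx(base_p, abs=1e-9)

    def test_mirroring_with_laterality_flip_preserves_parameters(self, rng):
        from fundusage.colorimetry import FEATURE_NAMES
        from fundusage.synthetic import render_fundus, sample_render_truth

        for _ in range(5):
            truth = sample_render_truth(rng)
            _, lm = render_fundus(truth)
            mirrored = lm.mirrored(width=560)
            assert mirrored.laterality != lm.laterality
            for orig, mirr in [(lm, mirrored)]:
                d1, d2 = disc_geometry(orig.disc_boundary), disc_geometry(mirr.disc_boundary)
                t1 = temporal_direction(d1.center, orig.fovea)
                t2 = temporal_direction(d2.center, mirr.fovea)
                assert d2.ovality == pytest.approx(d1.ovality, abs=1e-9)
                assert d2.radius == pytest.approx(d1.radius, abs=1e-9)
                for c1, c2 in zip(orig.crossings.values(), mirr.crossings.values()):
                    assert vessel_angle(d2.center, c2, t2) == pytest.approx(
                        vessel_angle(d1.center, c1, t1), abs=1e-9
                    )
                assert pmp_angle(d2.center, mirr.fovea, t2) == pytest.approx(
                    pmp_angle(d1.center, orig.fovea, t1), abs=1e-9
                )


class TestLandmarkValidation:
    def test_fovea_inside_disc_rejected(self):
        with pytest.raises(InvalidLandmarksError):
            make_landmarks(fovea=Point2D(101.0, 99.0))

    def test_crossing_at_disc_center_rejected(self):
        with pytest.raises(InvalidLandmarksError):
            make_landmarks(crossing_st_vein=Point2D(100.0, 100.0))

    def test_short_boundary_rejected(self):
        with pytest.raises(InvalidLandmarksError):
            make_landmarks(disc_boundary=tuple(Point2D(*p) for p in circle_points(5, 40.0)))
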