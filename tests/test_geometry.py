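"""3D mapping, centerline, polar grid, envelopes and phase refit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from aortasweep.cardiac import HeartFrequencyRange
from aortasweep.geometry import (
    GeometryError,
    PolarGrid,
    ProbePose,
    build_centerline,
    build_polar_grid,
    contour_to_world,
    envelope_radii,
    frame_origins,
    map_radius,
    polar_resample,
    refit_phase_contours,
)


def pose_from(rot: Rotation, trans, t=0.0) -> ProbePose:
    return ProbePose.from_rotation(rot, np.asarray(trans, dtype=float), t)


IDENTITY = pose_from(Rotation.identity(), [0, 0, 0])


class TestContourToWorld:
    def test_identity_pose_embeds_at_z0(self):
        pts = np.array([[1.0, 2.0], [-3.0, 0.5]])
        out = contour_to_world(pts, IDENTITY)
        assert np.allclose(out, np.column_stack([pts, [0, 0]]))

    def test_pure_translation_preserves_shape(self):
        pose = pose_from(Rotation.identity(), [0, 0, 50])
        pts = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        out = contour_to_world(pts, pose)
        assert np.allclose(out[:, 2], 50.0)
        assert np.allclose(out[:, :2], pts)

    def test_rotation_then_translation_matches_hand_computation(self):
        # 90 deg about x: (x, y, 0) -> (x, 0, y); then translate (1, 2, 3)
        pose = pose_from(Rotation.from_euler("x", 90, degrees=True), [1, 2, 3])
        pts = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, -1.0]])
        expected = np.array([[2.0, 2.0, 3.0], [1.0, 2.0, 4.0], [3.0, 2.0, 2.0]])
        assert np.allclose(contour_to_world(pts, pose), expected, atol=1e-9)

    def test_distances_preserved(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-10, 10, (20, 2))
        pose = pose_from(Rotation.random(rng=np.random.default_rng(4)), [5, -2, 7])
        out = contour_to_world(pts, pose)
        d_in = np.linalg.norm(pts[1:] - pts[:-1], axis=1)
        d_out = np.linalg.norm(out[1:] - out[:-1], axis=1)
        assert np.allclose(d_in, d_out, atol=1e-9)

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(GeometryError):
            ProbePose(np.zeros(3), np.array([1.0, 0.1, 0.0, 0.0]))


class TestCenterline:
    def test_collinear_centers_give_straight_segment(self):
        centers = np.column_stack([np.zeros(6), np.linspace(0, 50, 6), np.zeros(6)])
        cl = build_centerline(centers)
        assert np.abs(cl.points[:, [0, 2]]).max() < 1e-6
        assert np.all(np.diff(cl.arclength) > 0)

    def test_helix_recovered_within_half_mm(self):
        t = np.linspace(0, 4 * np.pi, 40)
        centers = np.column_stack([5 * np.cos(t), 10 * t / np.pi, 5 * np.sin(t)])
        cl = build_centerline(centers)
        # analytic helix distance: radius in the x-z plane should stay ~5
        r = np.hypot(cl.points[:, 0], cl.points[:, 2])
        assert np.abs(r - 5.0).max() < 0.5

    def test_three_centers_rejected(self):
        with pytest.raises(GeometryError):
            build_centerline(np.zeros((3, 3)))


class TestFrameOrigins:
    @staticmethod
    def straight_centerline():
        pts = np.column_stack([np.zeros(101), np.linspace(0, 100, 101), np.zeros(101)])
        return build_centerline(pts[::10])

    @staticmethod
    def plane_pose(y, tilt_deg=0.0):
        # plane normal along +y (vessel axis), optionally tilted about x
        rot = Rotation.from_euler("x", -90 + tilt_deg, degrees=True)
        return pose_from(rot, [0, y, 0])

    def test_orthogonal_planes_hit_sampled_centerline_points(self):
        cl = self.straight_centerline()
        poses = [self.plane_pose(y) for y in (10.0, 20.0, 30.0)]
        w, p, flags = frame_origins(cl, poses)
        assert np.allclose(w[:, 1], [10, 20, 30], atol=1e-9)
        assert np.allclose(w[:, [0, 2]], 0.0, atol=1e-9)
        assert not flags.any()

    def test_tilted_plane_matches_closed_form(self):
        cl = self.straight_centerline()
        pose = self.plane_pose(40.0, tilt_deg=30.0)
        w, p, flags = frame_origins(cl, [pose])
        n = pose.normal
        t_star = np.dot(pose.translation, n) / n[1]
        assert np.allclose(w[0], [0, t_star, 0], atol=1e-9)

    def test_no_crossing_falls_back_to_projection_with_flag(self):
        cl = self.straight_centerline()
        pose = self.plane_pose(150.0)  # beyond the centerline extent
        w, p, flags = frame_origins(cl, [pose])
        assert flags[0]
        # nearest centerline point (0, 100, 0) projected into the plane y=150
        assert np.allclose(w[0], [0, 150, 0], atol=1e-6)
        assert abs(np.dot(w[0] - pose.translation, pose.normal)) < 1e-9

    def test_double_crossing_prefers_continuity(self):
        # S-shaped centerline crosses the y=0 plane of a tilted frame twice;
        # the crossing nearest the previous origin must win
        y = np.linspace(0, 60, 121)
        x = 10 * np.sin(2 * np.pi * y / 60.0)
        cl = build_centerline(np.column_stack([x, y, np.zeros_like(y)])[::6])
        rot = Rotation.from_euler("z", 90, degrees=True)  # plane normal = -x
        poses = [self.plane_pose(28.0), pose_from(rot, [0.0, 30.0, 0.0])]
        w, p, flags = frame_origins(cl, poses)
        assert abs(w[1, 1] - 30.0) < 3.0  # near previous origin, not the far crossing


class TestPolarResample:
    def test_centered_circle_all_radii_equal(self):
        th = np.linspace(0, 2 * np.pi, 240, endpoint=False)
        circ = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
        r = polar_resample(circ, [0.0, 0.0], 72)
        assert np.abs(r - 10.0).max() < 2e-3

    def test_offset_origin_matches_limacon_closed_form(self):
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        circ = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
        r = polar_resample(circ, [-3.0, 0.0], 72)
        ang = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        expected = 3 * np.cos(ang) + np.sqrt(100 - 9 * np.sin(ang) ** 2)
        assert np.abs(r - expected).max() < 2e-3

    def test_origin_outside_raises(self):
        th = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        circ = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
        with pytest.raises(GeometryError):
            polar_resample(circ, [12.0, 0.0], 36)


def synthetic_grid(radius_fn, duration=10.0, fs=25.0, n_angles=24):
    """PolarGrid for a vessel centred on identity-pose frames."""
    t = np.arange(0, duration, 1 / fs)
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    radii = np.empty((n_angles, len(t)))
    for j, tj in enumerate(t):
        radii[:, j] = radius_fn(tj, angles)
    poses = [pose_from(Rotation.identity(), [0, 0, 2.0 * tj], tj) for tj in t]
    return PolarGrid(
        radii, angles, t, np.array([p.translation for p in poses]),
        np.zeros((len(t), 2)), poses,
    )


class TestEnvelopes:
    def test_sinusoid_envelopes_within_two_hundredths_mm(self):
        grid = synthetic_grid(lambda tj, a: np.full_like(a, 10 + np.sin(2 * np.pi * tj)))
        env = envelope_radii(grid, HeartFrequencyRange(1.0))
        interior = (grid.times > 1.0) & (grid.times < grid.times[-1] - 1.0)
        assert np.abs(env.r_es[:, interior] - 11.0).max() < 0.02
        assert np.abs(env.r_ed[:, interior] - 9.0).max() < 0.02

    def test_constant_signal_flagged_degenerate(self):
        grid = synthetic_grid(lambda tj, a: np.full_like(a, 10.0))
        env = envelope_radii(grid, HeartFrequencyRange(1.0))
        assert env.degenerate_angles.all()
        assert np.allclose(env.r_es, 10.0) and np.allclose(env.r_ed, 10.0)

    def test_envelopes_track_slow_radius_trend(self):
        # radius drifts 10 -> 15 mm with 5% pulsation: the ES/ED ratio stays 1.05
        def fn(tj, a):
            base = 10.0 + 5.0 * tj / 10.0
            return np.full_like(a, base * (1 + 0.05 * (0.5 - 0.5 * np.cos(2 * np.pi * tj))))

        grid = synthetic_grid(fn)
        env = envelope_radii(grid, HeartFrequencyRange(1.0))
        interior = (grid.times > 1.0) & (grid.times < grid.times[-1] - 1.0)
        ratio = env.r_es[0, interior] / env.r_ed[0, interior]
        assert np.abs(ratio - 1.05).max() < 0.0105

    def test_envelope_ordering_holds_everywhere(self):
        grid = synthetic_grid(
            lambda tj, a: 10 + np.sin(2 * np.pi * tj) * (1 + 0.2 * np.cos(a))
        )
        env = envelope_radii(grid, HeartFrequencyRange(1.0))
        assert np.all(env.r_ed <= env.r_es + 1e-12)
        assert np.all(env.r_ed <= grid.radii + 0.02)
        assert np.all(grid.radii <= env.r_es + 0.02)


class TestMapRadius:
    @pytest.mark.parametrize("r_ed,r_es,expected", [(10, 12, 11), (8, 8, 8), (5, 9, 7)])
    def test_midpoint_arithmetic(self, r_ed, r_es, expected):
        assert map_radius(r_ed, r_es) == pytest.approx(expected)

    def test_inverted_envelope_rejected(self):
        with pytest.raises(GeometryError):
            map_radius(10.0, 9.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(r_ed=st.floats(0.5, 30.0), extra=st.floats(0.0, 10.0))
    def test_midpoint_lies_between_envelopes(self, r_ed, extra):
        r = map_radius(r_ed, r_ed + extra)
        assert r_ed <= r <= r_ed + extra
        assert r == pytest.approx((2 * r_ed + extra) / 2)


class TestRefitPhases:
    def test_pulsating_elliptical_vessel_recovered(self):
        # per-frame true contour is an ellipse whose axes breathe by 10%
        def fn(tj, a):
            w = 0.5 - 0.5 * np.cos(2 * np.pi * tj)
            scale = 1 + 0.1 * w
            aa, bb = 12.0 * scale, 8.0 * scale
            return aa * bb / np.sqrt((bb * np.cos(a)) ** 2 + (aa * np.sin(a)) ** 2)

        grid = synthetic_grid(fn, n_angles=48)
        env = envelope_radii(grid, HeartFrequencyRange(1.0))
        phases = refit_phase_contours(grid, env)
        ed, es = phases["ED"], phases["ES"]
        j = len(grid.times) // 2  # mid-sweep frame, far from boundary cycles
        assert ed.ellipses[j].a == pytest.approx(12.0, abs=0.05)
        assert ed.ellipses[j].b == pytest.approx(8.0, abs=0.05)
        assert es.ellipses[j].a == pytest.approx(13.2, abs=0.05)

    def test_zero_pulsation_phases_coincide(self):
        grid = synthetic_grid(lambda tj, a: np.full_like(a, 10.0))
        phases = refit_phase_contours(grid, envelope_radii(grid, HeartFrequencyRange(1.0)))
        assert np.allclose(
            phases["ED"].contours_world, phases["ES"].contours_world, atol=1e-6
        )
        assert np.allclose(
            phases["MAP"].contours_world, phases["ES"].contours_world, atol=1e-6
        )

    def test_contours_stay_planar_in_their_frames(self):
        grid = synthetic_grid(lambda tj, a: np.full_like(a, 10 + np.sin(2 * np.pi * tj)))
        phases = refit_phase_contours(grid, envelope_radii(grid, HeartFrequencyRange(1.0)))
        for geom in phases.values():
            # identity-rotation poses: plane = {z = pose z}
            z = geom.contours_world[:, :, 2]
            assert np.abs(z - z.mean(axis=1, keepdims=True)).max() < 1e-9

    def test_map_is_midpoint_before_refit(self):
        grid = synthetic_grid(lambda tj, a: np.full_like(a, 10 + np.sin(2 * np.pi * tj)))
        env = envelope_radii(grid, HeartFrequencyRange(1.0))
        r_map = map_radius(env.r_ed, env.r_es)
        assert np.abs(r_map - 0.5 * (env.r_ed + env.r_es)).max() < 1e-9
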