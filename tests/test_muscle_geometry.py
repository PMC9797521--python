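import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hipload.anatomy import MuscleElement, WrappingCylinder
from hipload.kinematics import SegmentPose
from hipload.muscle_geometry import (
    GeometryError,
    cylinder_wrap,
    path_length,
    world_path,
)

Z = np.array([0.0, 0.0, 1.0])


def _identity_poses(*names):
    return {n: SegmentPose(np.eye(3), np.zeros(3)) for n in names}


def _el(path, **kw):
    kw.setdefault("pcsa", 10.0)
    return MuscleElement(id="e", muscle="e", path=path, **kw)


class TestCylinderWrap:
    def test_clear_segment_is_straight(self):
        p1, p2 = np.array([1.0, 1.0, 0.0]), np.array([2.0, 2.0, 1.0])
        pts, L, s = cylinder_wrap(p1, p2, np.zeros(3), Z, 0.5)
        assert s == 0 and len(pts) == 2
        assert L == pytest.approx(np.linalg.norm(p2 - p1), abs=0)

    def test_in_plane_closed_form(self):
        """Both points at 2*rho from the axis, chord through the axis:
        length = 2*sqrt(3)*rho + (pi/3)*rho."""
        rho = 0.13
        p1 = np.array([2 * rho, 0.0, 0.0])
        p2 = np.array([-2 * rho, 0.0, 0.0])
        _, L, s = cylinder_wrap(p1, p2, np.zeros(3), Z, rho)
        assert s != 0
        assert L == pytest.approx(2 * np.sqrt(3) * rho + np.pi / 3 * rho, abs=1e-9)

    def test_half_circumference_for_surface_points(self):
        rho = 0.2
        p1 = np.array([rho, 0.0, 0.0])
        p2 = np.array([-rho, 0.0, 0.0])
        _, L, _ = cylinder_wrap(p1, p2, np.zeros(3), Z, rho)
        assert L == pytest.approx(np.pi * rho, abs=1e-9)

    def test_helical_length_from_plane_development(self):
        rho = 0.13
        p1 = np.array([2 * rho, 0.0, 0.0])
        p2 = np.array([-2 * rho, 0.0, 0.4])
        _, L, _ = cylinder_wrap(p1, p2, np.zeros(3), Z, rho)
        planar = 2 * np.sqrt(3) * rho + np.pi / 3 * rho
        assert L == pytest.approx(np.hypot(planar, 0.4), abs=1e-9)

    def test_length_continuous_across_tangency(self):
        rho = 0.1
        p1 = np.array([0.5, 0.0, 0.0])
        prev = None
        for y in np.linspace(0.099, 0.101, 41):
            p2 = np.array([-0.5, y, 0.0])
            _, L, _ = cylinder_wrap(p1, p2, np.zeros(3), Z, rho)
            if prev is not None:
                assert abs(L - prev) < 1e-4
            prev = L
        # exactly at the boundary the two branches agree closely
        _, L_in, s_in = cylinder_wrap(p1, np.array([-0.5, 0.0999999, 0.0]), np.zeros(3), Z, rho)
        _, L_out, s_out = cylinder_wrap(p1, np.array([-0.5, 0.1000001, 0.0]), np.zeros(3), Z, rho)
        assert abs(L_in - L_out) < 1e-6

    def test_endpoint_inside_rejected(self):
        with pytest.raises(GeometryError):
            cylinder_wrap(np.array([0.01, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]),
                          np.zeros(3), Z, 0.1)

    def test_shorter_direction_chosen_and_hysteresis_on_ties(self):
        rho = 0.1
        p1 = np.array([0.5, 0.02, 0.0])
        p2 = np.array([-0.5, 0.02, 0.0])
        _, L_free, s_free = cylinder_wrap(p1, p2, np.zeros(3), Z, rho)
        assert s_free in (-1, +1)
        # symmetric chord through the axis: a tie; preference honoured
        p1s, p2s = np.array([0.5, 0.0, 0.0]), np.array([-0.5, 0.0, 0.0])
        _, _, s_pref = cylinder_wrap(p1s, p2s, np.zeros(3), Z, rho, prefer_direction=-1)
        assert s_pref == -1
        _, _, s_default = cylinder_wrap(p1s, p2s, np.zeros(3), Z, rho)
        assert s_default == +1


class TestWorldPath:
    def test_two_point_element_identity(self):
        el = _el([("thigh", [0.0, 0.0, 0.0]), ("shank", [0.3, 0.0, -0.4])])
        poses = _identity_poses("thigh", "shank")
        f = world_path(el, poses)
        assert f.length == pytest.approx(0.5)
        np.testing.assert_allclose(f.points[0], [0, 0, 0])
        np.testing.assert_allclose(f.points[-1], [0.3, 0, -0.4])
        # lines of action are unit and opposite
        d0 = f.records[0].direction
        d1 = f.records[1].direction
        np.testing.assert_allclose(np.linalg.norm(d0), 1.0, rtol=1e-12)
        np.testing.assert_allclose(d0, -d1, rtol=1e-12)

    def test_collinear_via_point_leaves_length_unchanged(self):
        el1 = _el([("thigh", [0.0, 0.0, 0.0]), ("shank", [0.0, 0.0, -0.5])])
        el2 = _el([("thigh", [0.0, 0.0, 0.0]), ("thigh", [0.0, 0.0, -0.2]),
                   ("shank", [0.0, 0.0, -0.5])])
        poses = _identity_poses("thigh", "shank")
        assert path_length(el2, poses) == pytest.approx(path_length(el1, poses), abs=1e-15)

    def test_rotation_equivariance(self):
        el = _el([("thigh", [0.02, 0.01, 0.0]), ("shank", [0.3, -0.05, -0.4])])
        Q = Rotation.from_rotvec([0.4, -0.3, 0.7]).as_matrix()
        d = np.array([0.5, 0.2, -0.1])
        poses = _identity_poses("thigh", "shank")
        moved = {s: SegmentPose(Q @ p.rotation, Q @ p.translation + d) for s, p in poses.items()}
        f0 = world_path(el, poses)
        f1 = world_path(el, moved)
        assert f1.length == pytest.approx(f0.length, rel=1e-12)
        for r0, r1 in zip(f0.records, f1.records):
            np.testing.assert_allclose(r1.direction, Q @ r0.direction, atol=1e-12)
            np.testing.assert_allclose(r1.point, Q @ r0.point + d, atol=1e-12)

    def test_wrap_force_records_sum_to_zero(self, toy, toy_bundle):
        """A wrapped element's records form a zero net wrench (massless cable)."""
        _, _, gt = toy_bundle
        poses = gt.poses.frame_poses(2)
        el = toy.element("gastroc")
        f = world_path(el, poses, toy.cylinders)
        assert f.wrap_engaged
        total_f = np.sum([r.direction for r in f.records], axis=0)
        total_m = np.sum([np.cross(r.point, r.direction) for r in f.records], axis=0)
        np.testing.assert_allclose(total_f, 0, atol=1e-12)
        np.testing.assert_allclose(total_m, 0, atol=1e-12)

    def test_wrapped_length_not_below_straight(self, toy, toy_bundle):
        _, _, gt = toy_bundle
        el = toy.element("gastroc")
        for i in range(gt.poses.n_frames):
            poses = gt.poses.frame_poses(i)
            f = world_path(el, poses, toy.cylinders)
            straight = np.linalg.norm(f.points[-1] - f.points[0])
            assert f.length >= straight - 1e-12


def _knee_axis_torque(anatomy, poses, element_id, forces=1.0):
    """Moment about the knee y-axis from the element's shank+foot records."""
    from hipload.muscle_geometry import world_path as wp

    el = anatomy.element(element_id)
    f = wp(el, poses, anatomy.cylinders)
    knee = poses["shank"].apply(anatomy.segments["shank"].proximal_jrc)
    axis = poses["shank"].rotation @ np.array([0.0, 1.0, 0.0])
    tau = 0.0
    for rec in f.records:
        if rec.segment in ("shank", "foot"):
            tau += np.cross(rec.point - knee, forces * rec.direction) @ axis
    return tau, f.length


class TestTendonExcursion:
    @pytest.mark.parametrize("element_id", ["knee_1", "knee_3", "gastroc"])
    def test_moment_arm_equals_minus_dl_dtheta(self, toy, toy_bundle, element_id):
        _, _, gt = toy_bundle
        base = gt.poses.frame_poses(2)

        def posed(theta):
            poses = dict(base)
            knee = base["shank"].apply(toy.segments["shank"].proximal_jrc)
            axis = base["shank"].rotation @ np.array([0.0, 1.0, 0.0])
            Q = Rotation.from_rotvec(axis * theta).as_matrix()
            for s in ("shank", "foot"):
                R = Q @ base[s].rotation
                t = knee + Q @ (base[s].translation - knee)
                poses[s] = SegmentPose(R, t)
            return poses

        h = 1e-6
        tau, _ = _knee_axis_torque(toy, posed(0.0), element_id)
        _, Lp = _knee_axis_torque(toy, posed(h), element_id)
        _, Lm = _knee_axis_torque(toy, posed(-h), element_id)
        dl_dtheta = (Lp - Lm) / (2 * h)
        assert tau == pytest.approx(-dl_dtheta, rel=1e-3, abs=1e-9)
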