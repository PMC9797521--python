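import numpy as np
import pytest

from hipload.anatomy import Subject
from hipload.dynamics import (
    DEFAULT_REGRESSION_TABLE,
    DynamicsError,
    GRAVITY,
    InertialParams,
    SegmentInertia,
    estimate_inertial_params,
    inertial_wrench,
    limb_closure_residual,
    net_joint_loads,
    skew,
)
from hipload.kinematics import ForcePlateSeries, PoseSeries, SegmentPose


class TestInertialParams:
    def test_mass_is_fraction_of_body_mass(self):
        subj = Subject(height=1.80, mass=70.0)
        p = estimate_inertial_params(subj, {"thigh": 0.4})
        assert p.segments["thigh"].mass == pytest.approx(0.1416 * 70.0)

    def test_principal_moment_definition(self):
        subj = Subject(height=1.80, mass=70.0)
        L = 0.4
        p = estimate_inertial_params(subj, {"thigh": L})
        e = DEFAULT_REGRESSION_TABLE["thigh"]
        M = e.mass_fraction * 70.0
        I = p.segments["thigh"].inertia_local
        expected = sorted([M * (r * L) ** 2 for r in e.rog_fractions])
        np.testing.assert_allclose(sorted(np.linalg.eigvalsh(I)), expected, rtol=1e-12)

    def test_full_table_matches_independent_row_by_row_evaluation(self):
        subj = Subject(height=1.80, mass=70.0)
        lengths = {"pelvis": 0.18, "thigh": 0.40, "shank": 0.40, "foot": 0.22, "patella": 0.04}
        p = estimate_inertial_params(subj, lengths)
        for seg, L in lengths.items():
            e = DEFAULT_REGRESSION_TABLE[seg]
            si = p.segments[seg]
            assert si.mass == pytest.approx(e.mass_fraction * 70.0, rel=1e-12)
            assert np.linalg.norm(si.com_from_proximal) == pytest.approx(
                e.com_fraction * L, rel=1e-12)
            np.testing.assert_allclose(
                sorted(np.linalg.eigvalsh(si.inertia_local)),
                sorted(si.mass * (np.array(e.rog_fractions) * L) ** 2), rtol=1e-12)

    def test_missing_table_entry_names_segment(self):
        with pytest.raises(DynamicsError, match="nonexistent"):
            estimate_inertial_params(Subject(1.8, 70.0), {"nonexistent": 0.3})


class TestInertialWrench:
    def _static_inertia(self):
        return SegmentInertia(7.0, np.array([0.0, 0.0, -0.17]), np.diag([0.1, 0.1, 0.02]))

    def test_static_gravity_only(self):
        si = self._static_inertia()
        pose = SegmentPose(np.eye(3), np.zeros(3))
        f, m = inertial_wrench(si, pose, np.zeros(3), np.zeros(3), np.zeros(3))
        np.testing.assert_allclose(f, [0, 0, 7.0 * 9.81], rtol=1e-12)
        np.testing.assert_allclose(m, 7.0 * skew(si.com_from_proximal) @ (-GRAVITY), rtol=1e-12)

    def test_free_fall_zero_wrench(self):
        si = self._static_inertia()
        pose = SegmentPose(np.eye(3), np.zeros(3))
        f, m = inertial_wrench(si, pose, GRAVITY, np.zeros(3), np.zeros(3))
        np.testing.assert_allclose(f, 0, atol=1e-12)
        np.testing.assert_allclose(m, 0, atol=1e-12)

    def test_spin_about_principal_axis_no_gyroscopic_term(self):
        si = SegmentInertia(2.0, np.zeros(3), np.diag([0.1, 0.2, 0.3]))
        pose = SegmentPose(np.eye(3), np.zeros(3))
        omega = np.array([0.0, 0.0, 4.0])
        alpha = np.array([0.0, 0.0, 2.5])
        f, m = inertial_wrench(si, pose, GRAVITY, omega, alpha)
        np.testing.assert_allclose(m, [0, 0, 0.3 * 2.5], atol=1e-12)


def _static_single_support(toy, mass_scale=1e-9):
    """Nearly massless limb standing on a constant GRF."""
    n = 5
    t = np.arange(n) / 100.0
    segs = ["foot", "shank", "thigh"]
    rot = {s: np.tile(np.eye(3), (n, 1, 1)) for s in segs}
    heights = {"foot": 0.1, "shank": 0.5, "thigh": 0.9}
    tra = {s: np.tile([0.0, 0.0, heights[s]], (n, 1)) for s in segs}
    poses = PoseSeries(t, 100.0, rot, tra, np.zeros(n))
    for s in segs:
        poses.omega[s] = np.zeros((n, 3))
        poses.alpha[s] = np.zeros((n, 3))
        poses.a_com[s] = np.zeros((n, 3))
    params = InertialParams({
        s: SegmentInertia(mass_scale, np.zeros(3), np.eye(3) * mass_scale) for s in segs})
    grf = ForcePlateSeries(
        np.tile([10.0, 0.0, 700.0], (n, 1)),
        np.tile([0.05, 0.02, 0.0], (n, 1)),
        np.zeros((n, 3)))
    return poses, params, grf


class TestNetJointLoads:
    def test_static_massless_hand_statics(self, toy):
        poses, params, grf = _static_single_support(toy)
        loads = net_joint_loads(poses, grf, params, toy)
        hip_p = np.array([0.0, 0.0, 0.9])  # thigh proximal JRC in lab
        np.testing.assert_allclose(loads["hip"]["force"][0], -grf.force[0], atol=1e-6)
        expected_m = -np.cross(grf.cop[0] - hip_p, grf.force[0])
        np.testing.assert_allclose(loads["hip"]["moment"][0], expected_m, atol=1e-6)

    def test_zero_mass_zero_grf_zero_loads(self, toy):
        poses, params, grf = _static_single_support(toy)
        grf0 = ForcePlateSeries(np.zeros_like(grf.force), grf.cop, np.zeros_like(grf.force))
        loads = net_joint_loads(poses, grf0, params, toy)
        for j in loads:
            np.testing.assert_allclose(loads[j]["force"], 0, atol=1e-6)
            np.testing.assert_allclose(loads[j]["moment"], 0, atol=1e-6)

    def test_linear_in_grf(self, toy, toy_bundle, toy_params):
        _, grf, gt = toy_bundle
        l1 = net_joint_loads(gt.poses, grf, toy_params, toy)
        grf2 = ForcePlateSeries(2.0 * grf.force, grf.cop, 2.0 * grf.free_moment)
        l2 = net_joint_loads(gt.poses, grf2, toy_params, toy)
        g0 = ForcePlateSeries(0.0 * grf.force, grf.cop, 0.0 * grf.free_moment)
        l0 = net_joint_loads(gt.poses, g0, toy_params, toy)
        for j in l1:
            np.testing.assert_allclose(
                l2[j]["force"] - l0[j]["force"], 2.0 * (l1[j]["force"] - l0[j]["force"]),
                rtol=1e-9, atol=1e-9)

    def test_frame_count_mismatch_rejected(self, toy, toy_bundle, toy_params):
        _, grf, gt = toy_bundle
        short = ForcePlateSeries(grf.force[:-1], grf.cop[:-1], grf.free_moment[:-1])
        with pytest.raises(DynamicsError):
            net_joint_loads(gt.poses, short, toy_params, toy)


class TestClosure:
    def test_whole_limb_closure_on_synthetic_frames(self, toy, toy_bundle, toy_params):
        _, grf, gt = toy_bundle
        res = limb_closure_residual(gt.poses, grf, toy_params, toy)
        assert np.max(res) < 1e-8

    def test_recursion_matches_optimizer_constraint_sums(self, toy, toy_bundle, toy_params):
        """Hip net load equals hip contact + pelvis-crossing muscle resultant
        (plus the patella's inertial wrench, which the three-segment
        recursion does not traverse)."""
        from hipload.dynamics import inertial_wrench as iw
        from hipload.muscle_geometry import compute_geometry

        _, grf, gt = toy_bundle
        loads = net_joint_loads(gt.poses, grf, toy_params, toy)
        i = gt.poses.n_frames // 2
        p = gt.problems[i]
        sol = gt.solutions[i]
        poses_i = gt.poses.frame_poses(i)
        geom = compute_geometry(toy, poses_i)
        hip_lab = poses_i["thigh"].apply(toy.segments["thigh"].proximal_jrc)
        f = sol.contacts["hip"].copy()
        m = np.zeros(3)
        for j, eid in enumerate(p.element_ids):
            for rec in geom[eid].records:
                if rec.segment == "pelvis":
                    f -= sol.forces[j] * rec.direction
                    m -= sol.forces[j] * np.cross(rec.point - hip_lab, rec.direction)
        fp, mp = iw(toy_params.segments["patella"], poses_i["patella"],
                    gt.poses.a_com["patella"][i], gt.poses.omega["patella"][i],
                    gt.poses.alpha["patella"][i])
        prox_pat = poses_i["patella"].apply(toy.segments["patella"].proximal_jrc)
        np.testing.assert_allclose(f, loads["hip"]["force"][i] + fp, atol=1e-6)
        np.testing.assert_allclose(
            m, loads["hip"]["moment"][i] + mp + np.cross(prox_pat - hip_lab, fp), atol=1e-6)
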