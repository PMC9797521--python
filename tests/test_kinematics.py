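import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from hipload.kinematics import (
    KinematicsError,
    MarkerTrial,
    PoseSeries,
    SegmentPose,
    calibrate,
    differentiate,
    fit_rigid,
    inverse_kinematics,
    lowpass_filter,
    solve_frame,
)
from hipload.dynamics import params_from_anatomy


def _sine_trial(freq, rate, n=400, amp=1.0):
    t = np.arange(n) / rate
    sig = amp * np.sin(2 * np.pi * freq * t)
    return MarkerTrial(rate, t, {"m": np.column_stack([sig, sig, sig])})


class TestLowpass:
    def test_constant_series_unchanged(self):
        t = np.arange(100) / 100.0
        trial = MarkerTrial(100.0, t, {"m": np.full((100, 3), 3.7)})
        out = lowpass_filter(trial)
        np.testing.assert_allclose(out.markers["m"], 3.7, rtol=1e-12)

    def test_passband_sine_amplitude_preserved(self):
        out = lowpass_filter(_sine_trial(1.0, 100.0))
        mid = out.markers["m"][100:-100, 0]
        ref = _sine_trial(1.0, 100.0).markers["m"][100:-100, 0]
        assert np.max(np.abs(mid - ref)) < 0.01  # |H|^2 at 1 Hz within 1%

    def test_stopband_sine_attenuated(self):
        out = lowpass_filter(_sine_trial(50.0, 200.0))
        assert np.max(np.abs(out.markers["m"][150:-150, 0])) < 1e-4

    def test_corner_at_nyquist_rejected(self):
        with pytest.raises(KinematicsError):
            lowpass_filter(_sine_trial(1.0, 100.0), fc=50.0)


def _static_from_poses(anatomy, poses, n=12, rate=100.0, noise=None, rng=None):
    t = np.arange(n) / rate
    markers = {}
    for name, seg in anatomy.segments.items():
        for lbl in seg.marker_labels:
            p = poses[name].apply(seg.landmarks[lbl])
            pos = np.tile(p, (n, 1))
            if noise:
                pos = pos + rng.normal(scale=noise, size=pos.shape)
            markers[lbl] = pos
    return MarkerTrial(rate, t, markers)


def _identity_poses(anatomy):
    return {s: SegmentPose(np.eye(3), np.zeros(3)) for s in anatomy.segments}


class TestCalibrate:
    def test_markers_at_landmarks_recovers_local_offsets(self, toy):
        static = _static_from_poses(toy, _identity_poses(toy))
        calib = calibrate(static, toy)
        assert calib.residual_rmse < 1e-12
        for lbl, seg in calib.marker_segment.items():
            np.testing.assert_allclose(
                calib.marker_local[lbl], toy.segments[seg].landmarks[lbl], atol=1e-12)

    def test_rigid_displacement_invariance(self, toy):
        R = Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
        tr = np.array([1.0, -2.0, 0.4])
        poses = {s: SegmentPose(R, tr) for s in toy.segments}
        calib = calibrate(_static_from_poses(toy, poses), toy)
        assert calib.residual_rmse < 1e-12
        for lbl, seg in calib.marker_segment.items():
            np.testing.assert_allclose(
                calib.marker_local[lbl], toy.segments[seg].landmarks[lbl], atol=1e-10)

    def test_perturbed_marker_residual_matches_rigid_fit_oracle(self, toy):
        static = _static_from_poses(toy, _identity_poses(toy))
        lbl = "thigh_1"
        static.markers[lbl] = static.markers[lbl] + np.array([0.0, 0.0, 0.005])
        calib = calibrate(static, toy)
        seg = toy.segments["thigh"]
        local = np.array([seg.landmarks[l] for l in seg.marker_labels])
        lab = np.array([static.markers[l][0] for l in seg.marker_labels])
        pose = fit_rigid(local, lab)
        resid = np.linalg.norm(local @ pose.rotation.T + pose.translation - lab, axis=1)
        # calibration residual over all segments equals the thigh fit share
        n_total = sum(len(s.marker_labels) for s in toy.segments.values())
        assert calib.residual_rmse == pytest.approx(
            np.sqrt(np.sum(resid ** 2) / n_total), rel=1e-9)

    def test_inter_hip_distance_measured(self, toy):
        calib = calibrate(_static_from_poses(toy, _identity_poses(toy)), toy)
        assert calib.inter_hip_distance == pytest.approx(0.18, rel=1e-12)


def _synth_frame(anatomy, poses):
    return {
        lbl: poses[name].apply(seg.landmarks[lbl])
        for name, seg in anatomy.segments.items()
        for lbl in seg.marker_labels
    }


@pytest.fixture()
def toy_calib(toy):
    return calibrate(_static_from_poses(toy, _identity_poses(toy)), toy)


class TestSolveFrame:
    def test_exact_recovery_and_hip_constraint(self, toy, toy_calib):
        true = {}
        rots = {"pelvis": [0.05, 0.02, -0.04], "thigh": [0.3, 0.1, 0.0],
                "patella": [0.25, 0.05, 0.0], "shank": [-0.2, 0.0, 0.1],
                "foot": [-0.1, 0.05, 0.02]}
        hip_p = toy.segments["pelvis"].distal_jrc
        Rp = Rotation.from_rotvec(rots["pelvis"]).as_matrix()
        tp = np.array([0.01, -0.02, 0.96])
        true["pelvis"] = SegmentPose(Rp, tp)
        hip_lab = true["pelvis"].apply(hip_p)
        for s in ("thigh", "patella", "shank", "foot"):
            R = Rotation.from_rotvec(rots[s]).as_matrix()
            if s == "thigh":
                true[s] = SegmentPose(R, hip_lab - R @ toy.segments["thigh"].proximal_jrc)
            else:
                true[s] = SegmentPose(R, np.array([0.0, 0.0, 0.9]) + R @ np.array([0, 0, -0.4]))
        positions = _synth_frame(toy, true)
        poses, rmse, ok = solve_frame(positions, toy_calib, toy, true)
        assert ok and rmse < 1e-9
        for s, p in true.items():
            assert np.linalg.norm(poses[s].translation - p.translation) < 1e-8
            dR = Rotation.from_matrix(poses[s].rotation.T @ p.rotation).magnitude()
            assert dR < 1e-8
        # hip spherical constraint holds exactly
        hc = poses["pelvis"].apply(hip_p) - poses["thigh"].apply(toy.segments["thigh"].proximal_jrc)
        assert np.linalg.norm(hc) < 1e-12

    def test_hip_constraint_absorbs_inconsistent_translation(self, toy, toy_calib):
        true = _identity_poses(toy)
        positions = _synth_frame(toy, true)
        for lbl, seg in toy_calib.marker_segment.items():
            if seg == "thigh":
                positions[lbl] = positions[lbl] + np.array([0.01, 0.0, 0.0])
        poses, rmse, ok = solve_frame(positions, toy_calib, toy, true)
        hip_p = toy.segments["pelvis"].distal_jrc
        hc = poses["pelvis"].apply(hip_p) - poses["thigh"].apply(toy.segments["thigh"].proximal_jrc)
        assert np.linalg.norm(hc) < 1e-9
        assert rmse > 1e-4  # the offset cannot be fully absorbed

    def test_too_few_markers_rejected(self, toy, toy_calib):
        true = _identity_poses(toy)
        positions = _synth_frame(toy, true)
        for lbl in list(positions):
            if toy_calib.marker_segment[lbl] == "foot" and lbl != "foot_1":
                positions[lbl] = None
        with pytest.raises(KinematicsError):
            solve_frame(positions, toy_calib, toy, true)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(-0.4, 0.4), st.floats(-0.4, 0.4), st.floats(-0.4, 0.4))
    def test_frame_invariance(self, rx, ry, rz):
        from hipload.synthetic import ToyConfig, toy_anatomy
        toy = toy_anatomy(ToyConfig(n_segments=3, seed=0))
        calib = calibrate(_static_from_poses(toy, _identity_poses(toy)), toy)
        base = _identity_poses(toy)
        # identity poses violate the spherical hip constraint; place the
        # thigh with its hip centre on the pelvis hip centre
        base["thigh"] = SegmentPose(np.eye(3), toy.segments["pelvis"].distal_jrc)
        positions = _synth_frame(toy, base)
        Q = Rotation.from_rotvec([rx, ry, rz]).as_matrix()
        d = np.array([0.3, -0.1, 0.2])
        moved = {lbl: Q @ p + d for lbl, p in positions.items()}
        p0, _, _ = solve_frame(positions, calib, toy, base)
        guess = {s: SegmentPose(Q @ p0[s].rotation, Q @ p0[s].translation + d) for s in p0}
        p1, rmse1, _ = solve_frame(moved, calib, toy, guess)
        assert rmse1 < 1e-9
        for s in p0:
            np.testing.assert_allclose(p1[s].rotation, Q @ p0[s].rotation, atol=1e-8)
            np.testing.assert_allclose(p1[s].translation, Q @ p0[s].translation + d, atol=1e-8)


class TestInverseKinematics:
    def test_exact_sequence_recovery(self, toy, toy_config, toy_bundle):
        trial, _, gt = toy_bundle
        calib = calibrate(_static_from_poses(toy, _identity_poses(toy)), toy)
        poses = inverse_kinematics(trial, calib, toy)
        assert np.max(poses.rmse) < 1e-7
        for s in gt.poses.segments:
            dt = np.max(np.linalg.norm(poses.translations[s] - gt.poses.translations[s], axis=1))
            assert dt < 1e-6
            for i in range(poses.n_frames):
                dR = Rotation.from_matrix(
                    poses.rotations[s][i].T @ gt.poses.rotations[s][i]).magnitude()
                assert dR < 1e-6

    def test_dropped_marker_frame_still_solves(self, toy, toy_bundle):
        trial, _, _ = toy_bundle
        t2 = MarkerTrial(trial.rate, trial.time,
                         {k: v.copy() for k, v in trial.markers.items()},
                         {k: v.copy() for k, v in trial.valid.items()})
        t2.valid["foot_4"][3] = False
        calib = calibrate(_static_from_poses(toy, _identity_poses(toy)), toy)
        poses = inverse_kinematics(t2, calib, toy)
        assert np.max(poses.rmse) < 1e-6


class TestDifferentiate:
    def _series(self, R_fun, t_fun, n=50, rate=100.0):
        t = np.arange(n) / rate
        R = np.array([R_fun(tt) for tt in t])
        tr = np.array([t_fun(tt) for tt in t])
        return PoseSeries(t, rate, {"thigh": R}, {"thigh": tr}, np.zeros(n))

    def test_constant_pose_zero_derivatives(self, toy):
        s = self._series(lambda t: np.eye(3), lambda t: np.array([1.0, 2.0, 3.0]))
        differentiate(s, toy, {"thigh": np.array([0.0, 0.0, -0.2])})
        assert np.all(s.omega["thigh"] == 0)
        assert np.all(s.alpha["thigh"] == 0)
        np.testing.assert_allclose(s.a_com["thigh"], 0, atol=1e-8)

    def test_uniform_rotation_about_z(self, toy):
        w = 3.0
        s = self._series(
            lambda t: Rotation.from_rotvec([0, 0, w * t]).as_matrix(),
            lambda t: np.zeros(3), n=100)
        differentiate(s, toy, {"thigh": np.zeros(3)})
        np.testing.assert_allclose(
            s.omega["thigh"][5:-5], np.tile([0.0, 0.0, w], (90, 1)), atol=5e-3)

    def test_quadratic_com_trajectory_exact(self, toy):
        a = np.array([0.3, -0.2, 0.5])
        s = self._series(lambda t: np.eye(3), lambda t: 0.5 * a * t * t, n=20)
        differentiate(s, toy, {"thigh": np.zeros(3)})
        np.testing.assert_allclose(s.a_com["thigh"], np.tile(a, (20, 1)), rtol=1e-8, atol=1e-10)
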