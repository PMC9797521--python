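"""Marker filtering, static calibration and 6-DOF inverse kinematics.

Per frame, segment poses are found by minimising the RMS distance between
measured markers and model (virtual) markers, with the hip modelled as a
spherical joint: the thigh keeps only its three rotational degrees of freedom
and its translation is eliminated through the pelvis hip centre.  Rotations
are parameterised by rotation vectors, which are singularity-free over the
per-frame increments encountered in gait.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .anatomy import AnatomyDataset, SEGMENT_NAMES


class KinematicsError(ValueError):
    pass


@dataclass
class MarkerTrial:
    """Lab-frame marker trajectories sampled uniformly at ``rate`` Hz."""

    rate: float
    time: np.ndarray                      # (n,)
    markers: Dict[str, np.ndarray]        # label -> (n, 3) [m]
    valid: Dict[str, np.ndarray] = field(default_factory=dict)  # label -> (n,) bool

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.shape[0]
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise KinematicsError("time must be strictly increasing")
        for lbl, pos in self.markers.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (n, 3):
                raise KinematicsError(f"marker {lbl}: shape {pos.shape} != ({n}, 3)")
            self.markers[lbl] = pos
        for lbl in self.markers:
            if lbl not in self.valid:
                self.valid[lbl] = np.ones(n, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]


@dataclass
class ForcePlateSeries:
    """Ground-reaction wrench per frame, lab frame: force [N], centre of
    pressure [m], free moment [N m]."""

    force: np.ndarray        # (n, 3)
    cop: np.ndarray          # (n, 3)
    free_moment: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.cop = np.asarray(self.cop, dtype=float)
        self.free_moment = np.asarray(self.free_moment, dtype=float)
        n = self.force.shape[0]
        if self.cop.shape != (n, 3) or self.free_moment.shape != (n, 3):
            raise KinematicsError("force-plate series shapes disagree")

    @property
    def n_frames(self) -> int:
        return self.force.shape[0]

    def resample(self, t_src: np.ndarray, t_dst: np.ndarray) -> "ForcePlateSeries":
        """Linear interpolation onto marker time stamps."""
        def interp(a: np.ndarray) -> np.ndarray:
            return np.column_stack([np.interp(t_dst, t_src, a[:, i]) for i in range(3)])
        return ForcePlateSeries(interp(self.force), interp(self.cop), interp(self.free_moment))


@dataclass
class SegmentPose:
    rotation: np.ndarray     # (3, 3), segment-local -> lab
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6 or np.linalg.det(R) < 0:
            raise KinematicsError("rotation must be a proper orthonormal matrix")

    def apply(self, local: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(local, float) + self.translation


@dataclass
class PoseSeries:
    """Per-frame poses for the tracked segments, with derived kinematics."""

    time: np.ndarray
    rate: float
    rotations: Dict[str, np.ndarray]      # seg -> (n, 3, 3)
    translations: Dict[str, np.ndarray]   # seg -> (n, 3)
    rmse: np.ndarray                      # (n,) marker-fit RMSE [m]
    flags: List[str] = field(default_factory=list)
    omega: Dict[str, np.ndarray] = field(default_factory=dict)      # (n, 3) rad/s
    alpha: Dict[str, np.ndarray] = field(default_factory=dict)      # (n, 3) rad/s^2
    a_com: Dict[str, np.ndarray] = field(default_factory=dict)      # (n, 3) m/s^2

    @property
    def segments(self) -> List[str]:
        return list(self.rotations)

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    def pose(self, seg: str, i: int) -> SegmentPose:
        return SegmentPose(self.rotations[seg][i], self.translations[seg][i])

    def frame_poses(self, i: int) -> Dict[str, SegmentPose]:
        return {s: self.pose(s, i) for s in self.rotations}


@dataclass
class CalibrationResult:
    """Marker positions expressed in segment-local frames, from a static trial."""

    marker_local: Dict[str, np.ndarray]          # label -> (3,)
    marker_segment: Dict[str, str]               # label -> segment name
    static_poses: Dict[str, SegmentPose]
    residual_rmse: float
    inter_hip_distance: Optional[float] = None


def lowpass_filter(trial: MarkerTrial, order: int = 4, fc: float = 10.0) -> MarkerTrial:
    """Zero-phase Butterworth low-pass filter of every marker coordinate.

    Forward-backward application squares the magnitude response and cancels
    phase lag; endpoints are protected by the filter's reflective padding.
    """
    if not fc < trial.rate / 2.0:
        raise KinematicsError(f"corner frequency {fc} Hz >= Nyquist {trial.rate / 2} Hz")
    b, a = butter(order, fc, fs=trial.rate)
    padlen = min(3 * max(len(a), len(b)), trial.n_frames - 1)
    out = {lbl: filtfilt(b, a, pos, axis=0, padtype="odd", padlen=padlen)
           for lbl, pos in trial.markers.items()}
    return MarkerTrial(trial.rate, trial.time.copy(), out, {k: v.copy() for k, v in trial.valid.items()})


def fit_rigid(local: np.ndarray, lab: np.ndarray) -> SegmentPose:
    """Least-squares rigid fit (Kabsch): find R, t minimising ||R a + t - b||."""
    local = np.asarray(local, float)
    lab = np.asarray(lab, float)
    ca, cb = local.mean(axis=0), lab.mean(axis=0)
    H = (lab - cb).T @ (local - ca)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    R = U @ D @ Vt
    return SegmentPose(R, cb - R @ ca)


def _collinear(pts: np.ndarray, tol: float = 1e-10) -> bool:
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s.shape[0] < 2 or s[1] <= tol * max(s[0], 1.0)


def calibrate(
    static: MarkerTrial,
    anatomy: AnatomyDataset,
    window: float = 0.1,
) -> CalibrationResult:
    """Derive marker-to-segment offsets from the first ``window`` seconds of a
    standing trial.

    Marker positions are time-averaged over the window; for every segment the
    anatomy landmarks matching its marker labels are rigidly fitted to the
    averages, and each marker's local offset is the average position expressed
    in the fitted segment frame.
    """
    t0 = static.time[0]
    sel = static.time <= t0 + window + 1e-12
    if not np.any(sel):
        raise KinematicsError("calibration window contains no frames")
    avg = {lbl: pos[sel].mean(axis=0) for lbl, pos in static.markers.items()}

    marker_local: Dict[str, np.ndarray] = {}
    marker_segment: Dict[str, str] = {}
    static_poses: Dict[str, SegmentPose] = {}
    sq_sum, n_mk = 0.0, 0
    for name, seg in anatomy.segments.items():
        labels = [l for l in seg.marker_labels if l in avg]
        if not labels:
            continue
        if len(labels) < 3:
            raise KinematicsError(f"segment {name}: fewer than 3 markers visible")
        local = np.array([seg.landmarks[l] for l in labels])
        if _collinear(local):
            raise KinematicsError(f"segment {name}: markers are collinear; pose under-determined")
        lab = np.array([avg[l] for l in labels])
        pose = fit_rigid(local, lab)
        static_poses[name] = pose
        for l, b in zip(labels, lab):
            marker_local[l] = pose.rotation.T @ (b - pose.translation)
            marker_segment[l] = name
            # residual of the anatomy-landmark fit (the offsets themselves
            # reproduce the averaged markers exactly by construction)
            sq_sum += float(np.sum((pose.apply(seg.landmarks[l]) - b) ** 2))
            n_mk += 1

    inter_hip = None
    pel = anatomy.segments.get("pelvis")
    if pel is not None and pel.distal_jrc is not None and "hip_contra" in pel.landmarks:
        inter_hip = float(np.linalg.norm(pel.landmarks["hip_contra"] - pel.distal_jrc))
        if "pelvis" in static_poses:
            # measured in the lab through the fitted pelvis pose (equals the
            # local distance exactly; kept as the measurement path)
            p = static_poses["pelvis"]
            inter_hip = float(np.linalg.norm(p.apply(pel.landmarks["hip_contra"]) - p.apply(pel.distal_jrc)))
    return CalibrationResult(marker_local, marker_segment, static_poses,
                             float(np.sqrt(sq_sum / max(n_mk, 1))), inter_hip)


def _hip_centres(anatomy: AnatomyDataset) -> Tuple[np.ndarray, np.ndarray]:
    """(pelvis-local, thigh-local) hip centre positions."""
    pel = anatomy.segments["pelvis"]
    th = anatomy.segments["thigh"]
    if pel.distal_jrc is None or th.proximal_jrc is None:
        raise KinematicsError("hip joint centres missing from anatomy")
    return pel.distal_jrc, th.proximal_jrc


class _FrameParam:
    """Maps a flat parameter vector to segment poses, eliminating the thigh
    translation through the spherical hip constraint when possible."""

    def __init__(self, segments: Sequence[str], anatomy: AnatomyDataset):
        self.segments = list(segments)
        self.hip_constrained = "pelvis" in self.segments and "thigh" in self.segments
        if self.hip_constrained:
            self.h_pelvis, self.h_thigh = _hip_centres(anatomy)
        self.layout: Dict[str, Tuple[int, int]] = {}
        k = 0
        for s in self.segments:
            ndof = 3 if (s == "thigh" and self.hip_constrained) else 6
            self.layout[s] = (k, ndof)
            k += ndof
        self.n_params = k

    def encode(self, poses: Mapping[str, SegmentPose]) -> np.ndarray:
        x = np.zeros(self.n_params)
        for s in self.segments:
            k, ndof = self.layout[s]
            x[k:k + 3] = Rotation.from_matrix(poses[s].rotation).as_rotvec()
            if ndof == 6:
                x[k + 3:k + 6] = poses[s].translation
        return x

    def decode(self, x: np.ndarray) -> Dict[str, SegmentPose]:
        poses: Dict[str, SegmentPose] = {}
        for s in self.segments:
            k, ndof = self.layout[s]
            R = Rotation.from_rotvec(x[k:k + 3]).as_matrix()
            if ndof == 6:
                poses[s] = SegmentPose(R, x[k + 3:k + 6].copy())
        if self.hip_constrained:
            k, _ = self.layout["thigh"]
            R = Rotation.from_rotvec(x[k:k + 3]).as_matrix()
            hip_lab = poses["pelvis"].apply(self.h_pelvis)
            poses["thigh"] = SegmentPose(R, hip_lab - R @ self.h_thigh)
        return poses


def solve_frame(
    positions: Mapping[str, Optional[np.ndarray]],
    calib: CalibrationResult,
    anatomy: AnatomyDataset,
    guess: Mapping[str, SegmentPose],
) -> Tuple[Dict[str, SegmentPose], float, bool]:
    """Fit all segment poses to one frame of markers.

    Returns (poses, marker RMSE [m], converged).  Markers with ``None`` /
    missing positions are excluded from the residual.  The thigh translation
    is eliminated through the hip spherical constraint, so the constraint is
    satisfied exactly by construction.
    """
    by_seg: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {}
    for lbl, pos in positions.items():
        if pos is None or lbl not in calib.marker_segment:
            continue
        by_seg.setdefault(calib.marker_segment[lbl], []).append(
            (calib.marker_local[lbl], np.asarray(pos, float))
        )
    segments = [s for s in SEGMENT_NAMES if s in by_seg]
    for s in segments:
        if len(by_seg[s]) < 3:
            raise KinematicsError(f"segment {s}: fewer than 3 valid markers in frame")
    param = _FrameParam(segments, anatomy)

    locals_ = {s: np.array([a for a, _ in by_seg[s]]) for s in segments}
    labs = {s: np.array([b for _, b in by_seg[s]]) for s in segments}
    n_mk = sum(len(v) for v in by_seg.values())

    def residual(x: np.ndarray) -> np.ndarray:
        poses = param.decode(x)
        out = []
        for s in segments:
            p = poses[s]
            out.append((locals_[s] @ p.rotation.T + p.translation - labs[s]).ravel())
        return np.concatenate(out)

    x0 = param.encode(guess)
    res = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    poses = param.decode(res.x)
    rmse = float(np.sqrt(np.mean(np.sum(residual(res.x).reshape(-1, 3) ** 2, axis=1))))
    return poses, rmse, bool(res.success)


def inverse_kinematics(
    trial: MarkerTrial,
    calib: CalibrationResult,
    anatomy: AnatomyDataset,
) -> PoseSeries:
    """Per-frame pose fit over a trial, warm-started from the previous frame
    (first frame from the calibration pose)."""
    n = trial.n_frames
    guess = dict(calib.static_poses)
    rotations: Dict[str, List[np.ndarray]] = {}
    translations: Dict[str, List[np.ndarray]] = {}
    rmse = np.zeros(n)
    flags: List[str] = []
    for i in range(n):
        positions = {
            lbl: (trial.markers[lbl][i] if trial.valid[lbl][i] else None)
            for lbl in trial.markers
        }
        poses, r, ok = solve_frame(positions, calib, anatomy, guess)
        if not ok:
            flags.append(f"frame {i}: solver did not report convergence (rmse={r:.3e})")
        rmse[i] = r
        for s, p in poses.items():
            rotations.setdefault(s, []).append(p.rotation)
            translations.setdefault(s, []).append(p.translation)
        guess = poses
    series = PoseSeries(
        trial.time.copy(), trial.rate,
        {s: np.array(v) for s, v in rotations.items()},
        {s: np.array(v) for s, v in translations.items()},
        rmse, flags,
    )
    return series


def _skew_to_vec(W: np.ndarray) -> np.ndarray:
    A = 0.5 * (W - W.T)
    return np.array([A[2, 1], A[0, 2], A[1, 0]])


def _second_derivative(y: np.ndarray, dt: float) -> np.ndarray:
    """Second time derivative, O(dt^2) everywhere.

    Central three-point stencil in the interior; four-point one-sided
    stencils at the first and last sample (exact for cubics).
    """
    n = y.shape[0]
    out = np.empty_like(y, dtype=float)
    out[1:-1] = (y[2:] - 2.0 * y[1:-1] + y[:-2]) / dt ** 2
    if n >= 4:
        out[0] = (2.0 * y[0] - 5.0 * y[1] + 4.0 * y[2] - y[3]) / dt ** 2
        out[-1] = (2.0 * y[-1] - 5.0 * y[-2] + 4.0 * y[-3] - y[-4]) / dt ** 2
    else:
        out[0] = out[1]
        out[-1] = out[-2]
    return out


def differentiate(series: PoseSeries, anatomy: AnatomyDataset,
                  com_local: Mapping[str, np.ndarray]) -> PoseSeries:
    """Fill angular velocity/acceleration and centre-of-mass acceleration.

    Central differences on interior frames, second-order one-sided at the
    ends; angular velocity is the axial vector of dR/dt R^T.
    ``com_local`` gives each segment's centre of mass in its local frame.
    """
    n = series.n_frames
    if n < 3:
        raise KinematicsError("differentiation needs at least 3 frames")
    t = series.time
    dt = float(np.median(np.diff(t)))
    for s in series.segments:
        R = series.rotations[s]                     # (n, 3, 3)
        dR = np.gradient(R, t, axis=0, edge_order=2)
        omega = np.array([_skew_to_vec(dR[i] @ R[i].T) for i in range(n)])
        alpha = np.gradient(omega, t, axis=0, edge_order=2)
        if n >= 4:
            # the chained one-sided gradients are only O(dt) at the very
            # ends; replace them with direct four-point stencils
            alpha[0] = (-11.0 * omega[0] + 18.0 * omega[1]
                        - 9.0 * omega[2] + 2.0 * omega[3]) / (6.0 * dt)
            alpha[-1] = (11.0 * omega[-1] - 18.0 * omega[-2]
                         + 9.0 * omega[-3] - 2.0 * omega[-4]) / (6.0 * dt)
        com = np.einsum("nij,j->ni", R, np.asarray(com_local[s], float)) + series.translations[s]
        series.omega[s] = omega
        series.alpha[s] = alpha
        series.a_com[s] = _second_derivative(com, dt)
    return series
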