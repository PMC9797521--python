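"""Synthetic anatomies and dynamically consistent trials with ground truth.

The generator builds a reduced lower-limb chain (pelvis, thigh, optional
shank/foot/patella) with realistic magnitudes (segment lengths 0.1-0.5 m,
PCSA 2-40 cm^2, maximum muscle stress 31.39 N/cm^2), prescribes smooth
sinusoidal joint motion, differentiates the chain kinematics analytically
(recursive rigid-body formulas, no finite differences), and defines the
ground-truth force solution as the global optimum of the convex frame
problem at the stated alpha.  Marker positions are exact up to optional
seeded Gaussian noise, so every pipeline stage can be tested against a
known answer without any external dataset.

Muscle elements are placed azimuthally around each joint with alternating
helical offsets, which spans the joint moment space in all three axes with
both signs — necessary because the hip and ankle contact forces act at the
proximal joint rotation centres and have no moment authority there.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .anatomy import (
    AnatomyDataset,
    AnatomySegment,
    MuscleElement,
    Subject,
    WrappingCylinder,
    compute_max_forces,
)
from .dynamics import GRAVITY, InertialParams, params_from_anatomy
from .force_share import FrameProblem, FrameSolution, SolverConfig, assemble_series
from .kinematics import ForcePlateSeries, MarkerTrial, PoseSeries
from .oracle import solve_oracle


class SyntheticError(ValueError):
    pass


@dataclass
class ToyConfig:
    n_segments: int = 5               # 2..5: pelvis+thigh, +shank, +foot, +patella
    muscles_per_joint: int = 4        # 1..4
    include_cylinder: bool = False
    marker_noise_sd: float = 0.0      # [m]
    grf_noise_sd: float = 0.0         # [N]
    amplitude_deg: float = 12.0       # joint-angle oscillation amplitude
    period_s: float = 1.0
    duration_s: float = 1.0
    rate: float = 100.0
    alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_segments <= 5:
            raise SyntheticError("n_segments must be in 2..5")
        if not 1 <= self.muscles_per_joint <= 4:
            raise SyntheticError("muscles_per_joint must be in 1..4")
        if self.marker_noise_sd < 0 or self.grf_noise_sd < 0:
            raise SyntheticError("noise sd must be >= 0")
        if self.include_cylinder and self.n_segments < 4:
            raise SyntheticError("the wrap cylinder requires the foot (n_segments >= 4)")

    @property
    def segments(self) -> List[str]:
        return ["pelvis", "thigh", "shank", "foot", "patella"][: self.n_segments]


@dataclass
class GroundTruth:
    poses: PoseSeries
    problems: List[FrameProblem]
    solutions: List[FrameSolution]
    params: InertialParams
    alpha: float

    @property
    def hcf_bw(self) -> np.ndarray:
        """Hip contact force magnitude per frame, %BW."""
        bw = self.problems[0].bw
        return np.array([s.hcf / bw * 100.0 for s in self.solutions])


_MARKER_OFFSETS: Dict[str, List[Tuple[float, float, float]]] = {
    "pelvis": [(0.06, 0.07, 0.03), (0.06, -0.07, 0.03), (-0.07, 0.05, 0.01), (-0.06, -0.06, 0.05)],
    "thigh": [(0.05, 0.03, -0.06), (-0.04, 0.05, -0.15), (0.05, -0.04, -0.25), (-0.03, -0.05, -0.33)],
    "shank": [(0.04, 0.03, -0.05), (-0.03, 0.04, -0.14), (0.04, -0.03, -0.24), (-0.03, -0.04, -0.32)],
    "foot": [(0.02, 0.03, 0.02), (0.12, 0.02, -0.03), (0.10, -0.03, -0.05), (-0.04, 0.00, 0.01)],
    "patella": [(0.020, 0.015, 0.010), (0.020, -0.015, 0.008), (0.012, 0.010, -0.012), (0.016, -0.010, -0.009)],
}

_HIP_LOCAL_PELVIS = np.array([0.0, 0.09, -0.06])
_L_THIGH = 0.40
_L_SHANK = 0.40

_HIP_GROUPS = ["hip_extensor", "hip_abductor", "other", "hip_adductor"]


def toy_anatomy(config: ToyConfig) -> AnatomyDataset:
    """Reduced chain anatomy; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    segs = config.segments
    segments: Dict[str, AnatomySegment] = {}

    def markers(name: str) -> Tuple[Dict[str, np.ndarray], Tuple[str, ...]]:
        lm = {f"{name}_{i+1}": np.array(o) for i, o in enumerate(_MARKER_OFFSETS[name])}
        return lm, tuple(lm)

    lm, labels = markers("pelvis")
    lm["hip_contra"] = _HIP_LOCAL_PELVIS * np.array([1.0, -1.0, 1.0])
    segments["pelvis"] = AnatomySegment(
        "pelvis", landmarks=lm, distal_jrc=_HIP_LOCAL_PELVIS.copy(), marker_labels=labels)

    lm, labels = markers("thigh")
    segments["thigh"] = AnatomySegment(
        "thigh", landmarks=lm, proximal_jrc=np.zeros(3), distal_jrc=np.array([0.0, 0.0, -_L_THIGH]),
        contact_points={"hip": np.zeros(3)}, marker_labels=labels)

    if "shank" in segs:
        lm, labels = markers("shank")
        segments["shank"] = AnatomySegment(
            "shank", landmarks=lm, proximal_jrc=np.zeros(3), distal_jrc=np.array([0.0, 0.0, -_L_SHANK]),
            contact_points={"tf_medial": np.array([0.0, 0.035, 0.005]),
                            "tf_lateral": np.array([0.0, -0.035, 0.005])},
            marker_labels=labels)
    if "foot" in segs:
        lm, labels = markers("foot")
        lm["toe"] = np.array([0.15, 0.0, -0.07])
        lm["heel"] = np.array([-0.05, 0.0, -0.07])
        segments["foot"] = AnatomySegment(
            "foot", landmarks=lm, proximal_jrc=np.zeros(3),
            contact_points={"ankle": np.zeros(3)}, marker_labels=labels)
    if "patella" in segs:
        lm, labels = markers("patella")
        lm["top"] = np.array([0.0, 0.0, 0.015])
        lm["bottom"] = np.array([0.0, 0.0, -0.015])
        segments["patella"] = AnatomySegment(
            "patella", landmarks=lm, proximal_jrc=np.zeros(3),
            contact_points={"pf": np.array([-0.02, 0.005, 0.0])}, marker_labels=labels)

    muscles: List[MuscleElement] = []
    n = config.muscles_per_joint

    def ring(k: int, n: int, radius: float, z: float, twist: float) -> np.ndarray:
        phi = 2.0 * np.pi * k / n + twist
        return np.array([radius * np.cos(phi), radius * np.sin(phi), z])

    def pcsa() -> float:
        return float(rng.uniform(22.0, 40.0))

    for k in range(n):
        tw = 0.2 * (1 if k % 2 == 0 else -1)
        muscles.append(MuscleElement(
            id=f"hip_{k+1}", muscle=f"hip_{k+1}",
            path=[("pelvis", _HIP_LOCAL_PELVIS + ring(k, n, 0.08, 0.03, tw)),
                  ("thigh", ring(k, n, 0.06, -0.16, -tw))],
            pcsa=pcsa(), group=_HIP_GROUPS[k % 4]))
    if "shank" in segs:
        for k in range(n):
            tw = 0.2 * (1 if k % 2 == 0 else -1)
            muscles.append(MuscleElement(
                id=f"knee_{k+1}", muscle=f"knee_{k+1}",
                path=[("thigh", ring(k, n, 0.08, -0.25, tw)),
                      ("shank", ring(k, n, 0.075, -0.15, -tw))],
                pcsa=pcsa(), group="knee"))
    if "foot" in segs:
        for k in range(n):
            tw = 0.2 * (1 if k % 2 == 0 else -1)
            muscles.append(MuscleElement(
                id=f"ankle_{k+1}", muscle=f"ankle_{k+1}",
                path=[("shank", ring(k, n, 0.05, -0.32, tw)),
                      ("foot", ring(k, n, 0.08, -0.05, -tw))],
                pcsa=pcsa(), group="ankle"))
    if "patella" in segs:
        quad_geo = [(-0.035, -0.012, 0.010), (-0.012, 0.014, -0.006),
                    (0.012, -0.014, 0.006), (0.035, 0.012, -0.010)]
        for k, (y0, x_ins, y_ins) in enumerate(quad_geo):
            muscles.append(MuscleElement(
                id=f"quad_{k+1}", muscle=f"vastus_{k+1}",
                path=[("thigh", np.array([0.045, y0, -0.15])),
                      ("patella", np.array([x_ins, 0.5 * y0 + y_ins, 0.015]))],
                pcsa=pcsa(), group="knee"))
        # the patellar tendon is broad: two tensile bands give the patella
        # moment balance a full positive cone together with the PF contact
        for tag, y0 in (("medial", 0.008), ("lateral", -0.008)):
            muscles.append(MuscleElement(
                id=f"patellar_tendon_{tag}", muscle="patellar_tendon",
                path=[("patella", np.array([0.004, y0, -0.015])),
                      ("shank", np.array([0.035, 1.5 * y0, -0.06]))],
                role="ligament", group="other"))

    cylinders: List[WrappingCylinder] = []
    if config.include_cylinder:
        muscles.append(MuscleElement(
            id="gastroc", muscle="gastrocnemius_medial",
            path=[("thigh", np.array([-0.035, 0.01, -0.34])),
                  ("foot", np.array([-0.05, 0.0, -0.02]))],
            pcsa=pcsa(), group="ankle"))
        cylinders.append(WrappingCylinder(
            id="femoral_condyle", segment="thigh",
            axis_point=np.array([-0.01, 0.0, -_L_THIGH]),
            axis_dir=np.array([0.0, 1.0, 0.0]),
            radius=0.025, wrapped_elements=("gastroc",)))

    ds = AnatomyDataset(
        subject=Subject(height=1.80, mass=70.0, sex="M", age=25.0),
        segments=segments, muscles=muscles, cylinders=cylinders)
    return compute_max_forces(ds)


class _Angle:
    """theta(t) = offset + amp * sin(2 pi t / T + phase), with derivatives."""

    def __init__(self, offset: float, amp: float, period: float, phase: float):
        self.offset, self.amp, self.w, self.phase = offset, amp, 2.0 * np.pi / period, phase

    def __call__(self, t: float) -> Tuple[float, float, float]:
        s = np.sin(self.w * t + self.phase)
        c = np.cos(self.w * t + self.phase)
        return (self.offset + self.amp * s,
                self.amp * self.w * c,
                -self.amp * self.w ** 2 * s)


def _rot_y(th: float) -> np.ndarray:
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(th: float) -> np.ndarray:
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class _Body:
    R: np.ndarray
    t: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    a_origin: np.ndarray


def _chain_state(config: ToyConfig, t: float, amp_scale: float = 1.0) -> Dict[str, _Body]:
    """Analytic poses and kinematics of every segment at time ``t``."""
    A = np.deg2rad(config.amplitude_deg) * amp_scale
    T = config.period_s
    hip = _Angle(0.15, A, T, 0.0)
    knee = _Angle(-0.25, -A, T, 0.0)
    ankle = _Angle(0.05, 0.4 * A, T, 1.6)
    pel_rot = _Angle(0.0, 0.05 * amp_scale, T, 0.4)
    w = 2.0 * np.pi / T

    # pelvis root: analytic translation + small axial rotation
    s1, c1 = np.sin(w * t), np.cos(w * t)
    s2, c2 = np.sin(2 * w * t + 0.5), np.cos(2 * w * t + 0.5)
    tp = np.array([0.02 * s1, 0.01 * s2, 0.95 + 0.015 * np.sin(2 * w * t)]) * \
        np.array([amp_scale, amp_scale, 1.0])
    tp[2] = 0.95 + 0.015 * amp_scale * np.sin(2 * w * t)
    ap = np.array([-0.02 * w ** 2 * s1 * amp_scale,
                   -0.01 * (2 * w) ** 2 * s2 * amp_scale,
                   -0.015 * (2 * w) ** 2 * amp_scale * np.sin(2 * w * t)])
    phi, dphi, ddphi = pel_rot(t)
    z = np.array([0.0, 0.0, 1.0])
    bodies: Dict[str, _Body] = {}
    bodies["pelvis"] = _Body(_rot_z(phi), tp, z * dphi, z * ddphi, ap)

    def attach(parent: str, offset_local: np.ndarray, axis: np.ndarray,
               th: float, dth: float, ddth: float) -> _Body:
        p = bodies[parent]
        r = p.R @ offset_local
        origin = p.t + r
        a_origin = p.a_origin + np.cross(p.alpha, r) + np.cross(p.omega, np.cross(p.omega, r))
        axis_lab = p.R @ axis
        R = p.R @ _rot_y(th) if np.allclose(axis, [0, 1, 0]) else p.R @ _rot_z(th)
        omega = p.omega + axis_lab * dth
        alpha = p.alpha + axis_lab * ddth + np.cross(p.omega, axis_lab * dth)
        return _Body(R, origin, omega, alpha, a_origin)

    y = np.array([0.0, 1.0, 0.0])
    th, dth, ddth = hip(t)
    bodies["thigh"] = attach("pelvis", _HIP_LOCAL_PELVIS, y, th, dth, ddth)
    if "shank" in config.segments:
        th, dth, ddth = knee(t)
        bodies["shank"] = attach("thigh", np.array([0.0, 0.0, -_L_THIGH]), y, th, dth, ddth)
    if "foot" in config.segments:
        th, dth, ddth = ankle(t)
        bodies["foot"] = attach("shank", np.array([0.0, 0.0, -_L_SHANK]), y, th, dth, ddth)
    if "patella" in config.segments:
        th, dth, ddth = knee(t)
        bodies["patella"] = attach(
            "thigh", np.array([0.055, 0.0, 0.015 - _L_THIGH]), y, 0.3 * th, 0.3 * dth, 0.3 * ddth)
    return bodies


def _pose_series(anatomy: AnatomyDataset, config: ToyConfig, time: np.ndarray,
                 params: InertialParams, amp_scale: float = 1.0) -> PoseSeries:
    com_local = params.com_local(anatomy)
    segs = config.segments
    n = time.size
    rot = {s: np.zeros((n, 3, 3)) for s in segs}
    tra = {s: np.zeros((n, 3)) for s in segs}
    omega = {s: np.zeros((n, 3)) for s in segs}
    alpha = {s: np.zeros((n, 3)) for s in segs}
    a_com = {s: np.zeros((n, 3)) for s in segs}
    for i, t in enumerate(time):
        bodies = _chain_state(config, float(t), amp_scale)
        for s in segs:
            b = bodies[s]
            rot[s][i] = b.R
            tra[s][i] = b.t
            omega[s][i] = b.omega
            alpha[s][i] = b.alpha
            c = b.R @ com_local[s]
            a_com[s][i] = b.a_origin + np.cross(b.alpha, c) + \
                np.cross(b.omega, np.cross(b.omega, c))
    series = PoseSeries(time.copy(), config.rate, rot, tra, np.zeros(n))
    series.omega, series.alpha, series.a_com = omega, alpha, a_com
    return series


def _markers_from_poses(anatomy: AnatomyDataset, poses: PoseSeries,
                        noise_sd: float, rng: np.random.Generator) -> MarkerTrial:
    markers: Dict[str, np.ndarray] = {}
    for name, seg in anatomy.segments.items():
        if name not in poses.segments:
            continue
        R = poses.rotations[name]
        t = poses.translations[name]
        for lbl in seg.marker_labels:
            pos = np.einsum("nij,j->ni", R, seg.landmarks[lbl]) + t
            if noise_sd > 0:
                pos = pos + rng.normal(scale=noise_sd, size=pos.shape)
            markers[lbl] = pos
    return MarkerTrial(poses.rate, poses.time.copy(), markers)


def _toy_grf(anatomy: AnatomyDataset, config: ToyConfig, poses: PoseSeries,
             rng: np.random.Generator) -> ForcePlateSeries:
    n = poses.n_frames
    bw = anatomy.subject.weight
    t = poses.time
    w = 2.0 * np.pi / config.period_s
    if "foot" not in poses.segments:
        return ForcePlateSeries(np.zeros((n, 3)), np.zeros((n, 3)), np.zeros((n, 3)))
    force = np.column_stack([
        0.02 * bw * np.sin(w * t + 0.2),
        0.015 * bw * np.sin(w * t + 1.1),
        0.45 * bw * (0.95 + 0.10 * np.sin(w * t + 0.6)),
    ])
    ankle = poses.translations["foot"]
    cop = np.column_stack([ankle[:, 0] + 0.02, ankle[:, 1], np.zeros(n)])
    free = np.column_stack([np.zeros(n), np.zeros(n), 0.2 * np.sin(w * t)])
    if config.grf_noise_sd > 0:
        force = force + rng.normal(scale=config.grf_noise_sd, size=force.shape)
    return ForcePlateSeries(force, cop, free)


def generate_static_trial(anatomy: AnatomyDataset, config: ToyConfig,
                          duration: float = 0.15) -> MarkerTrial:
    """Standing trial at the chain's neutral angles (calibration input)."""
    params = params_from_anatomy(anatomy)
    n = max(int(round(duration * config.rate)), 2)
    time = np.arange(n) / config.rate
    poses = _pose_series(anatomy, config, time, params, amp_scale=0.0)
    rng = np.random.default_rng(config.seed + 1)
    return _markers_from_poses(anatomy, poses, config.marker_noise_sd, rng)


def generate_trial(
    anatomy: AnatomyDataset,
    config: ToyConfig,
    solve_ground_truth: bool = True,
) -> Tuple[MarkerTrial, ForcePlateSeries, GroundTruth]:
    """Dynamic trial: markers, GRF and the ground-truth optimal solution."""
    params = params_from_anatomy(anatomy)
    n = max(int(round(config.duration_s * config.rate)), 3)
    time = np.arange(n) / config.rate
    poses = _pose_series(anatomy, config, time, params)
    rng = np.random.default_rng(config.seed + 2)
    trial = _markers_from_poses(anatomy, poses, config.marker_noise_sd, rng)
    grf = _toy_grf(anatomy, config, poses, rng)
    problems = assemble_series(anatomy, poses, params, grf,
                               SolverConfig(alpha=config.alpha))
    solutions: List[FrameSolution] = []
    if solve_ground_truth:
        for p in problems:
            sol = solve_oracle(p, alpha=config.alpha)
            if not sol.converged:
                raise SyntheticError(f"ground-truth solve failed: {sol.status}")
            solutions.append(sol)
    return trial, grf, GroundTruth(poses, problems, solutions, params, config.alpha)


def alpha_sweep_fixture(
    anatomy: AnatomyDataset,
    problems: List[FrameProblem],
    alphas: Tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 5.0),
) -> List[Dict[str, float]]:
    """Mean hip contact force and mean squared-stress sum per alpha."""
    from .force_share import solve_trial

    rows = []
    for a in alphas:
        sols = solve_trial(problems, SolverConfig(alpha=a))
        hcf = np.array([s.hcf for s in sols])
        stress = np.array([
            float(np.sum(s.activations[p.in_objective] ** 2))
            for s, p in zip(sols, problems)
        ])
        rows.append({
            "alpha": a,
            "mean_hcf": float(hcf.mean()),
            "mean_hcf_bw": float(hcf.mean() / problems[0].bw),
            "mean_sum_sq_activation": float(stress.mean()),
            "n_converged": int(sum(s.converged for s in sols)),
            "max_activation": float(max(np.max(s.activations) for s in sols)),
        })
    return rows
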