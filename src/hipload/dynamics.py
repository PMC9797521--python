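"""Segment inertial parameters and Newton-Euler wrench inverse dynamics.

Each dynamic segment carries a 6-component equation of motion whose
right-hand side (the inertial wrench about the segment's proximal joint
rotation centre) is

    force  = M (a_com - g)
    moment = M c~ (a_com - g) + I alpha + omega x I omega

with c the lab-frame vector from the proximal JRC to the centre of mass,
c~ its cross-product matrix, and I the lab-frame inertia tensor about the
centre of mass.  The ground-reaction wrench enters the foot equation as an
external wrench applied at the centre of pressure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .anatomy import AnatomyDataset, Subject, segment_lengths, STANDARD_GRAVITY
from .kinematics import ForcePlateSeries, PoseSeries, SegmentPose

GRAVITY = np.array([0.0, 0.0, -STANDARD_GRAVITY])


class DynamicsError(ValueError):
    pass


def skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


@dataclass
class RegressionEntry:
    """Fractions of body mass / segment length defining a segment's inertia.

    ``com_fraction`` positions the centre of mass along ``axis`` (a unit
    vector in the segment's local frame, proximal to distal); the radii of
    gyration are about the two transverse axes and the longitudinal axis.
    """

    mass_fraction: float
    com_fraction: float
    rog_fractions: Tuple[float, float, float]   # (sagittal, transverse, longitudinal)
    axis: Tuple[float, float, float] = (0.0, 0.0, -1.0)


#: Generic adult-male regression table (editable).  Fractions are of total
#: body mass and of the segment's characteristic length.  The patella entry
#: is a small nominal mass: regression sources do not tabulate it.
DEFAULT_REGRESSION_TABLE: Dict[str, RegressionEntry] = {
    "pelvis": RegressionEntry(0.1117, 0.3885, (0.551, 0.615, 0.587), axis=(0.0, 0.0, 1.0)),
    "thigh": RegressionEntry(0.1416, 0.4095, (0.329, 0.329, 0.149)),
    "shank": RegressionEntry(0.0433, 0.4395, (0.251, 0.246, 0.102)),
    "foot": RegressionEntry(0.0137, 0.4415, (0.257, 0.245, 0.124), axis=(1.0, 0.0, 0.0)),
    "patella": RegressionEntry(0.0005, 0.5, (0.3, 0.3, 0.3)),
}


@dataclass
class SegmentInertia:
    mass: float
    com_from_proximal: np.ndarray   # segment-local, from the proximal JRC [m]
    inertia_local: np.ndarray       # (3, 3) about the com, segment-local [kg m^2]

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise DynamicsError("segment mass must be > 0")
        I = np.asarray(self.inertia_local, float)
        if np.linalg.norm(I - I.T) > 1e-9:
            raise DynamicsError("inertia tensor must be symmetric")
        w = np.linalg.eigvalsh(I)
        if np.any(w < -1e-12):
            raise DynamicsError("inertia tensor must be positive semi-definite")
        self.inertia_local = I


@dataclass
class InertialParams:
    segments: Dict[str, SegmentInertia]

    def com_local(self, anatomy: AnatomyDataset) -> Dict[str, np.ndarray]:
        """Centre of mass in each segment's local frame (local origin based)."""
        out = {}
        for name, si in self.segments.items():
            prox = anatomy.segments[name].proximal_jrc
            if prox is None:
                prox = np.zeros(3)
            out[name] = prox + si.com_from_proximal
        return out


def _axis_frame(axis: np.ndarray) -> np.ndarray:
    """Orthonormal basis whose third column is ``axis`` (deterministic)."""
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return np.column_stack([e1, e2, a])


def estimate_inertial_params(
    subject: Subject,
    lengths: Mapping[str, float],
    table: Optional[Mapping[str, RegressionEntry]] = None,
) -> InertialParams:
    """Per-segment mass, com offset and inertia tensor from regression fractions."""
    if table is None:
        table = DEFAULT_REGRESSION_TABLE
    out: Dict[str, SegmentInertia] = {}
    for seg, L in lengths.items():
        if seg not in table:
            raise DynamicsError(f"regression table has no entry for segment {seg!r}")
        e = table[seg]
        M = e.mass_fraction * subject.mass
        axis = np.asarray(e.axis, float)
        axis = axis / np.linalg.norm(axis)
        com = e.com_fraction * L * axis
        r_sag, r_trn, r_lng = e.rog_fractions
        principal = np.diag([M * (r_sag * L) ** 2, M * (r_trn * L) ** 2, M * (r_lng * L) ** 2])
        Q = _axis_frame(axis)
        out[seg] = SegmentInertia(M, com, Q @ principal @ Q.T)
    return InertialParams(out)


def params_from_anatomy(
    anatomy: AnatomyDataset,
    table: Optional[Mapping[str, RegressionEntry]] = None,
) -> InertialParams:
    return estimate_inertial_params(anatomy.subject, segment_lengths(anatomy), table)


def inertial_wrench(
    inertia: SegmentInertia,
    pose: SegmentPose,
    a_com: np.ndarray,
    omega: np.ndarray,
    alpha: np.ndarray,
    g: np.ndarray = GRAVITY,
) -> Tuple[np.ndarray, np.ndarray]:
    """Inertial (force, moment-about-proximal-JRC) for one segment frame."""
    R = pose.rotation
    c_lab = R @ inertia.com_from_proximal
    I_lab = R @ inertia.inertia_local @ R.T
    rel = np.asarray(a_com, float) - np.asarray(g, float)
    force = inertia.mass * rel
    moment = inertia.mass * skew(c_lab) @ rel + I_lab @ np.asarray(alpha, float) \
        + np.cross(omega, I_lab @ np.asarray(omega, float))
    return force, moment


def net_joint_loads(
    poses: PoseSeries,
    grf: ForcePlateSeries,
    params: InertialParams,
    anatomy: AnatomyDataset,
    g: np.ndarray = GRAVITY,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Classical bottom-up intersegmental wrenches at ankle, knee and hip.

    Returns per joint a dict with ``force`` and ``moment`` arrays (n, 3), the
    net load applied to the distal segment at the joint centre (reaction on
    the proximal segment is the negative).  Used to validate the optimization
    constraints; it is not part of the force-sharing solve.
    """
    n = poses.n_frames
    if grf.n_frames != n:
        raise DynamicsError("pose and force-plate frame counts differ")
    chain = [("foot", "ankle"), ("shank", "knee"), ("thigh", "hip")]
    chain = [(s, j) for s, j in chain if s in poses.segments]
    out: Dict[str, Dict[str, np.ndarray]] = {
        j: {"force": np.zeros((n, 3)), "moment": np.zeros((n, 3))} for _, j in chain
    }
    for i in range(n):
        F_child = np.zeros(3)
        M_child = np.zeros(3)
        p_child = np.zeros(3)
        for k, (seg, joint) in enumerate(chain):
            pose = poses.pose(seg, i)
            si = params.segments[seg]
            prox = anatomy.segments[seg].proximal_jrc
            p_joint = pose.apply(prox if prox is not None else np.zeros(3))
            fi, mi = inertial_wrench(si, pose, poses.a_com[seg][i],
                                     poses.omega[seg][i], poses.alpha[seg][i], g)
            # external wrench on the foot: GRF at the COP plus free moment
            f_ext = np.zeros(3)
            m_ext = np.zeros(3)
            if seg == "foot":
                f_ext = grf.force[i]
                m_ext = np.cross(grf.cop[i] - p_joint, grf.force[i]) + grf.free_moment[i]
            F = fi - f_ext + F_child
            M = mi - m_ext + M_child + np.cross(p_child - p_joint, F_child)
            out[joint]["force"][i] = F
            out[joint]["moment"][i] = M
            F_child, M_child, p_child = F, M, p_joint
    return out


def limb_closure_residual(
    poses: PoseSeries,
    grf: ForcePlateSeries,
    params: InertialParams,
    anatomy: AnatomyDataset,
    loads: Optional[Dict[str, Dict[str, np.ndarray]]] = None,
    g: np.ndarray = GRAVITY,
) -> np.ndarray:
    """Force-balance residual of the whole limb per frame.

    Sum of segment inertial forces minus GRF minus the proximal (hip) net
    force must vanish; returns the per-frame residual norm, normalised by
    body weight.
    """
    if loads is None:
        loads = net_joint_loads(poses, grf, params, anatomy, g)
    top = "hip" if "hip" in loads else list(loads)[-1]
    chain = {"ankle": "foot", "knee": "shank", "hip": "thigh"}
    segs = [s for j, s in chain.items() if j in loads]
    n = poses.n_frames
    res = np.zeros(n)
    bw = anatomy.subject.weight
    for i in range(n):
        p_top = poses.pose(chain[top], i).apply(
            anatomy.segments[chain[top]].proximal_jrc)
        ftot = -grf.force[i] - loads[top]["force"][i]
        mtot = (-np.cross(grf.cop[i] - p_top, grf.force[i]) - grf.free_moment[i]
                - loads[top]["moment"][i])
        for s in segs:
            fi, mi = inertial_wrench(params.segments[s], poses.pose(s, i),
                                     poses.a_com[s][i], poses.omega[s][i],
                                     poses.alpha[s][i], g)
            prox = poses.pose(s, i).apply(anatomy.segments[s].proximal_jrc)
            ftot = ftot + fi
            mtot = mtot + mi + np.cross(prox - p_top, fi)
        res[i] = max(np.linalg.norm(ftot) / bw, np.linalg.norm(mtot) / bw)
    return res
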