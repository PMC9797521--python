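"""World-frame muscle paths, cylindrical wrapping, lines of action.

Muscle elements are ideal frictionless cables: tension is uniform along the
element, via points split it into straight sub-segments, and a wrapping
cylinder replaces an intersecting straight sub-segment by a tangent line,
a helical geodesic on the cylinder surface and a second tangent line.  The
wrap is computed in the plane development of the cylinder (single-cylinder
obstacle-set method): unrolling the surface and tangent planes into one
plane makes the shortest path a straight line, so the axial coordinate is
linear in the developed arc length and the total length is
sqrt(L_planar^2 + dz^2).

Force bookkeeping: each path point applies ``F`` times the unit vector(s)
toward its neighbouring path points to its host segment; a wrap applies the
reaction of the two tangent-segment tensions to the cylinder's segment at
the tangent points.  These wrenches sum to zero over the whole element.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .anatomy import AnatomyDataset, MuscleElement, WrappingCylinder
from .kinematics import SegmentPose


class GeometryError(ValueError):
    pass


@dataclass
class AttachmentRecord:
    """Force application of one element on one segment: force = F * direction."""

    segment: str
    point: np.ndarray       # lab frame [m]
    direction: np.ndarray   # unit (endpoints) or resultant of units (via/wrap)


@dataclass
class MusclePathFrame:
    element_id: str
    points: List[np.ndarray]            # ordered lab-frame polyline incl. arc
    length: float
    records: List[AttachmentRecord]
    wrap_engaged: bool = False
    wrap_direction: int = 0             # +1 / -1 when engaged


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length path sub-segment")
    return v / n


def cylinder_wrap(
    p1: np.ndarray,
    p2: np.ndarray,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    radius: float,
    prefer_direction: int = 0,
    n_arc: int = 12,
) -> Tuple[List[np.ndarray], float, int]:
    """Shortest cable path from p1 to p2 around a cylinder.

    Returns (points, length, direction) where direction is 0 (no contact),
    +1 or -1 (sense of the wrap about ``axis_dir``).  ``prefer_direction``
    breaks near-ties toward the previous frame's wrap sense (hysteresis);
    exact ties default to +1.
    """
    a0 = np.asarray(axis_point, float)
    ad = _unit(np.asarray(axis_dir, float))
    # cylinder frame: e1, e2 transverse, ad axial
    helper = np.array([1.0, 0.0, 0.0])
    if abs(ad @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(helper, ad))
    e2 = np.cross(ad, e1)

    def to_cyl(p):
        rel = np.asarray(p, float) - a0
        return np.array([rel @ e1, rel @ e2, rel @ ad])

    def to_lab(q):
        return a0 + q[0] * e1 + q[1] * e2 + q[2] * ad

    q1, q2 = to_cyl(p1), to_cyl(p2)
    d1 = float(np.hypot(q1[0], q1[1]))
    d2 = float(np.hypot(q2[0], q2[1]))
    if d1 < radius - 1e-12 or d2 < radius - 1e-12:
        raise GeometryError("path endpoint inside the wrapping cylinder")

    # transverse-plane clearance test for the straight segment
    u = q2[:2] - q1[:2]
    uu = float(u @ u)
    t = 0.5 if uu == 0 else float(np.clip(-(q1[:2] @ u) / uu, 0.0, 1.0))
    closest = q1[:2] + t * u
    if np.linalg.norm(closest) >= radius - 1e-12:
        p1a, p2a = np.asarray(p1, float), np.asarray(p2, float)
        return [p1a, p2a], float(np.linalg.norm(p2a - p1a)), 0

    phi1 = float(np.arctan2(q1[1], q1[0]))
    phi2 = float(np.arctan2(q2[1], q2[0]))
    b1 = float(np.arccos(np.clip(radius / d1, -1.0, 1.0)))
    b2 = float(np.arccos(np.clip(radius / d2, -1.0, 1.0)))
    tan1 = float(np.sqrt(d1 * d1 - radius * radius))
    tan2 = float(np.sqrt(d2 * d2 - radius * radius))

    def candidate(s: int):
        psi1 = phi1 + s * b1
        psi2 = phi2 - s * b2
        arc = (s * (psi2 - psi1)) % (2.0 * np.pi)
        l2d = tan1 + radius * arc + tan2
        return psi1, psi2, arc, l2d

    cands = {s: candidate(s) for s in (+1, -1)}
    lp, lm = cands[+1][3], cands[-1][3]
    if abs(lp - lm) < 1e-9 and prefer_direction in (+1, -1):
        s = prefer_direction
    else:
        s = +1 if lp <= lm + 1e-9 else -1
    psi1, psi2, arc, l2d = cands[s]
    dz = q2[2] - q1[2]
    length = float(np.hypot(l2d, dz))

    def z_at(dev: float) -> float:
        return q1[2] + dz * dev / l2d

    pts = [np.asarray(p1, float)]
    n_arc = max(int(n_arc), 2)
    for k in range(n_arc + 1):
        psi = psi1 + s * arc * k / n_arc
        dev = tan1 + radius * arc * k / n_arc
        pts.append(to_lab(np.array([radius * np.cos(psi), radius * np.sin(psi), z_at(dev)])))
    pts.append(np.asarray(p2, float))
    return pts, length, s


def _polyline_length(points: Sequence[np.ndarray]) -> float:
    return float(sum(np.linalg.norm(points[i + 1] - points[i]) for i in range(len(points) - 1)))


def world_path(
    element: MuscleElement,
    poses: Mapping[str, SegmentPose],
    cylinders: Sequence[WrappingCylinder] = (),
    prev_wrap_direction: int = 0,
) -> MusclePathFrame:
    """Lab-frame path, length and per-segment force records for one frame."""
    for seg, _ in element.path:
        if seg not in poses:
            raise GeometryError(f"element {element.id}: missing pose for segment {seg!r}")
    lab_pts = [(seg, poses[seg].apply(p)) for seg, p in element.path]
    cyl = next((c for c in cylinders if element.id in c.wrapped_elements), None)

    # full polyline with exact tangent points; book-keep wrap per sub-segment
    points: List[np.ndarray] = [lab_pts[0][1]]
    # anchor records: (segment, point, [neighbour points])
    neigh: List[List[np.ndarray]] = [[] for _ in lab_pts]
    wrap_records: List[AttachmentRecord] = []
    wrap_engaged = False
    wrap_dir = 0
    total_len = 0.0
    for i in range(len(lab_pts) - 1):
        (_, a), (_, b) = lab_pts[i], lab_pts[i + 1]
        if cyl is not None:
            cp = poses[cyl.segment]
            ax_pt = cp.apply(cyl.axis_point)
            ax_dir = cp.rotation @ cyl.axis_dir
            sub_pts, sub_len, s = cylinder_wrap(a, b, ax_pt, ax_dir, cyl.radius,
                                                prefer_direction=prev_wrap_direction)
        else:
            sub_pts, sub_len, s = [a, b], float(np.linalg.norm(b - a)), 0
        total_len += sub_len
        points.extend(sub_pts[1:])
        if s != 0:
            wrap_engaged = True
            wrap_dir = s
            t1, t2 = sub_pts[1], sub_pts[-2]
            neigh[i].append(t1)
            neigh[i + 1].append(t2)
            wrap_records.append(AttachmentRecord(cyl.segment, t1.copy(), _unit(a - t1)))
            wrap_records.append(AttachmentRecord(cyl.segment, t2.copy(), _unit(b - t2)))
        else:
            neigh[i].append(b)
            neigh[i + 1].append(a)

    records: List[AttachmentRecord] = []
    for (seg, p), nb in zip(lab_pts, neigh):
        direction = np.sum([_unit(q - p) for q in nb], axis=0)
        records.append(AttachmentRecord(seg, p.copy(), direction))
    records.extend(wrap_records)

    return MusclePathFrame(element.id, points, total_len, records,
                           wrap_engaged, wrap_dir)


def path_length(
    element: MuscleElement,
    poses: Mapping[str, SegmentPose],
    cylinders: Sequence[WrappingCylinder] = (),
) -> float:
    return world_path(element, poses, cylinders).length


def compute_geometry(
    anatomy: AnatomyDataset,
    poses: Mapping[str, SegmentPose],
    prev: Optional[Dict[str, int]] = None,
) -> Dict[str, MusclePathFrame]:
    """Paths for every element whose segments are all posed this frame."""
    out: Dict[str, MusclePathFrame] = {}
    prev = prev or {}
    for el in anatomy.muscles:
        if not all(seg in poses for seg, _ in el.path):
            continue
        out[el.id] = world_path(el, poses, anatomy.cylinders,
                                prev_wrap_direction=prev.get(el.id, 0))
    return out
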