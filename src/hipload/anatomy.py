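"""Musculoskeletal anatomical dataset: containers, scaling, strength modification.

The model comprises five rigid segments (pelvis, thigh, patella, shank, foot)
articulated through four joints (hip, tibiofemoral split into medial/lateral
compartments, patellofemoral, ankle).  Muscles are represented as line force
elements (origin, optional via points, insertion); each element's maximum
force potential is its physiological cross-sectional area (PCSA, cm^2) times
a maximum isometric muscle stress sigma_max (N/cm^2).  All positions are in
metres, expressed in the local frame of their host segment.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

SEGMENT_NAMES: Tuple[str, ...] = ("pelvis", "thigh", "patella", "shank", "foot")

#: Segments with a full 6-DOF Newton-Euler equation block in the force-sharing
#: problem (the pelvis has none; its motion is tracked but its dynamics are
#: not constrained).
DYNAMIC_SEGMENTS: Tuple[str, ...] = ("foot", "shank", "thigh", "patella")

MUSCLE_GROUPS: Tuple[str, ...] = (
    "ankle", "knee", "hip_abductor", "hip_adductor", "hip_extensor", "other",
)

#: Documented articular contact point labels and the segment each force is
#: applied to (the reaction acts on the articulating neighbour).
CONTACT_LABELS: Dict[str, Tuple[str, str]] = {
    # label: (applied-to segment, reaction segment)
    "hip": ("thigh", "pelvis"),
    "tf_medial": ("shank", "thigh"),
    "tf_lateral": ("shank", "thigh"),
    "pf": ("patella", "thigh"),
    "ankle": ("foot", "shank"),
}

STANDARD_GRAVITY = 9.81  # m/s^2

#: Maximum isometric muscle stress, N/cm^2.
DEFAULT_SIGMA_MAX = 31.39

#: Default multiplicative reductions of maximum force potential per functional
#: group, accounting for ageing and (for the abductors) hip-replacement
#: surgery: ankle and knee muscles -30%, hip adductors and extensors -25%,
#: hip abductors -50%.
DEFAULT_STRENGTH_MODIFIERS: Dict[str, float] = {
    "ankle": 0.70,
    "knee": 0.70,
    "hip_adductor": 0.75,
    "hip_extensor": 0.75,
    "hip_abductor": 0.50,
}


class AnatomyError(ValueError):
    """Raised when an anatomical dataset violates its invariants."""


def _vec3(x, what: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise AnatomyError(f"{what}: expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise AnatomyError(f"{what}: non-finite coordinates {v}")
    return v


@dataclass
class Subject:
    """Subject metadata.  ``mass`` in kg, ``height`` in m."""

    height: float
    mass: float
    sex: str = "M"
    age: float = 25.0

    @property
    def weight(self) -> float:
        """Body weight in newtons."""
        return self.mass * STANDARD_GRAVITY


@dataclass
class AnatomySegment:
    name: str
    landmarks: Dict[str, np.ndarray] = field(default_factory=dict)
    proximal_jrc: Optional[np.ndarray] = None
    distal_jrc: Optional[np.ndarray] = None
    contact_points: Dict[str, np.ndarray] = field(default_factory=dict)
    marker_labels: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in SEGMENT_NAMES:
            raise AnatomyError(f"unknown segment name {self.name!r}")
        self.landmarks = {k: _vec3(v, f"landmark {k}") for k, v in self.landmarks.items()}
        self.contact_points = {
            k: _vec3(v, f"contact point {k}") for k, v in self.contact_points.items()
        }
        for lbl in self.contact_points:
            if lbl not in CONTACT_LABELS:
                raise AnatomyError(
                    f"segment {self.name}: contact label {lbl!r} not in the "
                    f"documented set {sorted(CONTACT_LABELS)}"
                )
        if self.proximal_jrc is not None:
            self.proximal_jrc = _vec3(self.proximal_jrc, f"{self.name} proximal_jrc")
        if self.distal_jrc is not None:
            self.distal_jrc = _vec3(self.distal_jrc, f"{self.name} distal_jrc")
        self.marker_labels = tuple(self.marker_labels)


@dataclass
class MuscleElement:
    """A straight-line force element of a muscle (or a tensile ligament).

    ``path`` is an ordered list of (segment name, local position) pairs from
    origin to insertion; interior entries are frictionless via points.
    ``role`` is ``"muscle"`` (enters the muscle-stress objective) or
    ``"ligament"`` (tensile element with a large bound, excluded from it).
    """

    id: str
    muscle: str
    path: List[Tuple[str, np.ndarray]]
    pcsa: Optional[float] = None
    fmax: Optional[float] = None
    group: str = "other"
    role: str = "muscle"

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise AnatomyError(f"element {self.id}: path needs >= 2 points")
        self.path = [(seg, _vec3(p, f"element {self.id} path point")) for seg, p in self.path]
        for seg, _ in self.path:
            if seg not in SEGMENT_NAMES:
                raise AnatomyError(f"element {self.id}: unknown segment {seg!r}")
        if self.path[0][0] == self.path[-1][0]:
            raise AnatomyError(
                f"element {self.id}: origin and insertion on the same segment"
            )
        if self.group not in MUSCLE_GROUPS:
            raise AnatomyError(f"element {self.id}: unknown group {self.group!r}")
        if self.role not in ("muscle", "ligament"):
            raise AnatomyError(f"element {self.id}: unknown role {self.role!r}")
        if self.role == "muscle":
            if self.pcsa is None or not self.pcsa > 0:
                raise AnatomyError(f"element {self.id}: pcsa must be > 0, got {self.pcsa}")
        if self.fmax is not None and not self.fmax > 0:
            raise AnatomyError(f"element {self.id}: fmax must be > 0, got {self.fmax}")


@dataclass
class WrappingCylinder:
    """Cylindrical wrapping surface fixed to one segment."""

    id: str
    segment: str
    axis_point: np.ndarray
    axis_dir: np.ndarray
    radius: float
    wrapped_elements: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.segment not in SEGMENT_NAMES:
            raise AnatomyError(f"cylinder {self.id}: unknown segment {self.segment!r}")
        self.axis_point = _vec3(self.axis_point, f"cylinder {self.id} axis_point")
        self.axis_dir = _vec3(self.axis_dir, f"cylinder {self.id} axis_dir")
        n = float(np.linalg.norm(self.axis_dir))
        if abs(n - 1.0) > 1e-9:
            raise AnatomyError(f"cylinder {self.id}: axis_dir must be unit, |d| = {n}")
        if not self.radius > 0:
            raise AnatomyError(f"cylinder {self.id}: radius must be > 0")
        self.wrapped_elements = tuple(self.wrapped_elements)


@dataclass
class AnatomyDataset:
    subject: Subject
    segments: Dict[str, AnatomySegment]
    muscles: List[MuscleElement]
    cylinders: List[WrappingCylinder] = field(default_factory=list)
    sigma_max: float = DEFAULT_SIGMA_MAX

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, seg in self.segments.items():
            if name != seg.name:
                raise AnatomyError(f"segment keyed {name!r} is named {seg.name!r}")
        ids = [m.id for m in self.muscles]
        if len(ids) != len(set(ids)):
            raise AnatomyError("duplicate muscle element ids")
        for m in self.muscles:
            for seg, _ in m.path:
                if seg not in self.segments:
                    raise AnatomyError(
                        f"element {m.id}: path references missing segment {seg!r}"
                    )
        for c in self.cylinders:
            if c.segment not in self.segments:
                raise AnatomyError(f"cylinder {c.id}: missing segment {c.segment!r}")
            for eid in c.wrapped_elements:
                if eid not in ids:
                    raise AnatomyError(f"cylinder {c.id}: unknown element {eid!r}")
        if not self.sigma_max > 0:
            raise AnatomyError("sigma_max must be > 0")

    def element(self, eid: str) -> MuscleElement:
        for m in self.muscles:
            if m.id == eid:
                return m
        raise KeyError(eid)

    def copy(self) -> "AnatomyDataset":
        return copy.deepcopy(self)


@dataclass
class ScaleFactors:
    """Per-segment scale factors; scalar (isotropic) or 3-vector."""

    factors: Dict[str, Union[float, np.ndarray]]

    def __post_init__(self) -> None:
        out: Dict[str, Union[float, np.ndarray]] = {}
        for seg, f in self.factors.items():
            if seg not in SEGMENT_NAMES:
                raise AnatomyError(f"scale factor for unknown segment {seg!r}")
            arr = np.asarray(f, dtype=float)
            if arr.ndim == 0:
                if not arr > 0:
                    raise AnatomyError(f"scale factor for {seg} must be > 0")
                out[seg] = float(arr)
            else:
                v = _vec3(arr, f"scale factor {seg}")
                if not np.all(v > 0):
                    raise AnatomyError(f"scale factors for {seg} must be > 0")
                out[seg] = v
        self.factors = out

    def vector(self, seg: str) -> np.ndarray:
        f = self.factors[seg]
        return np.full(3, f) if np.isscalar(f) else np.asarray(f)

    def radial(self, seg: str) -> float:
        """Scalar factor applied to cylinder radii (geometric mean)."""
        return float(np.prod(self.vector(seg)) ** (1.0 / 3.0))


def compute_max_forces(dataset: AnatomyDataset) -> AnatomyDataset:
    """Set each muscle element's maximum force potential to sigma_max * PCSA.

    Ligament elements (no PCSA) are left untouched.
    """
    out = dataset.copy()
    for m in out.muscles:
        if m.role != "muscle":
            continue
        if m.pcsa is None or not m.pcsa > 0:
            raise AnatomyError(f"element {m.id}: pcsa must be > 0 to compute fmax")
        m.fmax = out.sigma_max * m.pcsa
    return out


def scale_factors_from_lengths(
    subject_lengths: Mapping[str, float],
    reference_lengths: Mapping[str, float],
) -> ScaleFactors:
    """Isotropic per-segment factors: subject length / reference length.

    The pelvis "length" is the inter-hip-centre distance on both sides of the
    ratio.  The patella inherits the thigh factor when not given explicitly
    (it is anatomically coupled to the femur and the quadriceps path).
    """
    factors: Dict[str, Union[float, np.ndarray]] = {}
    for seg in SEGMENT_NAMES:
        if seg == "patella" and seg not in subject_lengths:
            continue
        if seg not in subject_lengths or seg not in reference_lengths:
            raise AnatomyError(f"missing length for segment {seg!r}")
        s, r = float(subject_lengths[seg]), float(reference_lengths[seg])
        if not (s > 0 and r > 0):
            raise AnatomyError(f"non-positive length for segment {seg!r}")
        factors[seg] = s / r
    if "patella" not in factors:
        factors["patella"] = factors["thigh"]
    return ScaleFactors(factors)


def apply_scaling(dataset: AnatomyDataset, factors: ScaleFactors) -> AnatomyDataset:
    """Multiply every segment-local position by its host segment's factor.

    Affects landmarks, joint rotation centres, contact points, muscle path
    points and cylinder axis points; cylinder radii scale with the host
    segment's (radial) factor.  PCSA, fmax and sigma_max are unchanged.
    """
    for seg in SEGMENT_NAMES:
        if seg in dataset.segments and seg not in factors.factors:
            raise AnatomyError(f"no scale factor for segment {seg!r}")
    out = dataset.copy()
    for name, seg in out.segments.items():
        f = factors.vector(name)
        seg.landmarks = {k: v * f for k, v in seg.landmarks.items()}
        seg.contact_points = {k: v * f for k, v in seg.contact_points.items()}
        if seg.proximal_jrc is not None:
            seg.proximal_jrc = seg.proximal_jrc * f
        if seg.distal_jrc is not None:
            seg.distal_jrc = seg.distal_jrc * f
    for m in out.muscles:
        m.path = [(s, p * factors.vector(s)) for s, p in m.path]
    for c in out.cylinders:
        c.axis_point = c.axis_point * factors.vector(c.segment)
        d = c.axis_dir * factors.vector(c.segment)
        c.axis_dir = d / np.linalg.norm(d)
        c.radius = c.radius * factors.radial(c.segment)
    return out


def apply_strength_modifiers(
    dataset: AnatomyDataset,
    table: Optional[Mapping[str, float]] = None,
) -> AnatomyDataset:
    """Multiply fmax by the group's factor; unlisted groups are unchanged."""
    if table is None:
        table = DEFAULT_STRENGTH_MODIFIERS
    for g, f in table.items():
        if g not in MUSCLE_GROUPS:
            raise AnatomyError(f"strength modifier for unknown group {g!r}")
        if not (0.0 < f <= 1.0):
            raise AnatomyError(f"strength modifier for {g!r} must be in (0, 1], got {f}")
    out = dataset.copy()
    for m in out.muscles:
        if m.role != "muscle" or m.group not in table:
            continue
        if m.fmax is None:
            raise AnatomyError(f"element {m.id}: fmax unset; run compute_max_forces first")
        m.fmax = m.fmax * table[m.group]
    return out


def segment_lengths(dataset: AnatomyDataset) -> Dict[str, float]:
    """Characteristic length per segment, used for scaling and inertia.

    thigh/shank: proximal-to-distal JRC distance; foot: proximal JRC to the
    ``toe`` landmark; pelvis: inter-hip-centre distance (distal JRC to the
    ``hip_contra`` landmark when present, else twice the distal JRC offset);
    patella: span of its landmarks (fallback 0.04 m).
    """
    out: Dict[str, float] = {}
    for name, seg in dataset.segments.items():
        if name in ("thigh", "shank") and seg.proximal_jrc is not None and seg.distal_jrc is not None:
            out[name] = float(np.linalg.norm(seg.distal_jrc - seg.proximal_jrc))
        elif name == "foot" and seg.proximal_jrc is not None and "toe" in seg.landmarks:
            out[name] = float(np.linalg.norm(seg.landmarks["toe"] - seg.proximal_jrc))
        elif name == "pelvis" and seg.distal_jrc is not None:
            if "hip_contra" in seg.landmarks:
                out[name] = float(np.linalg.norm(seg.landmarks["hip_contra"] - seg.distal_jrc))
            else:
                out[name] = 2.0 * float(np.linalg.norm(seg.distal_jrc))
        elif name == "patella":
            pts = list(seg.landmarks.values())
            if len(pts) >= 2:
                arr = np.asarray(pts)
                out[name] = float(np.max(np.linalg.norm(arr[:, None] - arr[None, :], axis=-1)))
            else:
                out[name] = 0.04
        else:
            raise AnatomyError(f"cannot derive a length for segment {name!r}")
    return out
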