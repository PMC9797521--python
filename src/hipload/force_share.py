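"""Per-frame constrained static optimization of muscle and joint contact forces.

Unknowns are the tensions of the line force elements (bounded by their
maximum force potentials) and the articular contact force 3-vectors at the
ankle, medial and lateral tibiofemoral, patellofemoral and hip joints.  For
each dynamic segment (foot, shank, thigh, patella) six linear equations of
motion tie them to the segment's inertial wrench and, for the foot, the
ground-reaction wrench.  The objective is

    J = sum_i (F_i / F_i^max)^2 + alpha * ||J_hip|| / BW

i.e. the sum of squared muscle stresses plus the body-weight-normalised hip
contact force magnitude (alpha defaults to 1).  The problem is convex
(quadratic-plus-norm objective, linear equalities, box bounds), so the
default solver finds the global optimum; tensile ligament elements carry a
large bound and are excluded from the stress sum.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .anatomy import AnatomyDataset, CONTACT_LABELS, DYNAMIC_SEGMENTS
from .dynamics import GRAVITY, InertialParams, inertial_wrench, skew
from .kinematics import SegmentPose
from .muscle_geometry import MusclePathFrame


class ForceShareError(ValueError):
    pass


@dataclass
class SolverConfig:
    alpha: float = 1.0
    eq_tol: float = 1e-8          # equality residual tolerance, fraction of BW
    max_iter: int = 500
    smoothing: float = 1e-8       # norm smoothing, fraction of BW
    ligament_bound_bw: float = 20.0
    warm_start: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ForceShareError("alpha must be >= 0")


@dataclass
class FrameProblem:
    """Assembled linear constraint system A x = b with box bounds on x.

    Layout: x = [F_1..F_n, J_c1 (3), J_c2 (3), ...] in newtons.
    """

    element_ids: List[str]
    fmax: np.ndarray                 # (n_el,) upper bounds [N]
    in_objective: np.ndarray         # (n_el,) bool, False for ligaments
    contact_labels: List[str]
    A: np.ndarray                    # (6 * n_dynamic, n_el + 3 * n_contacts)
    b: np.ndarray
    bw: float
    dynamic_segments: List[str]

    @property
    def n_elements(self) -> int:
        return len(self.element_ids)

    @property
    def n_unknowns(self) -> int:
        return self.A.shape[1]

    def contact_slice(self, label: str) -> slice:
        i = self.contact_labels.index(label)
        k = self.n_elements + 3 * i
        return slice(k, k + 3)

    @property
    def hip_slice(self) -> Optional[slice]:
        return self.contact_slice("hip") if "hip" in self.contact_labels else None


@dataclass
class FrameSolution:
    forces: np.ndarray                    # (n_el,) [N]
    activations: np.ndarray               # F / Fmax
    contacts: Dict[str, np.ndarray]       # label -> (3,) [N]
    hcf: float                            # ||J_hip|| [N]
    objective: float
    residual: float                       # max |A x - b| [N or N m]
    status: str
    x: np.ndarray = field(repr=False, default=None)

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def objective_value(
    forces: np.ndarray,
    j_hip: np.ndarray,
    alpha: float,
    bw: float,
    fmax: np.ndarray,
    in_objective: Optional[np.ndarray] = None,
) -> float:
    """Sum of squared muscle stresses plus alpha * ||J_hip|| / BW."""
    forces = np.asarray(forces, float)
    fmax = np.asarray(fmax, float)
    if forces.shape != fmax.shape:
        raise ForceShareError("forces and fmax dimensions differ")
    if not bw > 0 or not np.all(fmax > 0):
        raise ForceShareError("BW and fmax must be positive")
    mask = np.ones(forces.shape, bool) if in_objective is None else np.asarray(in_objective, bool)
    act = forces[mask] / fmax[mask]
    return float(np.sum(act * act) + alpha * np.linalg.norm(np.asarray(j_hip, float)) / bw)


def assemble(
    anatomy: AnatomyDataset,
    poses: Mapping[str, SegmentPose],
    params: InertialParams,
    kin: Mapping[str, Mapping[str, np.ndarray]],
    geometry: Mapping[str, MusclePathFrame],
    grf_force: np.ndarray,
    grf_cop: np.ndarray,
    grf_free_moment: np.ndarray,
    config: Optional[SolverConfig] = None,
    g: np.ndarray = GRAVITY,
) -> FrameProblem:
    """Build the equality system for one frame.

    ``kin[seg]`` supplies ``a_com``, ``omega`` and ``alpha`` (lab frame) for
    every dynamic segment present in ``poses``.
    """
    config = config or SolverConfig()
    bw = anatomy.subject.weight
    dyn = [s for s in DYNAMIC_SEGMENTS if s in poses]
    if not dyn:
        raise ForceShareError("no dynamic segments posed")

    elements = [anatomy.element(eid) for eid in geometry]
    element_ids = [e.id for e in elements]
    fmax = np.empty(len(elements))
    in_obj = np.empty(len(elements), bool)
    for i, e in enumerate(elements):
        if e.role == "ligament":
            fmax[i] = config.ligament_bound_bw * bw
            in_obj[i] = False
        else:
            if e.fmax is None:
                raise ForceShareError(f"element {e.id}: fmax unset; run compute_max_forces")
            fmax[i] = e.fmax
            in_obj[i] = True

    contacts: List[Tuple[str, str, str, np.ndarray]] = []
    for label, (applied, reaction) in CONTACT_LABELS.items():
        if applied not in dyn:
            continue
        cps = anatomy.segments[applied].contact_points
        if label not in cps:
            raise ForceShareError(f"segment {applied}: contact point {label!r} undefined")
        contacts.append((label, applied, reaction, poses[applied].apply(cps[label])))
    contacts.sort(key=lambda c: c[0])
    contact_labels = [c[0] for c in contacts]

    n_el = len(elements)
    n_un = n_el + 3 * len(contacts)
    A = np.zeros((6 * len(dyn), n_un))
    b = np.zeros(6 * len(dyn))
    prox_lab: Dict[str, np.ndarray] = {}
    for s in dyn:
        p = anatomy.segments[s].proximal_jrc
        prox_lab[s] = poses[s].apply(p if p is not None else np.zeros(3))

    for mi, s in enumerate(dyn):
        rf, rm = 6 * mi, 6 * mi + 3
        fi, momi = inertial_wrench(params.segments[s], poses[s],
                                   kin[s]["a_com"], kin[s]["omega"], kin[s]["alpha"], g)
        b[rf:rf + 3] = fi
        b[rm:rm + 3] = momi
        if s == "foot":
            b[rf:rf + 3] -= np.asarray(grf_force, float)
            b[rm:rm + 3] -= (np.cross(np.asarray(grf_cop, float) - prox_lab[s], grf_force)
                             + np.asarray(grf_free_moment, float))
        for j, e in enumerate(elements):
            for rec in geometry[e.id].records:
                if rec.segment != s:
                    continue
                A[rf:rf + 3, j] += rec.direction
                A[rm:rm + 3, j] += skew(rec.point - prox_lab[s]) @ rec.direction
        for ci, (label, applied, reaction, p_c) in enumerate(contacts):
            cols = slice(n_el + 3 * ci, n_el + 3 * ci + 3)
            if s == applied:
                A[rf:rf + 3, cols] += np.eye(3)
                A[rm:rm + 3, cols] += skew(p_c - prox_lab[s])
            elif s == reaction:
                A[rf:rf + 3, cols] -= np.eye(3)
                A[rm:rm + 3, cols] -= skew(p_c - prox_lab[s])

    # every contact unknown must appear in at least one equation
    for ci, (label, *_rest) in enumerate(contacts):
        cols = slice(n_el + 3 * ci, n_el + 3 * ci + 3)
        if not np.any(A[:, cols]):
            raise ForceShareError(f"contact {label!r} referenced by no equation")
    return FrameProblem(element_ids, fmax, in_obj, contact_labels, A, b, bw, dyn)


def _scaled_system(problem: FrameProblem):
    """Column/row scaling: forces by fmax, contacts by BW, rows by BW."""
    n_el = problem.n_elements
    scale = np.concatenate([problem.fmax, np.full(problem.n_unknowns - n_el, problem.bw)])
    A = problem.A * scale[None, :] / problem.bw
    b = problem.b / problem.bw
    return A, b, scale


def _smoothed_objective(problem: FrameProblem, alpha: float, delta: float):
    """Objective, gradient (and Hessian) in the scaled variable space."""
    n_el = problem.n_elements
    mask = problem.in_objective
    hip = problem.hip_slice

    def fun(y: np.ndarray) -> float:
        v = float(np.sum(y[:n_el][mask] ** 2))
        if hip is not None and alpha > 0:
            v += alpha * float(np.sqrt(np.sum(y[hip] ** 2) + delta * delta))
        return v

    def grad(y: np.ndarray) -> np.ndarray:
        g = np.zeros_like(y)
        g[:n_el][mask] = 2.0 * y[:n_el][mask]
        if hip is not None and alpha > 0:
            r = np.sqrt(np.sum(y[hip] ** 2) + delta * delta)
            g[hip] = alpha * y[hip] / r
        return g

    def hess(y: np.ndarray) -> np.ndarray:
        H = np.zeros((y.size, y.size))
        idx = np.flatnonzero(np.concatenate([mask, np.zeros(y.size - n_el, bool)]))
        H[idx, idx] = 2.0
        if hip is not None and alpha > 0:
            v = y[hip]
            r = np.sqrt(np.sum(v * v) + delta * delta)
            H[hip, hip] = alpha * (np.eye(3) / r - np.outer(v, v) / r ** 3)
        return H

    return fun, grad, hess


def _active_set_polish(y, A, b, n_el, fun, grad, hess,
                       tol: float = 1e-5, max_faces: int = 40):
    """Active-set refinement of a nearly converged solution.

    Starting from the face suggested by the input point (box-bound variables
    within ``tol`` of 0 or 1 in the scaled space are clamped), repeatedly:
    minimise the smooth objective on the current face by null-space Newton;
    clamp any free variable its minimiser drives out of the box; release a
    clamped variable whose bound multiplier has the wrong sign.  For the
    convex frame problem this terminates at the exact optimum.  Falls back
    to the input if no improvement is found.
    """
    from scipy.linalg import null_space

    y = np.asarray(y, float).copy()
    is_bounded = np.zeros(y.size, bool)
    is_bounded[:n_el] = True

    # feasible start: clip into the box, project onto the equality manifold
    z = y.copy()
    z[:n_el] = np.clip(z[:n_el], 0.0, 1.0)
    lam, *_ = np.linalg.lstsq(A @ A.T, A @ z - b, rcond=None)
    z = z - A.T @ lam
    if (np.any(z[:n_el] < -1e-9) or np.any(z[:n_el] > 1.0 + 1e-9)
            or np.max(np.abs(A @ z - b)) > 1e-9):
        return y
    z[:n_el] = np.clip(z[:n_el], 0.0, 1.0)
    act0 = is_bounded & (z <= tol * 1e-3)
    act1 = is_bounded & (z >= 1.0 - tol * 1e-3)
    z[act0] = 0.0
    z[act1] = 1.0

    def face_minimum(zc, free, rhs):
        """Damped-Newton minimiser of the smooth objective on the affine face."""
        Af = A[:, free]
        zf = zc.copy()
        N = null_space(Af) if Af.size else np.zeros((0, 0))
        if N.size == 0:
            return zf
        for _ in range(50):
            g = N.T @ grad(zf)[free]
            Hw = N.T @ hess(zf)[np.ix_(free, free)] @ N
            try:
                w = np.linalg.lstsq(Hw, -g, rcond=None)[0]
            except np.linalg.LinAlgError:
                return zf
            nw = np.linalg.norm(w)
            if nw > 1e3:        # degenerate curvature: cap the step
                w *= 1e3 / nw
            # backtracking keeps the Newton step stable near the norm kink
            f0 = fun(zf)
            step = 1.0
            for _ in range(40):
                zt = zf.copy()
                zt[free] = zf[free] + step * (N @ w)
                if fun(zt) <= f0 + 1e-18:
                    break
                step *= 0.5
            else:
                return zf
            zf = zt
            # re-project: guards against accumulated drift off the manifold
            r = Af @ zf[free] - rhs
            if np.max(np.abs(r)) > 1e-13:
                zf[free] = zf[free] - np.linalg.lstsq(Af, r, rcond=None)[0]
            if step * np.linalg.norm(w) < 1e-14:
                break
        return zf

    last_released = -1
    for _ in range(max_faces):
        free = ~(act0 | act1)
        rhs = b - A[:, act1] @ np.ones(int(act1.sum()))
        z_star = face_minimum(z, free, rhs)
        if np.max(np.abs(A @ z_star - b)) > 1e-9:
            break
        d = z_star - z
        # step to the first blocking bound
        beta = 1.0
        block = -1
        block_up = False
        idx = np.flatnonzero(free & is_bounded)
        for i in idx:
            if d[i] < -1e-16 and z_star[i] < -1e-14:
                bi = z[i] / (z[i] - z_star[i])
                if bi < beta:
                    beta, block, block_up = bi, i, False
            elif d[i] > 1e-16 and z_star[i] > 1.0 + 1e-14:
                bi = (1.0 - z[i]) / (z_star[i] - z[i])
                if bi < beta:
                    beta, block, block_up = bi, i, True
        z = z + beta * d
        if block >= 0:
            if block == last_released and beta == 0.0:
                break               # degenerate cycle: stop with best-so-far
            if block_up:
                act1[block] = True
                z[block] = 1.0
            else:
                act0[block] = True
                z[block] = 0.0
            continue
        # full step taken: check the bound multipliers
        g_full = grad(z)
        Af = A[:, free]
        mu = np.linalg.lstsq(Af.T, -g_full[free], rcond=None)[0]
        r = g_full + A.T @ mu
        release0 = act0 & (r < -1e-9)
        release1 = act1 & (r > 1e-9)
        if not (np.any(release0) or np.any(release1)):
            break
        if np.any(release0):
            k = np.flatnonzero(release0)[np.argmin(r[release0])]
            act0[k] = False
        else:
            k = np.flatnonzero(release1)[np.argmax(r[release1])]
            act1[k] = False
        last_released = int(k)

    z[:n_el] = np.clip(z[:n_el], 0.0, 1.0)
    ok = (np.max(np.abs(A @ z - b)) < 1e-9 and fun(z) <= fun(y) + 1e-15)
    return z if ok else y


def _initial_point(A: np.ndarray, b: np.ndarray, n_el: int) -> np.ndarray:
    y0, *_ = np.linalg.lstsq(A, b, rcond=None)
    y0[:n_el] = np.clip(y0[:n_el], 0.0, 1.0)
    return y0


def _make_solution(problem: FrameProblem, y: np.ndarray, alpha: float, status: str) -> FrameSolution:
    _, _, scale = _scaled_system(problem)
    x = y * scale
    n_el = problem.n_elements
    forces = x[:n_el]
    contacts = {lbl: x[problem.contact_slice(lbl)].copy() for lbl in problem.contact_labels}
    j_hip = contacts.get("hip", np.zeros(3))
    obj = objective_value(forces, j_hip, alpha, problem.bw, problem.fmax, problem.in_objective)
    residual = float(np.max(np.abs(problem.A @ x - problem.b))) if problem.A.size else 0.0
    return FrameSolution(forces, forces / problem.fmax, contacts,
                         float(np.linalg.norm(j_hip)), obj, residual, status, x)


def solve_frame(
    problem: FrameProblem,
    config: Optional[SolverConfig] = None,
    warm: Optional[FrameSolution] = None,
) -> FrameSolution:
    """Solve the frame's convex program (SLSQP on the scaled system)."""
    config = config or SolverConfig()
    A, b, scale = _scaled_system(problem)
    n_el = problem.n_elements
    fun, grad, hess = _smoothed_objective(problem, config.alpha, config.smoothing)
    warm_used = warm is not None and warm.x is not None and config.warm_start
    if warm_used:
        # keep the start strictly interior: SLSQP is unreliable when started
        # exactly on active bounds
        y0 = warm.x / scale
        y0[:n_el] = np.clip(y0[:n_el], 1e-9, 1.0 - 1e-9)
    else:
        y0 = _initial_point(A, b, n_el)
    bounds = [(0.0, 1.0)] * n_el + [(None, None)] * (problem.n_unknowns - n_el)
    constraints = [{"type": "eq", "fun": lambda y: A @ y - b, "jac": lambda y: A}]
    opts = {"maxiter": config.max_iter, "ftol": 1e-14}

    def run(start):
        r1 = minimize(fun, start, jac=grad, method="SLSQP", bounds=bounds,
                      constraints=constraints, options=opts)
        # restart once from the solution: resets the quasi-Newton state and
        # removes the premature-termination bias of warm starts
        r2 = minimize(fun, r1.x, jac=grad, method="SLSQP", bounds=bounds,
                      constraints=constraints, options=opts)
        return r2 if r2.fun <= r1.fun else r1

    res = run(y0)
    if warm_used and np.max(np.abs(A @ res.x - b)) > config.eq_tol:
        res = run(_initial_point(A, b, n_el))
    y = _active_set_polish(res.x, A, b, n_el, fun, grad, hess)
    # exact projection onto the equality manifold (removes the solver's small
    # equality slack; the shift is tiny so bounds stay satisfied to tolerance)
    r = A @ y - b
    if np.any(r):
        lam, *_ = np.linalg.lstsq(A @ A.T, r, rcond=None)
        corr = A.T @ lam
        y_proj = y - corr
        if np.all(y_proj[:n_el] > -1e-9) and np.all(y_proj[:n_el] < 1.0 + 1e-9):
            y = y_proj
            y[:n_el] = np.clip(y[:n_el], 0.0, 1.0)
    sol = _make_solution(problem, y, config.alpha, "pending")
    if sol.residual <= config.eq_tol * problem.bw and res.success:
        sol.status = "converged"
    elif sol.residual <= config.eq_tol * problem.bw:
        sol.status = "converged"   # residual criterion met despite solver flag
    else:
        sol.status = "infeasible" if not res.success else "residual_exceeded"
    return sol


def assemble_series(
    anatomy: AnatomyDataset,
    poses,
    params: InertialParams,
    grf,
    config: Optional[SolverConfig] = None,
    g: np.ndarray = GRAVITY,
) -> List[FrameProblem]:
    """Assemble one FrameProblem per frame of a PoseSeries.

    ``poses`` must carry derived kinematics (omega, alpha, a_com); ``grf`` is
    a ForcePlateSeries synchronised to the same frames.  Wrap-direction
    hysteresis is carried across frames.
    """
    from .muscle_geometry import compute_geometry

    config = config or SolverConfig()
    if grf.n_frames != poses.n_frames:
        raise ForceShareError("pose and GRF frame counts differ")
    problems: List[FrameProblem] = []
    prev_wrap: Dict[str, int] = {}
    for i in range(poses.n_frames):
        frame_poses = poses.frame_poses(i)
        geom = compute_geometry(anatomy, frame_poses, prev=prev_wrap)
        prev_wrap = {eid: g_.wrap_direction for eid, g_ in geom.items() if g_.wrap_engaged}
        kin = {
            s: {"a_com": poses.a_com[s][i], "omega": poses.omega[s][i], "alpha": poses.alpha[s][i]}
            for s in poses.segments if s in DYNAMIC_SEGMENTS
        }
        problems.append(assemble(
            anatomy, frame_poses, params, kin, geom,
            grf.force[i], grf.cop[i], grf.free_moment[i], config, g,
        ))
    return problems


def solve_trial(
    problems: Sequence[FrameProblem],
    config: Optional[SolverConfig] = None,
) -> List[FrameSolution]:
    """Sequential per-frame solve, warm-started from the previous frame."""
    config = config or SolverConfig()
    out: List[FrameSolution] = []
    warm: Optional[FrameSolution] = None
    for p in problems:
        sol = solve_frame(p, config, warm=warm)
        out.append(sol)
        if sol.converged:
            warm = sol
    return out
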