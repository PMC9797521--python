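"""File formats, configuration and the end-to-end pipeline.

TSV dialect: tab-separated, ``.`` decimal, UTF-8, one header row, units in a
leading ``# units:`` comment line.  Marker files carry a ``time`` column plus
``<label>_x|_y|_z`` columns in metres, lab frame, +Z up.  Force-plate files
carry ``time, fx, fy, fz, copx, copy, copz, mx, my, mz`` (N, m, N m).

The anatomy file is JSON (schema version 1) with units stated in-file:
metres for positions, cm^2 for PCSA, N for forces, N/cm^2 for the maximum
muscle stress.  A C3D adapter is available when the optional ``ezc3d``
dependency is installed; the TSV path has no extra dependencies.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import anatomy as _anatomy
from .anatomy import (
    AnatomyDataset,
    AnatomySegment,
    MuscleElement,
    ScaleFactors,
    Subject,
    WrappingCylinder,
    apply_scaling,
    scale_factors_from_lengths,
    segment_lengths,
)
from .dynamics import params_from_anatomy
from .force_share import FrameSolution, SolverConfig, assemble_series, solve_trial
from .kinematics import (
    CalibrationResult,
    ForcePlateSeries,
    MarkerTrial,
    PoseSeries,
    calibrate,
    differentiate,
    inverse_kinematics,
    lowpass_filter,
)
from .metrics import Waveform, metrics_report, normalize_cycle
from scipy.spatial.transform import Rotation

ACTIVITY_TAGS = ("WN", "WS", "WF", "SU", "SD", "CU", "CD")

ANATOMY_SCHEMA_VERSION = 1


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# TSV dialect

def _write_tsv(path, df: pd.DataFrame, units: str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g", lineterminator="\n")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_marker_tsv(path, trial: MarkerTrial) -> None:
    cols = {"time": trial.time}
    for lbl in sorted(trial.markers):
        for i, ax in enumerate("xyz"):
            cols[f"{lbl}_{ax}"] = trial.markers[lbl][:, i]
    _write_tsv(path, pd.DataFrame(cols), "s m")


def read_marker_tsv(path, rate: Optional[float] = None) -> MarkerTrial:
    df = _read_tsv(path)
    if "time" not in df.columns:
        raise IOError_(f"{path}: no 'time' column")
    time = df["time"].to_numpy(float)
    if rate is None:
        if time.size < 2:
            raise IOError_(f"{path}: cannot infer rate from a single frame")
        rate = 1.0 / float(np.median(np.diff(time)))
    labels = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
    markers = {}
    for lbl in labels:
        try:
            markers[lbl] = df[[f"{lbl}_x", f"{lbl}_y", f"{lbl}_z"]].to_numpy(float)
        except KeyError as e:
            raise IOError_(f"{path}: incomplete coordinate triplet for {lbl!r}") from e
    valid = {lbl: np.all(np.isfinite(markers[lbl]), axis=1) for lbl in markers}
    return MarkerTrial(rate, time, markers, valid)


def write_grf_tsv(path, time: np.ndarray, grf: ForcePlateSeries) -> None:
    df = pd.DataFrame({
        "time": time,
        "fx": grf.force[:, 0], "fy": grf.force[:, 1], "fz": grf.force[:, 2],
        "copx": grf.cop[:, 0], "copy": grf.cop[:, 1], "copz": grf.cop[:, 2],
        "mx": grf.free_moment[:, 0], "my": grf.free_moment[:, 1], "mz": grf.free_moment[:, 2],
    })
    _write_tsv(path, df, "s N m N.m")


def read_grf_tsv(path) -> Tuple[np.ndarray, ForcePlateSeries]:
    df = _read_tsv(path)
    need = ["time", "fx", "fy", "fz", "copx", "copy", "copz", "mx", "my", "mz"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    return df["time"].to_numpy(float), ForcePlateSeries(
        df[["fx", "fy", "fz"]].to_numpy(float),
        df[["copx", "copy", "copz"]].to_numpy(float),
        df[["mx", "my", "mz"]].to_numpy(float),
    )


def write_pose_tsv(path, poses: PoseSeries) -> None:
    cols = {"time": poses.time}
    for seg in poses.segments:
        rv = Rotation.from_matrix(poses.rotations[seg]).as_rotvec()
        for i, ax in enumerate("xyz"):
            cols[f"{seg}_r{ax}"] = rv[:, i]
        for i, ax in enumerate("xyz"):
            cols[f"{seg}_t{ax}"] = poses.translations[seg][:, i]
    cols["rmse"] = poses.rmse
    _write_tsv(path, pd.DataFrame(cols), "s rad m")


def read_pose_tsv(path) -> PoseSeries:
    df = _read_tsv(path)
    time = df["time"].to_numpy(float)
    if time.size < 2:
        raise IOError_(f"{path}: need at least 2 frames")
    rate = 1.0 / float(np.median(np.diff(time)))
    segs = sorted({c[:-3] for c in df.columns if c.endswith(("_rx", "_ry", "_rz"))})
    rotations, translations = {}, {}
    for seg in segs:
        rv = df[[f"{seg}_rx", f"{seg}_ry", f"{seg}_rz"]].to_numpy(float)
        rotations[seg] = Rotation.from_rotvec(rv).as_matrix()
        translations[seg] = df[[f"{seg}_tx", f"{seg}_ty", f"{seg}_tz"]].to_numpy(float)
    rmse = df["rmse"].to_numpy(float) if "rmse" in df.columns else np.zeros(time.size)
    return PoseSeries(time, rate, rotations, translations, rmse)


def write_solution_tsv(path, time: np.ndarray, solutions: Sequence[FrameSolution],
                       element_ids: Sequence[str], bw: float) -> None:
    cols: Dict[str, object] = {"time": time}
    F = np.array([s.forces for s in solutions])
    for j, eid in enumerate(element_ids):
        cols[f"{eid}_force"] = F[:, j]
    labels = sorted(solutions[0].contacts)
    for lbl in labels:
        J = np.array([s.contacts[lbl] for s in solutions])
        for i, ax in enumerate("xyz"):
            cols[f"{lbl}_f{ax}"] = J[:, i]
    cols["hcf_bw"] = np.array([s.hcf / bw * 100.0 for s in solutions])
    cols["objective"] = np.array([s.objective for s in solutions])
    cols["residual"] = np.array([s.residual for s in solutions])
    cols["status"] = [s.status for s in solutions]
    _write_tsv(path, pd.DataFrame(cols), "s N %BW")


def write_activation_tsv(path, time: np.ndarray, solutions: Sequence[FrameSolution],
                         element_ids: Sequence[str]) -> None:
    cols: Dict[str, object] = {"time": time}
    A = np.array([s.activations for s in solutions])
    for j, eid in enumerate(element_ids):
        cols[eid] = A[:, j]
    _write_tsv(path, pd.DataFrame(cols), "s dimensionless")


# ---------------------------------------------------------------------------
# anatomy JSON

def anatomy_to_dict(ds: AnatomyDataset) -> dict:
    return {
        "format": "hipload-anatomy",
        "version": ANATOMY_SCHEMA_VERSION,
        "units": {"length": "m", "area": "cm^2", "force": "N", "stress": "N/cm^2"},
        "subject": asdict(ds.subject),
        "sigma_max": ds.sigma_max,
        "segments": {
            name: {
                "landmarks": {k: v.tolist() for k, v in seg.landmarks.items()},
                "proximal_jrc": None if seg.proximal_jrc is None else seg.proximal_jrc.tolist(),
                "distal_jrc": None if seg.distal_jrc is None else seg.distal_jrc.tolist(),
                "contact_points": {k: v.tolist() for k, v in seg.contact_points.items()},
                "marker_labels": list(seg.marker_labels),
            }
            for name, seg in ds.segments.items()
        },
        "muscles": [
            {
                "id": m.id, "muscle": m.muscle, "group": m.group, "role": m.role,
                "pcsa": m.pcsa, "fmax": m.fmax,
                "path": [[seg, p.tolist()] for seg, p in m.path],
            }
            for m in ds.muscles
        ],
        "cylinders": [
            {
                "id": c.id, "segment": c.segment, "axis_point": c.axis_point.tolist(),
                "axis_dir": c.axis_dir.tolist(), "radius": c.radius,
                "wrapped_elements": list(c.wrapped_elements),
            }
            for c in ds.cylinders
        ],
    }


def anatomy_from_dict(d: Mapping) -> AnatomyDataset:
    if d.get("format") != "hipload-anatomy":
        raise IOError_("not a hipload anatomy file (missing format tag)")
    if d.get("version") != ANATOMY_SCHEMA_VERSION:
        raise IOError_(f"unsupported anatomy schema version {d.get('version')!r}")
    for key in ("subject", "segments", "muscles"):
        if key not in d:
            raise IOError_(f"anatomy file missing required key {key!r}")
    segments = {
        name: AnatomySegment(
            name=name,
            landmarks={k: np.array(v) for k, v in s.get("landmarks", {}).items()},
            proximal_jrc=None if s.get("proximal_jrc") is None else np.array(s["proximal_jrc"]),
            distal_jrc=None if s.get("distal_jrc") is None else np.array(s["distal_jrc"]),
            contact_points={k: np.array(v) for k, v in s.get("contact_points", {}).items()},
            marker_labels=tuple(s.get("marker_labels", ())),
        )
        for name, s in d["segments"].items()
    }
    muscles = [
        MuscleElement(
            id=m["id"], muscle=m.get("muscle", m["id"]),
            path=[(seg, np.array(p)) for seg, p in m["path"]],
            pcsa=m.get("pcsa"), fmax=m.get("fmax"),
            group=m.get("group", "other"), role=m.get("role", "muscle"),
        )
        for m in d["muscles"]
    ]
    cylinders = [
        WrappingCylinder(
            id=c["id"], segment=c["segment"], axis_point=np.array(c["axis_point"]),
            axis_dir=np.array(c["axis_dir"]), radius=c["radius"],
            wrapped_elements=tuple(c.get("wrapped_elements", ())),
        )
        for c in d.get("cylinders", [])
    ]
    return AnatomyDataset(
        subject=Subject(**d["subject"]),
        segments=segments, muscles=muscles, cylinders=cylinders,
        sigma_max=d.get("sigma_max", _anatomy.DEFAULT_SIGMA_MAX),
    )


def save_anatomy(path, ds: AnatomyDataset) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(anatomy_to_dict(ds), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_anatomy(path) -> AnatomyDataset:
    with open(path, encoding="utf-8") as fh:
        return anatomy_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# C3D adapter (optional dependency)

def read_c3d(path, force_plate_channels: Optional[Mapping[str, str]] = None):
    """Read markers (and, when mapped, analog force channels) from a C3D file.

    Requires the optional ``ezc3d`` dependency.  Positions declared in mm are
    converted to metres.
    """
    try:
        import ezc3d  # noqa: F401
    except ImportError as e:
        raise ImportError(
            "C3D support needs the optional 'ezc3d' package "
            "(pip install hipload[c3d]); the TSV reader has no extra dependency"
        ) from e
    c3d = ezc3d.c3d(str(path))
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    labels = [l.strip() for l in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    unit = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["m"])[0]
    fac = 0.001 if str(unit).strip().lower() == "mm" else 1.0
    n = pts.shape[2]
    time = np.arange(n) / rate
    markers = {lbl: pts[:3, i, :].T * fac for i, lbl in enumerate(labels)}
    valid = {lbl: np.all(np.isfinite(markers[lbl]), axis=1) for lbl in markers}
    return MarkerTrial(rate, time, markers, valid)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    anatomy: str
    static_trial: str
    trial: str
    grf: str
    out_dir: str
    activity: str = "WN"
    filter_order: int = 4
    filter_fc: float = 10.0
    apply_filter: bool = True
    calibration_window: float = 0.1
    measured_hcf: Optional[str] = None
    cycle: Optional[Tuple[float, float]] = None     # (start, end) seconds
    subject_lengths: Optional[Dict[str, float]] = None
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_TAGS:
            raise IOError_(f"activity {self.activity!r} not in {ACTIVITY_TAGS}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        solver = SolverConfig(**d.pop("solver", {}))
        cycle = d.pop("cycle", None)
        cfg = cls(solver=solver, cycle=tuple(cycle) if cycle else None, **d)
        return cfg

    def validate_paths(self) -> None:
        for what in ("anatomy", "static_trial", "trial", "grf"):
            p = getattr(self, what)
            if not Path(p).is_file():
                raise IOError_(f"{what} file not found: {p}")
        if self.measured_hcf and not Path(self.measured_hcf).is_file():
            raise IOError_(f"measured_hcf file not found: {self.measured_hcf}")


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Scale -> calibrate -> filter -> IK -> dynamics -> optimize -> metrics.

    Writes intermediate TSVs, a metrics report and a machine-readable run log
    into ``config.out_dir``; returns a result bundle with the key outputs.
    """
    from . import __version__

    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: Dict[str, object] = {"version": __version__, "stages": [], "config": {
        "activity": config.activity, "alpha": config.solver.alpha,
        "filter": [config.filter_order, config.filter_fc, config.apply_filter],
        "seed": config.solver.seed,
    }}

    def stage(name: str):
        log["stages"].append(name)

    try:
        return _run_pipeline_stages(config, out, log, stage)
    except Exception as e:
        # name the failing stage; partial outputs already written are kept
        failed = log["stages"][-1] if log["stages"] else "load"
        log["failed_stage"] = failed
        with open(out / "runlog.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
            fh.write("\n")
        raise type(e)(f"pipeline stage {failed!r} failed: {e}") from e


def _run_pipeline_stages(config: "PipelineConfig", out: Path, log: dict, stage) -> Dict[str, object]:
    stage("load")
    ds = load_anatomy(config.anatomy)
    static = read_marker_tsv(config.static_trial)
    trial = read_marker_tsv(config.trial)
    t_grf, grf = read_grf_tsv(config.grf)

    if config.subject_lengths:
        stage("scale")
        factors = scale_factors_from_lengths(config.subject_lengths, segment_lengths(ds))
        ds = apply_scaling(ds, factors)
        log["scale_factors"] = {k: float(np.mean(v)) for k, v in factors.factors.items()}

    stage("calibrate")
    calib = calibrate(static, ds, window=config.calibration_window)
    log["calibration_rmse_m"] = calib.residual_rmse

    if config.apply_filter:
        stage("filter")
        trial = lowpass_filter(trial, order=config.filter_order, fc=config.filter_fc)

    stage("inverse_kinematics")
    poses = inverse_kinematics(trial, calib, ds)
    log["ik_flags"] = poses.flags
    log["ik_rmse_max_m"] = float(np.max(poses.rmse))
    params = params_from_anatomy(ds)
    differentiate(poses, ds, params.com_local(ds))
    write_pose_tsv(out / "poses.tsv", poses)

    stage("inverse_dynamics")
    grf_rs = grf.resample(t_grf, poses.time)
    problems = assemble_series(ds, poses, params, grf_rs, config.solver)

    stage("optimize")
    solutions = solve_trial(problems, config.solver)
    statuses = [s.status for s in solutions]
    log["solver_statuses"] = statuses
    bw = ds.subject.weight
    write_solution_tsv(out / "forces.tsv", poses.time, solutions, problems[0].element_ids, bw)
    write_activation_tsv(out / "activations.tsv", poses.time, solutions, problems[0].element_ids)

    result: Dict[str, object] = {
        "poses": poses, "problems": problems, "solutions": solutions,
        "out_dir": str(out), "log": log,
    }

    start, end = config.cycle if config.cycle else (float(poses.time[0]), float(poses.time[-1]))
    hcf_bw = np.array([s.hcf / bw * 100.0 for s in solutions])
    pred = normalize_cycle(poses.time, hcf_bw, start, end)
    pd_wave = pd.DataFrame({"cycle_pct": pred.cycle, "hcf_bw": pred.values})
    _write_tsv(out / "hcf_waveform.tsv", pd_wave, "%cycle %BW")
    result["hcf_waveform"] = pred

    if config.measured_hcf:
        stage("metrics")
        df = _read_tsv(config.measured_hcf)
        meas = normalize_cycle(df["time"].to_numpy(float), df["hcf_bw"].to_numpy(float), start, end)
        report = metrics_report(pred, meas, activity=config.activity)
        with open(out / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        result["metrics"] = report

    with open(out / "runlog.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return result
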