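"""Validation metrics for predicted vs measured hip-contact-force waveforms.

Waveforms are cycle-normalised to 101 samples over 0-100% of the activity
cycle and expressed in percent body weight (%BW).  Metrics: body-weight
normalised RMSE, coefficient of determination, and peak magnitude/timing
errors per peak window.  Walking and stair ascent show two force peaks
(loading response and push-off, toe-off near 60% of the cycle); stair
descent starts at toe-off with heel strike near 40%; chair activities show a
single peak.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

N_SAMPLES = 101

#: Default peak-search windows in % cycle per activity tag.
DEFAULT_PEAK_WINDOWS: Dict[str, List[Tuple[float, float]]] = {
    "WN": [(0.0, 30.0), (30.0, 60.0)],
    "WS": [(0.0, 30.0), (30.0, 60.0)],
    "WF": [(0.0, 30.0), (30.0, 60.0)],
    "SU": [(0.0, 30.0), (30.0, 60.0)],
    "SD": [(40.0, 70.0), (70.0, 100.0)],
    "CU": [(0.0, 100.0)],
    "CD": [(0.0, 100.0)],
}


class MetricsError(ValueError):
    pass


@dataclass
class Waveform:
    """101-sample cycle-normalised trace in %BW."""

    values: np.ndarray
    events: Dict[str, float] = field(default_factory=dict)  # e.g. {"toe_off": 60.0}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SAMPLES,):
            raise MetricsError(f"waveform must have {N_SAMPLES} samples, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise MetricsError("waveform contains non-finite values")

    @property
    def cycle(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, N_SAMPLES)


@dataclass
class PeakError:
    window: Tuple[float, float]
    measured_peak: float
    predicted_peak: float
    measured_at: float      # % cycle
    predicted_at: float     # % cycle
    magnitude_error: float  # % of measured peak, absolute
    timing_error: float     # % cycle, absolute
    plateau_flag: bool = False


@dataclass
class PeakReport:
    peaks: List[PeakError]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def normalize_cycle(time: np.ndarray, values: np.ndarray, start: float, end: float) -> Waveform:
    """Linear resampling of a time series onto 101 points over [start, end]."""
    time = np.asarray(time, float)
    values = np.asarray(values, float)
    if not end > start:
        raise MetricsError("cycle end must exceed start")
    if start < time[0] - 1e-9 or end > time[-1] + 1e-9:
        raise MetricsError("cycle window outside the series")
    grid = np.linspace(start, end, N_SAMPLES)
    return Waveform(np.interp(grid, time, values))


def rmse_bw(pred: Waveform, meas: Waveform) -> float:
    """Root-mean-square pointwise difference, %BW."""
    d = pred.values - meas.values
    return float(np.sqrt(np.mean(d * d)))


def r_squared(pred: Waveform, meas: Waveform) -> float:
    """1 - SS_res / SS_tot with the measured waveform as reference.

    May be negative for predictions worse than the measured mean.
    """
    m = meas.values
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0:
        raise MetricsError("measured waveform has zero variance")
    ss_res = float(np.sum((pred.values - m) ** 2))
    return 1.0 - ss_res / ss_tot


def _window_peak(w: Waveform, lo: float, hi: float) -> Tuple[float, float, bool]:
    cyc = w.cycle
    sel = (cyc >= lo - 1e-9) & (cyc <= hi + 1e-9)
    vals = w.values[sel]
    pos = cyc[sel]
    i = int(np.argmax(vals))          # ties break to the earliest sample
    plateau = bool(np.all(np.diff(vals) <= 0) or np.all(np.diff(vals) >= 0))
    return float(vals[i]), float(pos[i]), plateau


def peak_errors(
    pred: Waveform,
    meas: Waveform,
    windows: Optional[Sequence[Tuple[float, float]]] = None,
    activity: str = "WN",
) -> PeakReport:
    """Per-window peak magnitude and timing errors.

    Magnitude error = |pred_peak - meas_peak| / meas_peak * 100 (% of the
    experimental peak); timing error = |argmax difference| in % cycle.
    """
    if windows is None:
        windows = DEFAULT_PEAK_WINDOWS[activity]
    wins = [(float(a), float(b)) for a, b in windows]
    for (a, b) in wins:
        if not (0.0 <= a < b <= 100.0):
            raise MetricsError(f"invalid peak window {(a, b)}")
    for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
        if b1 > a2:
            raise MetricsError("peak windows overlap")
    peaks = []
    for lo, hi in wins:
        mp, mt, mflag = _window_peak(meas, lo, hi)
        pp, pt, pflag = _window_peak(pred, lo, hi)
        if mp == 0:
            raise MetricsError("measured peak is zero; magnitude error undefined")
        peaks.append(PeakError(
            (lo, hi), mp, pp, mt, pt,
            abs(pp - mp) / abs(mp) * 100.0, abs(pt - mt),
            mflag or pflag,
        ))
    return PeakReport(peaks)


def ensemble(trials: Sequence[Waveform]) -> Tuple[Waveform, Waveform]:
    """Pointwise arithmetic mean and sample standard deviation."""
    if len(trials) == 0:
        raise MetricsError("ensemble of zero trials")
    arr = np.array([t.values for t in trials])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(trials) > 1 else np.zeros(N_SAMPLES)
    return Waveform(mean), Waveform(sd)


def metrics_report(
    pred: Waveform,
    meas: Waveform,
    activity: str = "WN",
    windows: Optional[Sequence[Tuple[float, float]]] = None,
) -> Dict[str, object]:
    """Bundle of all waveform metrics, mirroring the validation table layout."""
    rep = peak_errors(pred, meas, windows=windows, activity=activity)
    out: Dict[str, object] = {
        "activity": activity,
        "rmse_bw": rmse_bw(pred, meas),
        "r_squared": r_squared(pred, meas),
        "n_peaks": rep.n_peaks,
    }
    for i, pk in enumerate(rep.peaks, start=1):
        out[f"peak{i}_magnitude_error_pct"] = pk.magnitude_error
        out[f"peak{i}_timing_error_pct"] = pk.timing_error
    return out
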