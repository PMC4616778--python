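"""Beat detection and pulse-contour stroke-volume estimation.

Turns a raw arterial pressure trace into an ordered beat sequence with
per-beat landmarks (diastolic foot, systolic peak), pulse pressure, systolic
area, and a pulse-contour stroke-volume surrogate (systolic area times a
calibration constant).  The surrogate's absolute scale is arbitrary; every
downstream index (SVV, dynamic elastance) is invariant to the calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.signal import savgol_filter

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .synthetic_data import WaveformRecord

__all__ = [
    "Beat",
    "BeatSeries",
    "RespWindow",
    "detect_beats",
    "estimate_stroke_volume",
    "add_stroke_volume_estimates",
    "segment_respiratory_cycles",
]

MIN_SAMPLING_RATE_HZ = 25.0
#: End of systole for area integration, as a fraction of the instantaneous
#: beat period (no dicrotic notch is assumed; ejection is roughly the first
#: third of the cycle).
SYSTOLE_FRACTION = 0.35
#: Slope threshold for upstroke detection, relative to the trace's 95th
#: percentile slope.
SLOPE_THRESHOLD_FRAC = 0.30
#: Physiological instantaneous heart-rate bounds; beats outside are flagged.
HR_BOUNDS_BPM = (20.0, 250.0)


@dataclass
class Beat:
    """One cardiac cycle's landmarks and derived quantities."""

    foot_index: int  # sample index of the diastolic foot (beat onset)
    peak_index: int  # sample index of the systolic peak
    sbp: float  # mmHg
    dbp: float  # mmHg
    systolic_area: float  # mmHg*s, pressure above dbp from foot to systole end
    period_s: float  # foot-to-foot interval
    sv_estimate: float = float("nan")  # mL, calibration_k * systolic_area
    flagged: bool = False  # instantaneous HR outside physiological bounds

    @property
    def pp(self) -> float:
        return self.sbp - self.dbp


@dataclass
class BeatSeries:
    beats: list[Beat]
    sampling_rate: float  # Hz
    resp_rate: float  # breaths/min, ventilator-set
    duration: float  # s, of the underlying trace

    def foot_times(self) -> np.ndarray:
        return np.array([b.foot_index for b in self.beats]) / self.sampling_rate


@dataclass(frozen=True)
class RespWindow:
    """One ventilator cycle: the beats whose foot falls inside it."""

    start_s: float
    end_s: float
    beat_indices: tuple[int, ...]
    complete: bool  # at least 2 beats


def detect_beats(waveform: "WaveformRecord") -> BeatSeries:
    """Segment an arterial trace into beats.

    The diastolic foot is the local minimum preceding each systolic upstroke
    (contiguous slope runs above 30% of the trace's 95th-percentile slope);
    the systolic peak is the pressure maximum before the next foot.  Beats
    touching the trace boundaries are discarded.  Deterministic and
    idempotent.
    """
    fs = waveform.sampling_rate
    if fs < MIN_SAMPLING_RATE_HZ:
        raise ValueError(
            f"sampling rate too low: {fs:g} Hz < {MIN_SAMPLING_RATE_HZ:g} Hz"
        )
    p = np.asarray(waveform.samples, dtype=float)
    if np.ptp(p) < 1.0:
        raise ValueError("no pulsatile signal")

    # Smooth for landmark *detection* only; values are read off the raw trace.
    win = max(5, int(round(0.11 * fs)) | 1)
    win = min(win, len(p) - 1 if len(p) % 2 == 0 else len(p) - 2)
    smooth = savgol_filter(p, window_length=win, polyorder=3)
    slope = np.gradient(smooth) * fs
    thr = SLOPE_THRESHOLD_FRAC * np.percentile(slope, 95)
    if thr <= 0:
        raise ValueError("no pulsatile signal")

    # Upstrokes: contiguous runs of above-threshold slope.  Runs separated by
    # less than half the fastest physiological beat belong to the same beat;
    # runs shorter than ~30 ms are noise, not a systolic upstroke.
    above = np.nonzero(slope > thr)[0]
    if len(above) == 0:
        raise ValueError("no pulsatile signal")
    gap = max(1, int(round(0.5 * 60.0 / HR_BOUNDS_BPM[1] * fs)))
    breaks = np.nonzero(np.diff(above) > gap)[0]
    min_run = max(2, int(round(0.03 * fs)))
    runs = [r for r in np.split(above, breaks + 1) if len(r) >= min_run]
    if not runs:
        raise ValueError("no pulsatile signal")
    starts = np.array([r[0] for r in runs])

    # Foot: the last sample before each upstroke that sits at the bottom of
    # the preceding diastolic valley.  "Bottom" is judged on the smoothed
    # trace within a noise-scaled tolerance, so that a flat diastolic run-off
    # (or noise dips earlier in diastole) cannot pull the foot away from the
    # upstroke onset.
    noise_est = 1.4826 * float(np.median(np.abs(p - smooth)))
    amp = float(np.percentile(smooth, 95) - np.percentile(smooth, 5))
    tol = max(3.0 * noise_est, 1e-6 * amp)
    back = int(round(0.3 * fs))
    feet = []
    for s in starts:
        lo = max(0, s - back)
        seg = smooth[lo:s + 1]
        cand = np.nonzero(seg <= seg.min() + tol)[0]
        foot = lo + int(cand[-1])
        # refine on the raw trace: walk down any remaining descent so the
        # foot sits on the true onset minimum, not a sample early
        while foot + 1 < len(p) - 1 and p[foot + 1] < p[foot]:
            foot += 1
        feet.append(foot)
    feet = np.unique(feet)
    if len(feet) < 2:
        raise ValueError("no pulsatile signal")

    min_period = int(round(60.0 / HR_BOUNDS_BPM[1] * fs))
    n_dropped = 0
    beats: list[Beat] = []
    for i in range(len(feet) - 1):
        a, b = int(feet[i]), int(feet[i + 1])
        if a == 0:  # touches the trace start
            continue
        if b - a < min_period:  # detection artifact, not a physiologic beat
            continue
        peak = a + int(np.argmax(p[a:b]))
        dbp, sbp = float(p[a]), float(p[peak])
        if sbp - dbp <= 0:
            n_dropped += 1
            continue
        period = (b - a) / fs
        # integrate pressure above dbp over the systolic window, with a
        # fractionally interpolated endpoint so the area is insensitive to
        # how the window boundary falls between samples
        end_f = a + SYSTOLE_FRACTION * (b - a)
        end_i = min(int(np.floor(end_f)), len(p) - 2)
        seg = p[a:end_i + 1] - dbp
        area = float(np.trapezoid(seg, dx=1.0 / fs))
        frac = end_f - end_i
        if frac > 0:
            p_end = p[end_i] + frac * (p[end_i + 1] - p[end_i])
            area += 0.5 * ((p[end_i] - dbp) + (p_end - dbp)) * frac / fs
        if area <= 0:  # noise swamped a low-amplitude beat
            n_dropped += 1
            continue
        hr = 60.0 / period
        beats.append(Beat(
            foot_index=a, peak_index=peak, sbp=sbp, dbp=dbp,
            systolic_area=area, period_s=period,
            flagged=not (HR_BOUNDS_BPM[0] <= hr <= HR_BOUNDS_BPM[1]),
        ))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} beat(s) with non-positive pulse "
                      "pressure or systolic area (noise-dominated)",
                      stacklevel=2)
    if not beats:
        raise ValueError("no pulsatile signal")
    return BeatSeries(beats=beats, sampling_rate=fs,
                      resp_rate=waveform.resp_rate,
                      duration=waveform.duration)


def estimate_stroke_volume(beat: Beat, calibration_k: float = 1.0) -> float:
    """Pulse-contour stroke volume: ``calibration_k * systolic_area`` (mL).

    The absolute scale is arbitrary (the monitor's internal calibration is
    proprietary); SVV and dynamic elastance are invariant to it.
    """
    if calibration_k <= 0:
        raise ValueError("calibration_k must be positive")
    if not beat.systolic_area > 0:
        raise ValueError("non-positive systolic area")
    return calibration_k * beat.systolic_area


def add_stroke_volume_estimates(series: BeatSeries,
                                calibration_k: float = 1.0) -> BeatSeries:
    """Return a copy of the series with ``sv_estimate`` filled on every beat."""
    beats = [replace(b, sv_estimate=estimate_stroke_volume(b, calibration_k))
             for b in series.beats]
    return BeatSeries(beats=beats, sampling_rate=series.sampling_rate,
                      resp_rate=series.resp_rate, duration=series.duration)


def segment_respiratory_cycles(series: BeatSeries) -> list[RespWindow]:
    """Clock-aligned ventilator cycles and the beats falling inside each.

    Windows of duration ``60/resp_rate`` s start at t=0 (the ventilator rate
    is set and fixed, so cycles are aligned to the clock, not derived from
    the pressure signal).  Windows with fewer than 2 beats, or not fully
    covered by detected beats (boundary truncation), are flagged incomplete
    and excluded from index computation.
    """
    if series.resp_rate <= 0:
        raise ValueError("resp_rate must be positive")
    period = 60.0 / series.resp_rate
    foot_times = series.foot_times()
    span_lo = foot_times[0]
    span_hi = foot_times[-1] + series.beats[-1].period_s
    tol = 1.0 / series.sampling_rate
    n_windows = int(np.floor(series.duration / period + 1e-9))
    windows = []
    for k in range(n_windows):
        lo, hi = k * period, (k + 1) * period
        idx = tuple(int(i) for i in
                    np.nonzero((foot_times >= lo) & (foot_times < hi))[0])
        covered = (lo >= span_lo - tol) and (hi <= span_hi + tol)
        windows.append(RespWindow(start_s=lo, end_s=hi, beat_indices=idx,
                                  complete=len(idx) >= 2 and covered))
    return windows
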