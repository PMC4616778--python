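"""Pulse pressure variation, stroke volume variation, and dynamic arterial elastance.

The three indices follow the clinical measurement conventions of bedside
monitors rather than a single idealized formula:

* PPV is computed per respiratory cycle as ``100 * 2*(PPmax - PPmin) /
  (PPmax + PPmin)`` and reported on an 8-s epoch grid, each reported reading
  being the rolling mean of 4 consecutive epochs.
* SVV is computed per respiratory cycle as ``100 * (SVmax - SVmin) / SVmean``
  and reported every 20 s as the mean over the cycles in the window.
* Dynamic arterial elastance is the ratio of the averages of the last 3
  readings of each series (ratio of averages, not average of ratios), pairing
  the two native update grids at a common time point.

The module also implements the protocol rules around the fluid challenge:
the preload-dependence/hypotension gate (SVV > 10% sustained for 10 min, and
MAP < 65 mmHg or SBP < 90 mmHg) and the arterial-pressure responder rule
(MAP increase >= 15%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .synthetic_data import WaveformRecord
    from .waveform_features import BeatSeries, RespWindow

__all__ = [
    "IndexReading",
    "IndexSeries",
    "HemodynamicSnapshot",
    "PatientRecord",
    "PPV_EPOCH_S",
    "SVV_WINDOW_S",
    "compute_ppv",
    "compute_svv",
    "compute_index_series",
    "compute_dynamic_ea",
    "classify_responder",
    "check_preload_dependency",
    "mean_arterial_pressure",
    "RESPONDER_THRESHOLD",
]

#: Native update grids of the two monitors: PPV on 8-s epochs (averaged over
#: 4 consecutive epochs), SVV every 20 s.
PPV_EPOCH_S = 8.0
PPV_EPOCHS_PER_READING = 4
SVV_WINDOW_S = 20.0

#: Fractional MAP increase defining an arterial-pressure responder.
RESPONDER_THRESHOLD = 0.15

#: Preload-dependence / hypotension gate constants.
SVV_GATE_PCT = 10.0
MAP_GATE_MMHG = 65.0
SBP_GATE_MMHG = 90.0
GATE_HISTORY_S = 600.0


@dataclass(frozen=True)
class IndexReading:
    time_s: float
    value: float


@dataclass
class IndexSeries:
    """PPV and SVV readings on their native grids, plus paired Ea values."""

    ppv_readings: list[IndexReading]
    svv_readings: list[IndexReading]
    ea_readings: list[IndexReading] = field(default_factory=list)


@dataclass
class HemodynamicSnapshot:
    """Per-patient hemodynamic state at one protocol time point."""

    timepoint: str  # one of T1..T4
    map: float  # mmHg
    sbp: float  # mmHg
    heart_rate: float  # /min
    cardiac_index: float | None = None  # L/min/m^2
    stroke_volume_index: float | None = None  # mL/m^2
    svv: float | None = None  # %
    ppv: float | None = None  # %
    ea: float | None = None  # dimensionless

    def __post_init__(self) -> None:
        if self.timepoint not in {"T1", "T2", "T3", "T4"}:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.map >= self.sbp:
            raise ValueError("MAP must be below systolic pressure")
        if self.map <= 0:
            raise ValueError("pressures must be positive")


@dataclass
class PatientRecord:
    """T1-T4 snapshots of one patient around the fluid challenge.

    ``responder`` is a derived property, never stored: it always equals the
    >= 15% MAP-increase rule applied to the T2 (pre) and T3 (post) snapshots.
    """

    patient_id: str
    snapshots: dict[str, HemodynamicSnapshot]

    @property
    def responder(self) -> bool:
        try:
            before = self.snapshots["T2"].map
            after = self.snapshots["T3"].map
        except KeyError as exc:
            raise ValueError(
                f"patient {self.patient_id}: missing snapshot {exc} for "
                "responder classification"
            ) from None
        return classify_responder(before, after)


# --------------------------------------------------------------------------
# Index computation
# --------------------------------------------------------------------------

def _cycle_values(beats: "BeatSeries", cycles: Sequence["RespWindow"],
                  attr: str, formula) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle index values and cycle midpoints over complete windows."""
    mids, vals = [], []
    for win in cycles:
        if not win.complete:
            continue
        x = np.array([getattr(beats.beats[i], attr) for i in win.beat_indices],
                     dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"beat {attr} missing or non-finite in window "
                             f"[{win.start_s:g}, {win.end_s:g}) s")
        mids.append(0.5 * (win.start_s + win.end_s))
        vals.append(formula(x))
    return np.asarray(mids), np.asarray(vals)


def _ppv_formula(pp: np.ndarray) -> float:
    return 100.0 * 2.0 * (pp.max() - pp.min()) / (pp.max() + pp.min())


def _svv_formula(sv: np.ndarray) -> float:
    return 100.0 * (sv.max() - sv.min()) / sv.mean()


def compute_ppv(beats: "BeatSeries",
                cycles: Sequence["RespWindow"]) -> list[IndexReading]:
    """PPV readings on the 8-s epoch grid, averaged over 4 rolling epochs.

    Per complete respiratory cycle ``PPV = 100 * 2*(PPmax - PPmin) /
    (PPmax + PPmin)``; each 8-s epoch takes the mean over the cycles whose
    midpoint falls inside it; each reported reading is the mean of 4
    consecutive usable epochs (stride one epoch), time-stamped at the end of
    its last epoch.
    """
    mids, vals = _cycle_values(beats, cycles, "pp", _ppv_formula)
    n_epochs = int(beats.duration // PPV_EPOCH_S)
    epoch_times, epoch_vals = [], []
    for k in range(n_epochs):
        lo, hi = k * PPV_EPOCH_S, (k + 1) * PPV_EPOCH_S
        sel = (mids >= lo) & (mids < hi)
        if not np.any(sel):
            warnings.warn(
                f"no complete respiratory cycle in epoch [{lo:g}, {hi:g}) s; "
                "epoch skipped", stacklevel=2)
            continue
        epoch_times.append(hi)
        epoch_vals.append(float(vals[sel].mean()))
    if len(epoch_vals) < PPV_EPOCHS_PER_READING:
        raise ValueError(
            f"need at least {PPV_EPOCHS_PER_READING} usable 8-s epochs, "
            f"got {len(epoch_vals)}"
        )
    readings = []
    for k in range(PPV_EPOCHS_PER_READING - 1, len(epoch_vals)):
        window = epoch_vals[k - PPV_EPOCHS_PER_READING + 1: k + 1]
        readings.append(IndexReading(epoch_times[k], float(np.mean(window))))
    return readings


def compute_svv(beats: "BeatSeries",
                cycles: Sequence["RespWindow"]) -> list[IndexReading]:
    """SVV readings every 20 s.

    Per complete respiratory cycle ``SVV = 100 * (SVmax - SVmin) / SVmean``
    from the beats' stroke-volume estimates; each 20-s window reports the
    mean over the cycles whose midpoint falls inside it.  Invariant to the
    stroke-volume calibration constant (the formula is scale-free).
    """
    mids, vals = _cycle_values(beats, cycles, "sv_estimate", _svv_formula)
    readings = []
    n_windows = int(beats.duration // SVV_WINDOW_S)
    for k in range(n_windows):
        lo, hi = k * SVV_WINDOW_S, (k + 1) * SVV_WINDOW_S
        sel = (mids >= lo) & (mids < hi)
        if not np.any(sel):
            warnings.warn(
                f"no complete respiratory cycle in window [{lo:g}, {hi:g}) s; "
                "window skipped", stacklevel=2)
            continue
        readings.append(IndexReading(hi, float(vals[sel].mean())))
    return readings


def compute_index_series(beats: "BeatSeries",
                         cycles: Sequence["RespWindow"]) -> IndexSeries:
    """Both index series plus the paired Ea value at each PPV reading time."""
    ppv = compute_ppv(beats, cycles)
    svv = compute_svv(beats, cycles)
    ea: list[IndexReading] = []
    times = sorted({r.time_s for r in ppv} | {r.time_s for r in svv})
    for t in times:
        n_ppv = sum(1 for r in ppv if r.time_s <= t + 1e-9)
        n_svv = sum(1 for r in svv if r.time_s <= t + 1e-9)
        if n_ppv >= 3 and n_svv >= 3:
            ea.append(IndexReading(t, compute_dynamic_ea(ppv, svv, t)))
    return IndexSeries(ppv_readings=ppv, svv_readings=svv, ea_readings=ea)


def compute_dynamic_ea(ppv_readings: Sequence[IndexReading],
                       svv_readings: Sequence[IndexReading],
                       at_time: float) -> float:
    """Dynamic arterial elastance at ``at_time``.

    The ratio of the average of the last 3 PPV readings to the average of the
    last 3 SVV readings at or before ``at_time`` (ratio of averages); the two
    series live on different native grids, so this pairing also absorbs the
    8-s vs 20-s update mismatch.
    """
    tol = 1e-9
    ppv3 = [r.value for r in ppv_readings if r.time_s <= at_time + tol][-3:]
    svv3 = [r.value for r in svv_readings if r.time_s <= at_time + tol][-3:]
    if len(ppv3) < 3 or len(svv3) < 3:
        raise ValueError(
            f"need 3 readings of each series at or before t={at_time:g} s "
            f"(have {len(ppv3)} PPV, {len(svv3)} SVV)"
        )
    mean_svv = float(np.mean(svv3))
    if mean_svv == 0:
        raise ValueError("SVV zero; Ea undefined")
    return float(np.mean(ppv3)) / mean_svv


# --------------------------------------------------------------------------
# Protocol rules
# --------------------------------------------------------------------------

def classify_responder(map_before: float, map_after: float,
                       threshold: float = RESPONDER_THRESHOLD) -> bool:
    """Arterial-pressure responder: MAP increase >= 15% (boundary inclusive).

    The comparison carries a 1e-12 guard so that floating-point
    representation of the MAPs cannot flip a case sitting exactly on the
    boundary; clinically distinct cases are orders of magnitude away from it.
    """
    if map_before <= 0 or map_after <= 0:
        raise ValueError("MAP values must be positive")
    return (map_after - map_before) / map_before >= threshold - 1e-12


def check_preload_dependency(svv_readings: Sequence[IndexReading],
                             map: float, sbp: float) -> bool:
    """Protocol gate for the fluid challenge.

    True iff every SVV reading in the trailing 10-min window is strictly
    above 10% AND the patient is hypotensive (MAP < 65 mmHg or SBP < 90 mmHg,
    strict inequalities as printed on the protocol).
    """
    if not svv_readings:
        raise ValueError("insufficient history: no SVV readings")
    times = [r.time_s for r in svv_readings]
    if max(times) - min(times) < GATE_HISTORY_S:
        raise ValueError(
            "insufficient history: SVV readings must span at least 10 min"
        )
    t_last = max(times)
    window = [r.value for r in svv_readings
              if r.time_s >= t_last - GATE_HISTORY_S]
    sustained = all(v > SVV_GATE_PCT for v in window)
    hypotensive = (map < MAP_GATE_MMHG) or (sbp < SBP_GATE_MMHG)
    return sustained and hypotensive


def mean_arterial_pressure(waveform: "WaveformRecord",
                           t_start: float | None = None,
                           t_end: float | None = None) -> float:
    """Time-averaged arterial pressure over a window (the definition of MAP)."""
    t = waveform.times
    lo = t_start if t_start is not None else t[0]
    hi = t_end if t_end is not None else t[-1]
    sel = (t >= lo) & (t <= hi)
    if not np.any(sel):
        raise ValueError("empty averaging window")
    return float(np.mean(waveform.samples[sel]))
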