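"""Synthetic arterial waveforms and fluid-challenge cohorts with known ground truth.

Two generators back the whole test surface of this package:

``simulate_waveform``
    A mechanically ventilated arterial pressure trace.  Beat-to-beat stroke
    volume is sinusoidally modulated at the ventilator frequency with relative
    depth ``m``; pulse pressure is coupled to stroke volume through a power
    law ``PP = k * SV**gamma``, so the true PPV, SVV and their ratio (dynamic
    arterial elastance) are analytically known.  In the small-modulation limit
    the true PPV/SVV ratio tends to ``gamma``, which makes the tone exponent a
    clean recovery target for the downstream pipeline.

``simulate_cohort``
    A two-group cohort of per-patient hemodynamic snapshots at protocol time
    points T1-T4 in which a patient's dynamic elastance stochastically
    determines the mean-arterial-pressure response to a fluid challenge.
    Responder labels are never stored; they are recomputed downstream from the
    MAP values, which keeps the classification rule an honest round trip.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dynamic_indices import HemodynamicSnapshot, PatientRecord

__all__ = [
    "WaveformSimConfig",
    "GroundTruth",
    "WaveformRecord",
    "CohortSimConfig",
    "simulate_waveform",
    "simulate_cohort",
    "simulate_two_group_scores",
    "MIN_DURATION_S",
]

#: Minimum simulated duration: four 8-s pulse-pressure epochs plus one 20-s
#: stroke-volume window must fit in the trace.
MIN_DURATION_S = 4 * 8.0 + 20.0

# Pulse template geometry: linear systolic upstroke over the first 30% of the
# cycle, exponential decay over the remaining 70%.  The beat analyzer
# integrates the first 35% of the cycle ("ejection fraction of the period"
# convention); the fraction of that window's area as a multiple of PP*period
# can range over (0.15, 0.20) depending on the decay rate.
_UPSTROKE_FRAC = 0.30
_SYSTOLE_FRAC = 0.35
_AREA_FRAC_NOMINAL = 0.175  # systolic area = this * PP * period at baseline SV


@dataclass(frozen=True)
class WaveformSimConfig:
    """Generative parameters of the ventilated-waveform simulator.

    ``sv_modulation_depth`` is the simulator's ground-truth analogue of SVV/2
    (in the continuous limit SVV = 2m * 100%); ``tone_exponent`` is the
    ground-truth analogue of dynamic arterial elastance.
    """

    heart_rate: float = 60.0  # beats/min
    resp_rate: float = 12.0  # breaths/min (ventilator-set)
    sampling_rate: float = 100.0  # Hz
    duration: float = 60.0  # s
    sv_baseline: float = 80.0  # mL
    sv_modulation_depth: float = 0.10  # dimensionless, in [0, 0.5)
    tone_exponent: float = 1.0  # gamma > 0
    diastolic_baseline: float = 55.0  # mmHg
    compliance_scale: float = 0.5  # mmHg per mL**gamma
    noise_sd: float = 0.5  # mmHg additive Gaussian
    baseline_swing: float = 0.0  # mmHg additive respiratory baseline offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heart_rate <= self.resp_rate:
            raise ValueError(
                "heart_rate must exceed resp_rate (need >=2 beats per breath)"
            )
        if self.heart_rate < 4 * self.resp_rate:
            warnings.warn(
                "fewer than 4 beats per respiratory cycle; PPV/SVV extrema "
                "are coarsely sampled",
                stacklevel=2,
            )
        if self.sampling_rate < 25:
            raise ValueError("sampling_rate must be >= 25 Hz")
        if self.duration < MIN_DURATION_S:
            raise ValueError(
                f"duration {self.duration:g} s too short: need at least "
                f"{MIN_DURATION_S:g} s (four 8-s PPV epochs plus one 20-s "
                "SVV window)"
            )
        if not 0 <= self.sv_modulation_depth < 0.5:
            raise ValueError("sv_modulation_depth must be in [0, 0.5)")
        if self.tone_exponent <= 0:
            raise ValueError("tone_exponent must be > 0")
        if self.sv_baseline <= 0 or self.compliance_scale <= 0:
            raise ValueError("sv_baseline and compliance_scale must be > 0")
        if self.diastolic_baseline <= 0:
            raise ValueError("diastolic_baseline must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic index values implied by the generative beat sequence."""

    true_ppv: float  # %
    true_svv: float  # %
    true_ea: float | None  # dimensionless; None when SVV = 0


@dataclass
class WaveformRecord:
    """A uniformly sampled arterial pressure trace plus acquisition metadata."""

    samples: np.ndarray  # mmHg
    sampling_rate: float  # Hz
    resp_rate: float  # breaths/min, ventilator-set
    ground_truth: GroundTruth | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


def _area_fraction(alpha: float) -> float:
    """Systolic-window area of the unit template as a fraction of PP*period.

    The template rises linearly to 1 over ``_UPSTROKE_FRAC`` of the cycle and
    decays as ``exp(-alpha*(u - _UPSTROKE_FRAC))`` afterwards; the analyzer's
    window ends at ``_SYSTOLE_FRAC``.
    """
    tail = _SYSTOLE_FRAC - _UPSTROKE_FRAC
    return _UPSTROKE_FRAC / 2 + (1.0 - math.exp(-alpha * tail)) / alpha


def _solve_decay_rate(target_fraction: float) -> float:
    """Decay rate whose systolic-window area fraction equals ``target``."""
    lo, hi = 1e-6, 5e4
    tgt = float(np.clip(target_fraction, _area_fraction(hi) + 2e-4,
                        _area_fraction(lo) - 2e-4))
    return brentq(lambda a: _area_fraction(a) - tgt, lo, hi, xtol=1e-12)


def _beat_sequence(config: WaveformSimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Foot times, stroke volumes and pulse pressures of every simulated beat."""
    period = 60.0 / config.heart_rate
    n_beats = int(math.ceil(config.duration / period)) + 1
    t_foot = np.arange(n_beats) * period
    f_resp = config.resp_rate / 60.0
    sv = config.sv_baseline * (
        1.0 + config.sv_modulation_depth * np.sin(2 * np.pi * f_resp * t_foot)
    )
    pp = config.compliance_scale * sv ** config.tone_exponent
    return t_foot, sv, pp


def _ground_truth(config: WaveformSimConfig) -> GroundTruth:
    """Analytic PPV/SVV/Ea over the beats of the first respiratory cycle."""
    t_foot, sv, pp = _beat_sequence(config)
    in_cycle = t_foot < 60.0 / config.resp_rate
    sv_c, pp_c = sv[in_cycle], pp[in_cycle]
    true_svv = 100.0 * (sv_c.max() - sv_c.min()) / sv_c.mean()
    true_ppv = 100.0 * 2.0 * (pp_c.max() - pp_c.min()) / (pp_c.max() + pp_c.min())
    true_ea = true_ppv / true_svv if true_svv > 0 else None
    return GroundTruth(true_ppv=true_ppv, true_svv=true_svv, true_ea=true_ea)


def simulate_waveform(config: WaveformSimConfig) -> WaveformRecord:
    """Render a ventilated arterial pressure trace with known index values.

    Beat ``j`` starts at ``j * 60/heart_rate``; its stroke volume is
    ``SV_j = sv_baseline * (1 + m*sin(2*pi*f_resp*t_j))`` and its pulse
    pressure ``PP_j = k * SV_j**gamma``.  Each beat is a stylized pulse:
    linear upstroke from the diastolic baseline to ``baseline + PP_j`` over
    30% of the cycle, exponential decay back towards baseline over the rest.
    The per-beat decay rate is solved so that the systolic area (first 35% of
    the cycle, the same convention the beat analyzer uses) is proportional to
    the true ``SV_j`` — the waveform therefore carries stroke-volume
    information beyond its pulse pressure, exactly as a pulse-contour monitor
    assumes.  Gaussian noise of sd ``noise_sd`` is added.  Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(config.seed)
    period = 60.0 / config.heart_rate
    t_foot, sv, pp = _beat_sequence(config)

    # Per-beat decay rate: area fraction must scale as SV_j / PP_j, i.e. as
    # (SV_j / sv_baseline)**(1 - gamma) relative to the nominal fraction.
    rel = (sv / config.sv_baseline) ** (1.0 - config.tone_exponent)
    targets = _AREA_FRAC_NOMINAL * rel
    uniq, inv = np.unique(np.round(targets, 15), return_inverse=True)
    alphas = np.array([_solve_decay_rate(t) for t in uniq])[inv]

    n = int(round(config.duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    j = np.minimum((t / period).astype(int), len(t_foot) - 1)
    u = t / period - j
    pp_t, alpha_t = pp[j], alphas[j]
    rise = u < _UPSTROKE_FRAC
    pulse = np.where(
        rise,
        pp_t * (u / _UPSTROKE_FRAC),
        pp_t * np.exp(-alpha_t * np.maximum(u - _UPSTROKE_FRAC, 0.0)),
    )
    pressure = config.diastolic_baseline + pulse
    if config.baseline_swing:
        pressure = pressure + config.baseline_swing * np.sin(
            2 * np.pi * config.resp_rate / 60.0 * t
        )
    if config.noise_sd > 0:
        pressure = pressure + rng.normal(0.0, config.noise_sd, size=n)

    return WaveformRecord(
        samples=pressure,
        sampling_rate=config.sampling_rate,
        resp_rate=config.resp_rate,
        ground_truth=_ground_truth(config),
    )


# --------------------------------------------------------------------------
# Cohort generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Generative parameters of the fluid-challenge cohort.

    A patient's dynamic elastance is drawn from a two-component Normal
    mixture (component weight ``responder_weight`` on the high-elastance
    component) or from a single Normal when ``mixture`` is False.  The MAP
    response to the fluid challenge is linear in elastance:
    ``dMAP% = map_intercept + map_slope * Ea + eps``,
    ``eps ~ Normal(0, map_noise_sd)``.  Responder labels are derived
    downstream from the >= 15% MAP-increase rule, never drawn directly.

    Defaults calibrate the two component means to 0.79 (responder-leaning)
    and 0.61, the ``ea_sd`` to 0.145 so the binormal separation has an AUC of
    about 0.81, and the MAP model so that the 15% responder boundary sits at
    Ea = 0.75.
    """

    n_patients: int = 39
    ea_mean_responder: float = 0.79
    ea_mean_nonresponder: float = 0.61
    ea_sd: float = 0.145
    responder_weight: float = 17.0 / 39.0
    mixture: bool = True
    map_intercept: float = -30.0  # beta0, %
    map_slope: float = 60.0  # beta1, % per Ea unit
    map_noise_sd: float = 3.0  # eps sd, %-points
    t2_map_range: tuple[float, float] = (55.0, 64.0)  # mmHg, below 65
    svv_range: tuple[float, float] = (11.0, 16.0)  # %, above 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.ea_sd < 0 or self.map_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.responder_weight <= 1:
            raise ValueError("responder_weight must be in [0, 1]")
        lo, hi = self.t2_map_range
        if not (0 < lo <= hi < 65):
            raise ValueError("t2_map_range must lie in (0, 65) mmHg")
        lo, hi = self.svv_range
        if not (10 < lo <= hi):
            raise ValueError("svv_range must lie above 10%")


def _snapshot(rng: np.random.Generator, timepoint: str, map_: float,
              svv: float, ea: float) -> HemodynamicSnapshot:
    """One plausible hemodynamic snapshot consistent with MAP/SVV/Ea."""
    return HemodynamicSnapshot(
        timepoint=timepoint,
        map=map_,
        sbp=map_ * rng.uniform(1.35, 1.55),
        heart_rate=rng.uniform(55.0, 90.0),
        cardiac_index=rng.uniform(2.0, 3.2),
        stroke_volume_index=rng.uniform(25.0, 42.0),
        svv=svv,
        ppv=ea * svv,
        ea=ea,
    )


def simulate_cohort(config: CohortSimConfig) -> list[PatientRecord]:
    """Generate per-patient T1-T4 snapshots around a fluid challenge.

    T2 always satisfies the protocol gate (SVV > 10% and MAP < 65 mmHg);
    T3 MAP equals T2 MAP scaled by the model's percentage change.  Responder
    status is *not* stored: ``PatientRecord.responder`` recomputes it from
    the T2/T3 MAPs.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    for i in range(config.n_patients):
        if config.mixture:
            hi = rng.random() < config.responder_weight
            mu = config.ea_mean_responder if hi else config.ea_mean_nonresponder
        else:
            mu = (config.responder_weight * config.ea_mean_responder
                  + (1 - config.responder_weight) * config.ea_mean_nonresponder)
        ea = max(rng.normal(mu, config.ea_sd), 0.05)
        eps = rng.normal(0.0, config.map_noise_sd) if config.map_noise_sd else 0.0
        dmap_pct = config.map_intercept + config.map_slope * ea + eps

        map_t2 = rng.uniform(*config.t2_map_range)
        svv_t2 = rng.uniform(*config.svv_range)
        map_t3 = map_t2 + map_t2 * (dmap_pct / 100.0)
        if map_t3 <= 0:
            raise ValueError(
                f"map model produced non-positive T3 MAP ({map_t3:.1f} mmHg) "
                f"for patient {i}: check map_intercept/map_slope"
            )
        svv_t3 = svv_t2 * rng.uniform(0.5, 0.8)  # fluid loading lowers SVV
        snapshots = {
            "T1": _snapshot(rng, "T1", rng.uniform(66.0, 85.0),
                            rng.uniform(7.0, 12.0), ea),
            "T2": _snapshot(rng, "T2", map_t2, svv_t2, ea),
            "T3": _snapshot(rng, "T3", map_t3, svv_t3, ea),
            "T4": _snapshot(rng, "T4", rng.uniform(65.0, 90.0),
                            rng.uniform(6.0, 11.0), ea),
        }
        records.append(PatientRecord(patient_id=f"P{i + 1:03d}",
                                     snapshots=snapshots))
    return records


def simulate_two_group_scores(
    n_pos: int,
    n_neg: int,
    mu_pos: float = 0.79,
    mu_neg: float = 0.61,
    sd: float = 0.145,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binormal scores with known group membership.

    The true AUC of this sampling scheme is
    ``Phi((mu_pos - mu_neg) / sqrt(2) / sd)`` — the closed form used as the
    oracle in confidence-interval calibration studies.
    Returns ``(scores, labels)`` with positives first.
    """
    rng = np.random.default_rng(rng)
    scores = np.concatenate([
        rng.normal(mu_pos, sd, size=n_pos),
        rng.normal(mu_neg, sd, size=n_neg),
    ])
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return scores, labels
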