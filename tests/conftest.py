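import warnings

import numpy as np
import pytest

from dynea import dynamic_indices as di
from dynea import waveform_features as wf
from dynea.synthetic_data import WaveformSimConfig, simulate_waveform
from dynea.waveform_features import Beat, BeatSeries


def run_waveform_pipeline(**kwargs):
    """Simulate a waveform and push it through beats -> cycles -> indices."""
    defaults = dict(heart_rate=60.0, resp_rate=12.0, sampling_rate=100.0,
                    duration=60.0, noise_sd=0.0)
    defaults.update(kwargs)
    cfg = WaveformSimConfig(**defaults)
    record = simulate_waveform(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = wf.add_stroke_volume_estimates(wf.detect_beats(record))
        cycles = wf.segment_respiratory_cycles(series)
        idx = di.compute_index_series(series, cycles)
    return record, series, cycles, idx


def make_beat_series(pp, sv=None, period=1.0, fs=100.0, resp_rate=12.0):
    """A hand-built beat sequence: beat j at time j*period with given pp/sv."""
    pp = np.asarray(pp, dtype=float)
    sv = np.full_like(pp, 10.0) if sv is None else np.asarray(sv, dtype=float)
    dbp = 60.0
    beats = [
        Beat(foot_index=int(round(j * period * fs)),
             peak_index=int(round(j * period * fs)) + 1,
             sbp=dbp + pp[j], dbp=dbp, systolic_area=sv[j],
             period_s=period, sv_estimate=sv[j])
        for j in range(len(pp))
    ]
    return BeatSeries(beats=beats, sampling_rate=fs, resp_rate=resp_rate,
                      duration=len(pp) * period)


@pytest.fixture(scope="session")
def clean_pipeline():
    """Noise-free default waveform (HR 60, RR 12, m=0.10, gamma=1)."""
    return run_waveform_pipeline(sv_modulation_depth=0.10, tone_exponent=1.0,
                                 seed=0)
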