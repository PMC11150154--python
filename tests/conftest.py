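"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from secsurge import BeatSeries, DetectorConfig, SimConfig


def make_series(sbp, dt=1.0, night_id="test", quality=None, dbp=None):
    """Beat series with uniform beat spacing from an SBP sequence."""
    sbp = np.asarray(sbp, dtype=float)
    t = np.arange(sbp.size) * dt
    return BeatSeries(night_id=night_id, time_s=t, sbp_mmHg=sbp,
                      dbp_mmHg=dbp, quality=quality)


def triangular_bump(baseline=120.0, peak=150.0, up_beats=30, down_beats=45,
                    pre=120, post=120, dt=1.0, night_id="bump"):
    """Flat baseline with one triangular surge; returns (series, apex_index)."""
    rise = np.linspace(baseline, peak, up_beats + 1)[1:]
    fall = np.linspace(peak, baseline, down_beats + 1)[1:]
    sbp = np.concatenate([np.full(pre, baseline), rise, fall,
                          np.full(post, baseline)])
    apex = pre + up_beats - 1
    return make_series(sbp, dt=dt, night_id=night_id), apex


@pytest.fixture
def detector_config():
    return DetectorConfig()


@pytest.fixture
def quiet_sim_config():
    """Noise-free simulator settings: planted surges only."""
    return SimConfig(beat_noise_sd_mmHg=0.0, confuser_rate_per_night=0.0,
                     artifact_rate_per_night=0.0)


@pytest.fixture
def short_sim_config():
    """A 1-hour night for fast end-to-end tests."""
    return SimConfig(duration_s=3600.0, sa_surge_rate_per_night=4.0,
                     nonsa_surge_rate_per_night=3.0,
                     confuser_rate_per_night=4.0,
                     artifact_rate_per_night=1.0)
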