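"""Synthetic overnight beat-by-beat recordings with planted sec-surges.

A generated night is a ~1 Hz jittered beat train carrying:

* a slowly drifting nocturnal SBP baseline (sinusoid, random phase);
* planted surges — raised-cosine rise and fall, amplitudes drawn from a
  truncated normal calibrated to the observed severity of sec-surges in
  suspected-OSA patients (mean 26.0, SD 4.3 mmHg; with the 122.2 mmHg
  baseline the mean peak lands near 148.2 mmHg) — annotated with exact
  start/peak/end beat indices;
* for each SA-class surge, a preceding polysomnography event (apnea,
  hypopnea, or desaturation) ending ``sa_event_lead_s`` before the surge;
* sub-threshold "confuser" blood-pressure-variability bumps of the same
  shape but 5-12 mmHg amplitude;
* per-beat Gaussian noise and occasional 1-3 beat motion-artifact spikes
  flagged ``artifact``.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import logging
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import SimConfig
from .types import (
    BeatSeries,
    IntermittentSeries,
    PsgEvent,
    SurgeAnnotation,
    QUALITY_ARTIFACT,
    QUALITY_VALID,
)

__all__ = ["generate_night", "generate_intermittent", "generate_nights"]

log = logging.getLogger(__name__)

MIN_BEAT_INTERVAL_S = 0.2


class NightTooCrowdedError(RuntimeError):
    """Surge placement failed repeatedly; lower the rates or lengthen the
    night."""


def _truncated_normal(rng, mean, sd, lo, hi, max_draws=1000) -> float:
    for _ in range(max_draws):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def _draw_count(rng, rate: float, dispersion: Optional[float]) -> int:
    """Poisson by default; negative binomial when overdispersion is on."""
    if rate <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(rate))
    r = dispersion
    p = r / (r + rate)
    return int(rng.negative_binomial(r, p))


def _raised_cosine(t: np.ndarray, start: float, up: float, down: float,
                   amp: float) -> np.ndarray:
    """Smooth unimodal bump: 0 at ``start``, ``amp`` at ``start+up``, 0 at
    ``start+up+down``; differentiable everywhere."""
    out = np.zeros_like(t)
    rel = t - start
    rising = (rel >= 0) & (rel < up)
    out[rising] = amp * (1 - np.cos(np.pi * rel[rising] / up)) / 2
    falling = (rel >= up) & (rel <= up + down)
    out[falling] = amp * (1 + np.cos(np.pi * (rel[falling] - up) / down)) / 2
    return out


def _place(rng, width: float, zone: Tuple[float, float],
           occupied: List[Tuple[float, float]], lo: float, hi: float,
           attempts: int = 500) -> float:
    """Draw a start time in [lo, hi] whose exclusion zone avoids all
    occupied zones; zone offsets are relative to the start time."""
    z0, z1 = zone
    for _ in range(attempts):
        s = rng.uniform(lo, hi)
        a, b = s + z0, s + width + z1
        if all(b <= oa or a >= ob for oa, ob in occupied):
            occupied.append((a, b))
            return float(s)
    raise NightTooCrowdedError(
        "night too crowded: could not place a surge without overlap"
    )


# exclusion-zone margins (seconds, relative to the event's own interval):
# surges reserve room for their PSG event + the detector's lookback before
# the start and a little recovery after the end; confusers just avoid
# distorting anything nearby.
_SURGE_ZONE = (-160.0, 40.0)
_CONFUSER_ZONE = (-70.0, 30.0)


def generate_night(config: SimConfig | None = None, seed: int = 0
                   ) -> Tuple[BeatSeries, List[SurgeAnnotation], List[PsgEvent]]:
    """Generate one synthetic night: series, planted labels, PSG events."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    # --- beat train -------------------------------------------------------
    n_guess = int(config.duration_s / config.mean_beat_interval_s * 1.2) + 64
    intervals = rng.normal(config.mean_beat_interval_s,
                           config.beat_interval_jitter_sd_s, n_guess)
    intervals = np.clip(intervals, MIN_BEAT_INTERVAL_S, None)
    t = np.concatenate([[0.0], np.cumsum(intervals)])
    t = t[t <= config.duration_s]
    n = t.size

    # --- baseline ---------------------------------------------------------
    phase = rng.uniform(0, 2 * np.pi)
    clean = config.baseline_sbp_mmHg + config.drift_amplitude_mmHg * np.sin(
        2 * np.pi * t / config.drift_period_s + phase
    )

    # --- planted surges ---------------------------------------------------
    n_sa = _draw_count(rng, config.sa_surge_rate_per_night,
                       config.negbin_dispersion)
    n_nonsa = _draw_count(rng, config.nonsa_surge_rate_per_night,
                          config.negbin_dispersion)
    occupied: List[Tuple[float, float]] = []
    surges = []  # (start_t, up, down, amp, sa)
    margin = 250.0
    for is_sa in [True] * n_sa + [False] * n_nonsa:
        amp = _truncated_normal(rng, config.surge_amplitude_mean_mmHg,
                                config.surge_amplitude_sd_mmHg,
                                *config.surge_amplitude_bounds_mmHg)
        up = rng.uniform(*config.upward_duration_range_s)
        down = rng.uniform(*config.downward_duration_range_s)
        start = _place(rng, up + down, _SURGE_ZONE, occupied,
                       margin, config.duration_s - margin - (up + down))
        surges.append((start, up, down, amp, is_sa))
    for start, up, down, amp, _ in surges:
        clean += _raised_cosine(t, start, up, down, amp)

    # --- confusers: same shape, sub-threshold amplitude -------------------
    n_conf = _draw_count(rng, config.confuser_rate_per_night, None)
    for _ in range(n_conf):
        amp = rng.uniform(*config.confuser_amplitude_range_mmHg)
        up = rng.uniform(*config.upward_duration_range_s)
        down = rng.uniform(*config.downward_duration_range_s)
        start = _place(rng, up + down, _CONFUSER_ZONE, occupied,
                       margin, config.duration_s - margin - (up + down))
        clean += _raised_cosine(t, start, up, down, amp)

    # --- annotations (on the clean, pre-noise signal) ---------------------
    annotations: List[SurgeAnnotation] = []
    events: List[PsgEvent] = []
    night_id = f"sim-{seed}"
    for start, up, down, amp, is_sa in sorted(surges):
        end_t = start + up + down
        s_idx = int(np.searchsorted(t, start, side="right")) - 1
        e_idx = int(np.searchsorted(t, end_t, side="left"))
        e_idx = min(e_idx, n - 1)
        span = slice(s_idx, e_idx + 1)
        p_idx = s_idx + int(np.argmax(clean[span]))
        annotations.append(SurgeAnnotation(
            night_id=night_id, start_idx=s_idx, peak_idx=p_idx,
            end_idx=e_idx, source="label",
            sa_class="sa" if is_sa else "non_sa",
        ))
        if is_sa:
            ev_end = start - config.sa_event_lead_s
            ev_dur = rng.uniform(*config.psg_event_duration_range_s)
            kind = PsgEvent.KINDS[rng.integers(0, 3)]
            events.append(PsgEvent(night_id=night_id, kind=kind,
                                   start_s=ev_end - ev_dur, end_s=ev_end))
    events.sort(key=lambda e: e.start_s)

    # --- noise and artifacts ----------------------------------------------
    sbp = clean + rng.normal(0.0, config.beat_noise_sd_mmHg, n)
    quality = np.full(n, QUALITY_VALID, dtype=object)
    n_art = _draw_count(rng, config.artifact_rate_per_night, None)
    surge_zones = occupied[:len(surges)]
    for _ in range(n_art):
        for _attempt in range(100):
            i = int(rng.integers(0, n - 3))
            if all(not (a <= t[i] <= b) for a, b in surge_zones):
                break
        else:
            continue
        length = int(rng.integers(1, 4))
        mag = rng.uniform(*config.artifact_magnitude_range_mmHg)
        if rng.random() < 0.5:
            mag = -mag
        sbp[i:i + length] += mag
        quality[i:i + length] = QUALITY_ARTIFACT

    dbp = sbp - 45.0 + rng.normal(0.0, 2.0, n)

    series = BeatSeries(night_id=night_id, time_s=t, sbp_mmHg=sbp,
                        dbp_mmHg=dbp, quality=quality)
    for ann in annotations:
        ann.validate_against(series)
    return series, annotations, events


def generate_nights(n_nights: int, base_seed: int = 0,
                    config: SimConfig | None = None):
    """Convenience: ``[(series, labels, events), ...]`` for seeds
    ``base_seed .. base_seed + n_nights - 1``."""
    config = config or SimConfig()
    return [generate_night(config, base_seed + i) for i in range(n_nights)]


def generate_intermittent(series: BeatSeries, interval_s: float = 1800.0,
                          window_s: float = 60.0) -> IntermittentSeries:
    """Emulate every-30-min cuff readings: the median valid-beat SBP in a
    ``window_s`` window centered on each sampling time."""
    if series.duration_s < interval_s:
        raise ValueError(
            f"{series.night_id}: series shorter than one sampling interval"
        )
    t0 = series.time_s[0]
    n_samples = int(series.duration_s // interval_s)
    v = series.valid_indices
    tv = series.time_s[v]
    yv = series.sbp_mmHg[v]
    times, readings = [], []
    for i in range(1, n_samples + 1):
        ts = t0 + i * interval_s
        lo = np.searchsorted(tv, ts - window_s / 2)
        hi = np.searchsorted(tv, ts + window_s / 2, side="right")
        if hi <= lo:
            warnings.warn(
                f"{series.night_id}: no valid beats around t={ts:.0f} s; "
                "reading skipped"
            )
            continue
        times.append(ts)
        readings.append(float(np.median(yv[lo:hi])))
    return IntermittentSeries(night_id=series.night_id,
                              time_s=np.array(times),
                              sbp_mmHg=np.array(readings))
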