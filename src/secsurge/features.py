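"""The 48-feature description of a candidate sec-surge.

Each candidate is summarized by exactly 48 real-valued features in six
groups of eight, mirroring the clinician's reading of a surge:

* ``reactivity`` — how the pressure takes off (onset slope, rise jerkiness,
  times to fractional amplitude, pre-start plateau width);
* ``recovery`` — the mirrored dynamics of the fall, plus undershoot below
  the starting pressure;
* ``amplitude`` — pressure levels and excess pressure-time area;
* ``upward`` / ``downward`` — durations, slopes, and areas of the rise and
  fall limbs;
* ``whole`` — whole-event duration, symmetry, and segment statistics.

Every feature is a one-line formula over the beats in [start, end] (plus
the short pre-start stability window and the night-median SBP reference),
so a learned threshold on any of them stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .types import BeatSeries, SurgeAnnotation

__all__ = [
    "GROUPS",
    "FeatureSpec",
    "FeatureVector",
    "feature_catalogue",
    "extract_features",
    "extract_feature_matrix",
]

GROUPS = ("reactivity", "recovery", "amplitude", "upward", "downward", "whole")

#: beats of pre-start plateau used by the baseline-range feature
PRESTART_BEATS = 10


@dataclass(frozen=True)
class FeatureSpec:
    """Catalogue entry: name, group, prose definition, and covariance
    metadata (how the value responds to a uniform time dilation by k and to
    adding a constant c to all SBP values)."""

    name: str
    group: str
    definition: str
    time_scaling: str   # "k", "1/k", "none", or "other"
    level_shift: str    # "c", "none", or "other"


def _catalogue() -> List[FeatureSpec]:
    F = FeatureSpec
    specs = [
        # reactivity: rise-dynamics shape on [start, peak]
        F("react_onset_slope", "reactivity",
          "least-squares SBP slope over the first 5 beats from start (mmHg/s)",
          "1/k", "none"),
        F("react_diff_sd", "reactivity",
          "SD of successive SBP differences in [start, peak] (mmHg)",
          "none", "none"),
        F("react_max_accel", "reactivity",
          "max positive second difference of SBP in [start, peak] (mmHg)",
          "none", "none"),
        F("react_t25", "reactivity",
          "time from start to first beat at >= 25% amplitude (s)",
          "k", "none"),
        F("react_t75", "reactivity",
          "time from start to first beat at >= 75% amplitude (s)",
          "k", "none"),
        F("react_t_ratio", "reactivity",
          "ratio t75/t25 of the rise", "none", "none"),
        F("react_reversals", "reactivity",
          "count of local SBP reversals (sign changes) in the rise",
          "none", "none"),
        F("react_prestart_range", "reactivity",
          "SBP range over the pre-start stability window (mmHg)",
          "none", "none"),
        # recovery: mirrored fall dynamics on [peak, end]
        F("recov_offset_slope", "recovery",
          "least-squares fall rate over the first 5 beats from peak (mmHg/s)",
          "1/k", "none"),
        F("recov_diff_sd", "recovery",
          "SD of successive SBP differences in [peak, end] (mmHg)",
          "none", "none"),
        F("recov_max_accel", "recovery",
          "max positive second difference of the time-reversed fall (mmHg)",
          "none", "none"),
        F("recov_t25", "recovery",
          "time to 25% of the fall range on the time-reversed fall (s)",
          "k", "none"),
        F("recov_t75", "recovery",
          "time to 75% of the fall range on the time-reversed fall (s)",
          "k", "none"),
        F("recov_t_ratio", "recovery",
          "ratio t75/t25 of the time-reversed fall", "none", "none"),
        F("recov_reversals", "recovery",
          "count of local SBP reversals in the fall", "none", "none"),
        F("recov_undershoot", "recovery",
          "max(0, start SBP - end SBP) (mmHg)", "none", "none"),
        # amplitude: pressure levels
        F("amp_surge", "amplitude",
          "amplitude: peak SBP - start SBP (mmHg)", "none", "none"),
        F("amp_peak_sbp", "amplitude", "peak SBP (mmHg)", "none", "c"),
        F("amp_start_sbp", "amplitude", "start SBP (mmHg)", "none", "c"),
        F("amp_end_sbp", "amplitude", "end SBP (mmHg)", "none", "c"),
        F("amp_relative_pct", "amplitude",
          "amplitude as a percentage of start SBP", "none", "other"),
        F("amp_max_beat_rise", "amplitude",
          "max single-beat SBP rise in [start, end] (mmHg)", "none", "none"),
        F("amp_area_above_start", "amplitude",
          "trapezoid area of SBP above start SBP over [start, end] (mmHg*s)",
          "k", "none"),
        F("amp_peak_above_median", "amplitude",
          "peak SBP minus the night median of valid SBP (mmHg)",
          "none", "none"),
        # upward limb on [start, peak]
        F("up_duration", "upward",
          "upward duration: t(peak) - t(start) (s)", "k", "none"),
        F("up_mean_slope", "upward",
          "amplitude / upward duration (mmHg/s)", "1/k", "none"),
        F("up_max_beat_slope", "upward",
          "max beat-to-beat SBP slope in the rise (mmHg/s)", "1/k", "none"),
        F("up_beat_count", "upward",
          "number of valid beats in [start, peak]", "none", "none"),
        F("up_rising_fraction", "upward",
          "fraction of strictly rising successive pairs in the rise",
          "none", "none"),
        F("up_area_above_start", "upward",
          "trapezoid area above start SBP over [start, peak] (mmHg*s)",
          "k", "none"),
        F("up_t50", "upward",
          "time from start to first beat at >= 50% amplitude (s)",
          "k", "none"),
        F("up_ls_slope", "upward",
          "least-squares SBP slope over [start, peak] (mmHg/s)",
          "1/k", "none"),
        # downward limb on [peak, end]
        F("down_duration", "downward",
          "downward duration: t(end) - t(peak) (s)", "k", "none"),
        F("down_mean_slope", "downward",
          "(peak SBP - end SBP) / downward duration (mmHg/s)", "1/k", "none"),
        F("down_max_beat_slope", "downward",
          "max beat-to-beat SBP fall rate in the fall (mmHg/s)",
          "1/k", "none"),
        F("down_beat_count", "downward",
          "number of valid beats in [peak, end]", "none", "none"),
        F("down_falling_fraction", "downward",
          "fraction of strictly falling successive pairs in the fall",
          "none", "none"),
        F("down_area_above_end", "downward",
          "trapezoid area above end SBP over [peak, end] (mmHg*s)",
          "k", "none"),
        F("down_t50", "downward",
          "time from peak to first beat at <= 50% of the fall range (s)",
          "k", "none"),
        F("down_ls_slope", "downward",
          "negated least-squares SBP slope over [peak, end] (mmHg/s)",
          "1/k", "none"),
        # whole event
        F("whole_duration", "whole",
          "total duration: t(end) - t(start) (s)", "k", "none"),
        F("whole_up_down_ratio", "whole",
          "upward duration / downward duration", "none", "none"),
        F("whole_beat_count", "whole",
          "number of valid beats in [start, end]", "none", "none"),
        F("whole_mean_sbp", "whole",
          "mean SBP over [start, end] (mmHg)", "none", "c"),
        F("whole_sbp_sd", "whole",
          "SD of SBP over [start, end] (mmHg)", "none", "none"),
        F("whole_symmetry", "whole",
          "min(up, down) / max(up, down) durations", "none", "none"),
        F("whole_t_above_half", "whole",
          "time with SBP >= start + amplitude/2, linear interpolation (s)",
          "k", "none"),
        F("whole_mean_beat_interval", "whole",
          "mean beat interval in [start, end] (s)", "k", "none"),
    ]
    assert len(specs) == 48
    return specs


_CATALOGUE = _catalogue()
_BY_NAME = {s.name: s for s in _CATALOGUE}
_NAMES = [s.name for s in _CATALOGUE]


def feature_catalogue() -> List[FeatureSpec]:
    """The fixed 48-entry catalogue, in stable (group, index) order."""
    return list(_CATALOGUE)


def feature_group(name: str) -> str:
    return _BY_NAME[name].group


class FeatureVector:
    """Named 48-vector of features for one candidate."""

    __slots__ = ("values",)

    def __init__(self, values: Dict[str, float]):
        if set(values) != set(_NAMES):
            missing = set(_NAMES) - set(values)
            extra = set(values) - set(_NAMES)
            raise ValueError(
                f"feature vector mismatch: missing {sorted(missing)}, "
                f"extra {sorted(extra)}"
            )
        self.values = {n: float(values[n]) for n in _NAMES}
        bad = [n for n, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features: {bad}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in _NAMES])

    @property
    def names(self) -> List[str]:
        return list(_NAMES)


def _ls_slope(t: np.ndarray, y: np.ndarray) -> float:
    if t.size < 2:
        return 0.0
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(tc, y - y.mean()) / denom)


def _area_above(t: np.ndarray, y: np.ndarray, ref: float) -> float:
    return float(np.trapezoid(np.clip(y - ref, 0.0, None), t))


def _first_crossing_time(t: np.ndarray, y: np.ndarray, thr: float) -> float:
    """Time from t[0] to the first beat with y >= thr (last beat if never)."""
    hit = np.flatnonzero(y >= thr)
    i = int(hit[0]) if hit.size else int(t.size - 1)
    return float(t[i] - t[0])


def _fall_crossing_time(tf: np.ndarray, yf: np.ndarray, peak_sbp: float,
                        fall_range: float) -> float:
    """Time from the peak to the first beat at or below half the fall range."""
    if fall_range <= 0:
        return 0.0
    hit = np.flatnonzero(yf <= peak_sbp - 0.5 * fall_range)
    i = int(hit[0]) if hit.size else int(yf.size - 1)
    return float(tf[i] - tf[0])


def _reversals(y: np.ndarray) -> float:
    d = np.diff(y)
    d = d[d != 0]
    if d.size < 2:
        return 0.0
    return float(np.sum(d[:-1] * d[1:] < 0))


def _rise_dynamics(t: np.ndarray, y: np.ndarray, amp: float) -> dict:
    """Shape metrics of a rising limb: onset slope, diff SD, max positive
    acceleration, times to 25%/75% amplitude and their ratio, reversals."""
    base = float(y[0])
    d = np.diff(y)
    out = {
        "onset_slope": _ls_slope(t[:5], y[:5]),
        "diff_sd": float(np.std(d)) if d.size >= 1 else 0.0,
        "max_accel": float(np.max(np.diff(y, 2))) if y.size >= 3 else 0.0,
    }
    if amp > 0:
        t25 = _first_crossing_time(t, y, base + 0.25 * amp)
        t75 = _first_crossing_time(t, y, base + 0.75 * amp)
    else:
        t25 = t75 = 0.0
    out["t25"] = t25
    out["t75"] = t75
    out["t_ratio"] = t75 / t25 if t25 > 0 else 1.0
    out["reversals"] = _reversals(y)
    return out


def _time_above(t: np.ndarray, y: np.ndarray, thr: float) -> float:
    """Total time the linearly interpolated SBP spends at/above ``thr``."""
    total = 0.0
    for i in range(t.size - 1):
        y0, y1 = y[i], y[i + 1]
        dt = t[i + 1] - t[i]
        a0, a1 = y0 >= thr, y1 >= thr
        if a0 and a1:
            total += dt
        elif a0 != a1:
            frac = abs(y0 - thr) / abs(y1 - y0)
            total += dt * (frac if a0 else 1.0 - frac)
    return float(total)


def extract_features(series: BeatSeries, cand: SurgeAnnotation,
                     night_median: float | None = None) -> FeatureVector:
    """Compute the 48-feature vector for one candidate.

    Only valid beats in [start, end], the pre-start stability window, and
    the night-median SBP reference enter the computation.  Deterministic;
    raises for segments of fewer than 3 valid beats.
    """
    cand.validate_against(series)
    v = series.valid_indices
    t_all = series.time_s
    y_all = series.sbp_mmHg
    seg = v[(v >= cand.start_idx) & (v <= cand.end_idx)]
    if seg.size < 3:
        raise ValueError(
            f"{series.night_id}: degenerate segment "
            f"({seg.size} valid beats) for candidate at beat {cand.start_idx}"
        )
    t = t_all[seg]
    y = y_all[seg]
    p_pos = int(np.searchsorted(seg, cand.peak_idx))
    if p_pos >= seg.size or seg[p_pos] != cand.peak_idx:
        raise ValueError("candidate peak is not a valid beat")
    tr, yr = t[:p_pos + 1], y[:p_pos + 1]          # rise [start, peak]
    tf, yf = t[p_pos:], y[p_pos:]                  # fall [peak, end]
    start_sbp = float(y[0])
    peak_sbp = float(y[p_pos])
    end_sbp = float(y[-1])
    amp = getattr(cand, "amplitude_mmHg", None)
    if amp is None or amp == 0.0:
        amp = peak_sbp - start_sbp
    amp = float(amp)
    fall_range = peak_sbp - end_sbp
    up_dur = float(tr[-1] - tr[0]) if tr.size > 1 else 0.0
    down_dur = float(tf[-1] - tf[0]) if tf.size > 1 else 0.0

    if night_median is None:
        night_median = float(np.median(y_all[v]))

    # pre-start stability window
    s_pos = int(np.searchsorted(v, cand.start_idx))
    pre = y_all[v[max(0, s_pos - PRESTART_BEATS + 1):s_pos + 1]]
    pre_range = float(pre.max() - pre.min()) if pre.size >= 2 else 0.0

    rise = _rise_dynamics(tr, yr, amp)
    # recovery: the time-reversed fall is a rise from end SBP back to peak
    t_rev = tf[-1] - tf[::-1]
    y_rev = yf[::-1]
    fall = _rise_dynamics(t_rev, y_rev, fall_range)

    dr = np.diff(yr)
    df = np.diff(yf)
    dtr = np.diff(tr)
    dtf = np.diff(tf)

    vals = {
        "react_onset_slope": rise["onset_slope"],
        "react_diff_sd": rise["diff_sd"],
        "react_max_accel": rise["max_accel"],
        "react_t25": rise["t25"],
        "react_t75": rise["t75"],
        "react_t_ratio": rise["t_ratio"],
        "react_reversals": rise["reversals"],
        "react_prestart_range": pre_range,
        "recov_offset_slope": -_ls_slope(tf[:5], yf[:5]),
        "recov_diff_sd": fall["diff_sd"],
        "recov_max_accel": fall["max_accel"],
        "recov_t25": fall["t25"],
        "recov_t75": fall["t75"],
        "recov_t_ratio": fall["t_ratio"],
        "recov_reversals": fall["reversals"],
        "recov_undershoot": max(0.0, start_sbp - end_sbp),
        "amp_surge": amp,
        "amp_peak_sbp": peak_sbp,
        "amp_start_sbp": start_sbp,
        "amp_end_sbp": end_sbp,
        "amp_relative_pct": 100.0 * amp / start_sbp,
        "amp_max_beat_rise": float(np.max(np.diff(y))),
        "amp_area_above_start": _area_above(t, y, start_sbp),
        "amp_peak_above_median": peak_sbp - night_median,
        "up_duration": up_dur,
        "up_mean_slope": amp / up_dur if up_dur > 0 else 0.0,
        "up_max_beat_slope": float(np.max(dr / dtr)) if dr.size else 0.0,
        "up_beat_count": float(tr.size),
        "up_rising_fraction": float(np.mean(dr > 0)) if dr.size else 0.0,
        "up_area_above_start": _area_above(tr, yr, start_sbp),
        "up_t50": _first_crossing_time(tr, yr, start_sbp + 0.5 * amp),
        "up_ls_slope": _ls_slope(tr, yr),
        "down_duration": down_dur,
        "down_mean_slope": fall_range / down_dur if down_dur > 0 else 0.0,
        "down_max_beat_slope": float(np.max(-df / dtf)) if df.size else 0.0,
        "down_beat_count": float(tf.size),
        "down_falling_fraction": float(np.mean(df < 0)) if df.size else 0.0,
        "down_area_above_end": _area_above(tf, yf, end_sbp),
        "down_t50": _fall_crossing_time(tf, yf, peak_sbp, fall_range),
        "down_ls_slope": -_ls_slope(tf, yf),
        "whole_duration": float(t[-1] - t[0]),
        "whole_up_down_ratio": up_dur / down_dur if down_dur > 0 else 1.0,
        "whole_beat_count": float(t.size),
        "whole_mean_sbp": float(np.mean(y)),
        "whole_sbp_sd": float(np.std(y)),
        "whole_symmetry": (
            min(up_dur, down_dur) / max(up_dur, down_dur)
            if max(up_dur, down_dur) > 0 else 1.0
        ),
        "whole_t_above_half": _time_above(t, y, start_sbp + 0.5 * amp),
        "whole_mean_beat_interval": float((t[-1] - t[0]) / (t.size - 1)),
    }
    return FeatureVector(vals)


def extract_feature_matrix(series: BeatSeries,
                           cands: Sequence[SurgeAnnotation]):
    """Feature vectors for many candidates as a pandas DataFrame (one row
    per candidate, catalogue column order)."""
    import pandas as pd

    v = series.valid_indices
    med = float(np.median(series.sbp_mmHg[v])) if v.size else 0.0
    rows = [extract_features(series, c, night_median=med).values
            for c in cands]
    return pd.DataFrame(rows, columns=_NAMES)
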