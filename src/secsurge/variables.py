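"""Nocturnal BP variables: conventional (intermittent cuff) and sec-surge.

Conventional variables summarize the every-30-min cuff SBP readings the way
the blood-pressure-variability literature does: mean, SD, coefficient of
variation (CV = 100·SD/mean), and average real variability (ARV, the mean
absolute successive difference).  Sec-surge variables summarize detected or
labelled surges per night — peak SBP, amplitude (peak − start SBP), and
upward/downward/total durations — overall and split into sleep-apnea
related vs non-SA surges by temporal association with PSG events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence

import numpy as np

from .types import BeatSeries, IntermittentSeries, PsgEvent, SurgeAnnotation

__all__ = [
    "ConventionalVariables",
    "ClassSummary",
    "SurgeVariables",
    "conventional_variables",
    "surge_variables",
    "categorize_sa",
]


@dataclass
class ConventionalVariables:
    mean_sbp: float
    sd_sbp: float
    cv_sbp_percent: float
    arv_sbp: float

    def as_dict(self) -> dict:
        return asdict(self)


def conventional_variables(readings: IntermittentSeries,
                           ddof: int = 1) -> ConventionalVariables:
    """Mean, SD (sample by default), CV, and ARV of intermittent SBP.

    Requires at least two readings; ``ddof=0`` switches to population SD.
    """
    y = np.asarray(readings.sbp_mmHg, dtype=float)
    if y.size < 2:
        raise ValueError(
            f"{readings.night_id}: need >= 2 readings, got {y.size}"
        )
    mean = float(np.mean(y))
    sd = float(np.std(y, ddof=ddof))
    cv = 100.0 * sd / mean if mean > 0 else 0.0
    arv = float(np.mean(np.abs(np.diff(y))))
    return ConventionalVariables(mean_sbp=mean, sd_sbp=sd,
                                 cv_sbp_percent=cv, arv_sbp=arv)


@dataclass
class ClassSummary:
    """Per-night surge summary for one class (or all surges)."""

    n_surges: int
    mean_peak: Optional[float]
    max_peak: Optional[float]
    mean_amplitude: Optional[float]
    mean_upward_duration_s: Optional[float]
    mean_downward_duration_s: Optional[float]
    mean_total_duration_s: Optional[float]

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SurgeVariables:
    overall: ClassSummary
    sa: ClassSummary
    non_sa: ClassSummary

    def as_dict(self) -> dict:
        return {"overall": self.overall.as_dict(),
                "sa": self.sa.as_dict(),
                "non_sa": self.non_sa.as_dict()}


def _summary(series: BeatSeries,
             surges: Sequence[SurgeAnnotation]) -> ClassSummary:
    if not surges:
        return ClassSummary(0, None, None, None, None, None, None)
    t = series.time_s
    y = series.sbp_mmHg
    peaks = np.array([y[s.peak_idx] for s in surges])
    amps = np.array([y[s.peak_idx] - y[s.start_idx] for s in surges])
    up = np.array([t[s.peak_idx] - t[s.start_idx] for s in surges])
    down = np.array([t[s.end_idx] - t[s.peak_idx] for s in surges])
    return ClassSummary(
        n_surges=len(surges),
        mean_peak=float(peaks.mean()),
        max_peak=float(peaks.max()),
        mean_amplitude=float(amps.mean()),
        mean_upward_duration_s=float(up.mean()),
        mean_downward_duration_s=float(down.mean()),
        mean_total_duration_s=float((up + down).mean()),
    )


def surge_variables(series: BeatSeries,
                    surges: Sequence[SurgeAnnotation]) -> SurgeVariables:
    """Night summary of surge severity, overall and per SA class.

    Per surge: peak = SBP at the peak beat, amplitude = peak − start SBP,
    upward duration = t(peak) − t(start), downward = t(end) − t(peak).
    Empty classes report ``None`` means, never zeros.
    """
    for s in surges:
        s.validate_against(series)
    return SurgeVariables(
        overall=_summary(series, list(surges)),
        sa=_summary(series, [s for s in surges if s.sa_class == "sa"]),
        non_sa=_summary(series, [s for s in surges if s.sa_class == "non_sa"]),
    )


def categorize_sa(surges: Sequence[SurgeAnnotation],
                  events: Sequence[PsgEvent],
                  series: BeatSeries,
                  window_s: float = 30.0) -> List[SurgeAnnotation]:
    """Classify each surge as SA-related or not by PSG-event association.

    A surge is ``sa`` iff some apnea/hypopnea/desaturation event overlaps
    the window [start_time − window_s, peak_time]; otherwise ``non_sa``.
    Input order is preserved; ``sa_class`` is overwritten.
    """
    t = series.time_s
    out: List[SurgeAnnotation] = []
    for s in surges:
        lo = t[s.start_idx] - window_s
        hi = t[s.peak_idx]
        hit = any(ev.start_s <= hi and ev.end_s >= lo for ev in events
                  if ev.night_id == s.night_id)
        out.append(s.with_class("sa" if hit else "non_sa"))
    return out
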