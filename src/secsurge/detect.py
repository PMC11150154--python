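"""Candidate sec-surge extraction from a beat-by-beat SBP series.

Three steps, composed by :func:`detect_candidates`:

1. :func:`find_candidate_peaks` — local maxima of the SBP train under a
   time-based sliding window (beat intervals are irregular, so the window is
   in seconds, not beats).
2. :func:`locate_start` — walk backward from the peak to the end of the
   stable pre-surge SBP plateau.
3. :func:`locate_end` — walk forward to the first beat where SBP has decayed
   by ``decay_fraction`` (default 75%) of the amplitude below the peak.

Beats flagged ``artifact``/``gap`` are transparent: they are skipped, never
compared.  A silent gap longer than ``gap_split_s`` splits the night into
segments processed independently.
"""

from __future__ import annotations

import logging
import warnings
from typing import List, NamedTuple

import numpy as np

from .config import DetectorConfig
from .types import BeatSeries, CandidateSurge

__all__ = [
    "find_candidate_peaks",
    "locate_start",
    "locate_end",
    "detect_candidates",
    "TruncatedCandidateError",
]

log = logging.getLogger(__name__)


class TruncatedCandidateError(ValueError):
    """A candidate peak sits at a segment boundary and cannot be delimited."""


class StartResult(NamedTuple):
    index: int
    fallback: bool


class EndResult(NamedTuple):
    index: int
    fallback: bool


def _segments(series: BeatSeries, gap_split_s: float) -> List[np.ndarray]:
    """Indices of valid beats, split wherever consecutive valid beats are
    more than ``gap_split_s`` apart."""
    v = series.valid_indices
    if v.size == 0:
        return []
    t = series.time_s[v]
    cut = np.flatnonzero(np.diff(t) > gap_split_s) + 1
    return [seg for seg in np.split(v, cut) if seg.size > 0]


class _SparseMax:
    """O(n log n) range-maximum table over a 1-D array (inclusive queries)."""

    def __init__(self, y: np.ndarray):
        n = y.size
        levels = max(1, int(np.floor(np.log2(max(n, 1)))) + 1)
        self.table = [np.asarray(y, dtype=float)]
        for k in range(1, levels):
            prev = self.table[-1]
            half = 1 << (k - 1)
            if prev.size <= half:
                break
            self.table.append(np.maximum(prev[:-half], prev[half:]))

    def query(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        span = hi - lo + 1
        k = np.floor(np.log2(span)).astype(int)
        out = np.empty(lo.size, dtype=float)
        for kk in np.unique(k):
            m = k == kk
            tb = self.table[kk]
            left = tb[lo[m]]
            right = tb[hi[m] - (1 << int(kk)) + 1]
            out[m] = np.maximum(left, right)
        return out


def find_candidate_peaks(series: BeatSeries,
                         config: DetectorConfig | None = None) -> List[int]:
    """Sliding-window local maxima of valid-beat SBP; candidate surge peaks.

    A valid beat qualifies iff it is the earliest beat attaining the maximum
    SBP over the valid beats within ``window_s`` centered on it, and at
    least one valid beat in that window lies strictly below it (so a fully
    flat window yields nothing).  Returned indices address the full series
    and are strictly increasing.
    """
    config = config or DetectorConfig()
    if series.duration_s < config.window_s:
        warnings.warn(
            f"{series.night_id}: series shorter than the sliding window; "
            "no candidate peaks"
        )
        return []
    half = config.window_s / 2.0
    peaks: List[int] = []
    for seg in _segments(series, config.gap_split_s):
        t = series.time_s[seg]
        y = series.sbp_mmHg[seg]
        lo = np.searchsorted(t, t - half, side="left")
        hi = np.searchsorted(t, t + half, side="right") - 1
        wmax = _SparseMax(y).query(lo, hi)
        for i in np.flatnonzero(y >= wmax):
            win = y[lo[i]:hi[i] + 1]
            j = lo[i] + int(np.argmax(win))      # earliest argmax
            if j != i:
                continue
            if not np.any(win < y[i]):           # fully tied window
                continue
            peaks.append(int(seg[i]))
    return sorted(peaks)


def locate_start(series: BeatSeries, peak: int,
                 config: DetectorConfig | None = None) -> StartResult:
    """Find the surge start: the end of the stable pre-surge SBP plateau.

    Walking backward from the peak (over valid beats, within
    ``max_lookback_s``), returns the latest beat ``s`` such that

    * the ``stability_beats`` valid beats ending at ``s`` span an SBP range
      of at most ``stability_range_mmHg``, and
    * ``sbp[s] <= sbp[peak] - min_amplitude_mmHg`` — i.e. the plateau sits
      below the surge, not on its shoulder or flat top.

    If no such beat exists the start falls back to the minimum-SBP valid
    beat within the lookback span (``fallback=True``).
    """
    config = config or DetectorConfig()
    v = series.valid_indices
    pos = int(np.searchsorted(v, peak))
    if pos >= v.size or v[pos] != peak:
        raise ValueError(f"peak index {peak} is not a valid beat")
    t = series.time_s
    y = series.sbp_mmHg
    peak_t = t[peak]
    peak_sbp = y[peak]
    lo_pos = int(np.searchsorted(t[v], peak_t - config.max_lookback_s,
                                 side="left"))
    if pos == 0 or lo_pos >= pos:
        raise TruncatedCandidateError(
            f"{series.night_id}: no valid beats before peak at beat {peak}"
        )
    k = config.stability_beats
    ceiling = peak_sbp - config.min_amplitude_mmHg
    for q in range(pos - 1, lo_pos - 1, -1):
        if y[v[q]] > ceiling:
            continue
        if q - k + 1 < 0:
            continue
        win = y[v[q - k + 1:q + 1]]
        if win.max() - win.min() <= config.stability_range_mmHg:
            return StartResult(int(v[q]), False)
    span = v[lo_pos:pos]
    return StartResult(int(span[np.argmin(y[span])]), True)


def locate_end(series: BeatSeries, start: int, peak: int,
               config: DetectorConfig | None = None) -> EndResult:
    """Find the surge end: first valid beat past the peak whose SBP has
    decayed by ``decay_fraction`` of the amplitude, searching at most
    ``max_recovery_s`` forward; falls back to the minimum-SBP beat in that
    span when the decay threshold is never crossed."""
    config = config or DetectorConfig()
    y = series.sbp_mmHg
    t = series.time_s
    amplitude = y[peak] - y[start]
    if not start < peak:
        raise ValueError("start must precede peak")
    if amplitude <= 0:
        raise ValueError("candidate amplitude must be positive")
    threshold = y[peak] - config.decay_fraction * amplitude
    v = series.valid_indices
    pos = int(np.searchsorted(v, peak))
    hi_pos = int(np.searchsorted(t[v], t[peak] + config.max_recovery_s,
                                 side="right"))
    span = v[pos + 1:hi_pos]
    if span.size == 0:
        raise TruncatedCandidateError(
            f"{series.night_id}: no valid beats after peak at beat {peak}"
        )
    below = y[span] <= threshold
    if np.any(below):
        return EndResult(int(span[np.argmax(below)]), False)
    return EndResult(int(span[np.argmin(y[span])]), True)


def detect_candidates(series: BeatSeries,
                      config: DetectorConfig | None = None
                      ) -> List[CandidateSurge]:
    """Compose peak finding, start, and end location into candidate surges.

    Candidates below ``min_amplitude_mmHg`` are discarded, as are
    fallback-delimited candidates whose interval swallows a neighbouring
    candidate's peak.  Where two surviving intervals still overlap beyond a
    shared boundary, the smaller-amplitude one is dropped.  Output is
    sorted by start index and deterministic.
    """
    config = config or DetectorConfig()
    config.validate()
    y = series.sbp_mmHg
    raw: List[CandidateSurge] = []
    for peak in find_candidate_peaks(series, config):
        try:
            s = locate_start(series, peak, config)
            e = locate_end(series, s.index, peak, config)
        except TruncatedCandidateError:
            log.info("%s: truncated candidate at beat %d discarded",
                     series.night_id, peak)
            continue
        amplitude = float(y[peak] - y[s.index])
        if amplitude < config.min_amplitude_mmHg:
            continue
        raw.append(CandidateSurge(
            night_id=series.night_id,
            start_idx=s.index, peak_idx=peak, end_idx=e.index,
            amplitude_mmHg=amplitude,
            start_fallback=s.fallback, end_fallback=e.fallback,
        ))
    raw.sort(key=lambda c: c.peak_idx)
    # fallback-delimited candidates must not swallow a neighbour's peak
    peaks = [c.peak_idx for c in raw]
    kept = []
    for c in raw:
        if c.start_fallback or c.end_fallback:
            if any(c.start_idx <= p <= c.end_idx and p != c.peak_idx
                   for p in peaks):
                continue
        kept.append(c)
    # resolve residual overlaps: drop the smaller-amplitude candidate
    changed = True
    while changed:
        changed = False
        out: List[CandidateSurge] = []
        for c in kept:
            if out and c.start_idx < out[-1].end_idx:
                prev = out[-1]
                if c.amplitude_mmHg > prev.amplitude_mmHg:
                    out[-1] = c
                changed = True
            else:
                out.append(c)
        kept = out
    return sorted(kept, key=lambda c: c.start_idx)
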