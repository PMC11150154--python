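"""Candidate extraction: sliding-window peaks, start/end location, and
equivalence with brute-force oracles on random series."""

import numpy as np
import pytest

from secsurge import (
    BeatSeries,
    DetectorConfig,
    SimConfig,
    detect_candidates,
    find_candidate_peaks,
    generate_night,
    locate_end,
    locate_start,
)

from conftest import make_series, triangular_bump


# ---------------------------------------------------------------------------
# independent brute-force oracles (full O(n*w) rescans)

def _same_segment(t, valid, i, j, config):
    lo, hi = min(i, j), max(i, j)
    seg = [k for k in valid if lo <= k <= hi]
    return all(t[b] - t[a] <= config.gap_split_s
               for a, b in zip(seg, seg[1:]))


def brute_peaks(series, config):
    t, y, q = series.time_s, series.sbp_mmHg, series.quality
    valid = np.flatnonzero(q == "valid")
    out = []
    half = config.window_s / 2
    if series.duration_s < config.window_s:
        return out
    for i in valid:
        win = [j for j in valid if t[i] - half <= t[j] <= t[i] + half
               and _same_segment(t, valid, i, j, config)]
        others = [j for j in win if j != i]
        if not others:
            continue
        if any(y[j] > y[i] for j in others):
            continue
        if any(y[j] == y[i] and j < i for j in others):
            continue
        if all(y[j] == y[i] for j in others):
            continue
        out.append(int(i))
    return out


def brute_start(series, peak, config):
    t, y = series.time_s, series.sbp_mmHg
    valid = np.flatnonzero(series.quality == "valid")
    before = [j for j in valid
              if j < peak and t[peak] - t[j] <= config.max_lookback_s]
    k = config.stability_beats
    for s in sorted(before, reverse=True):
        if y[s] > y[peak] - config.min_amplitude_mmHg:
            continue
        window = [j for j in valid if j <= s][-k:]
        if len(window) < k:
            continue
        vals = [y[j] for j in window]
        if max(vals) - min(vals) <= config.stability_range_mmHg:
            return s, False
    return min(before, key=lambda j: (y[j], j)), True


def brute_end(series, start, peak, config):
    t, y = series.time_s, series.sbp_mmHg
    valid = np.flatnonzero(series.quality == "valid")
    thr = y[peak] - config.decay_fraction * (y[peak] - y[start])
    after = [j for j in valid
             if j > peak and t[j] - t[peak] <= config.max_recovery_s]
    for e in after:
        if y[e] <= thr:
            return e, False
    return min(after, key=lambda j: (y[j], j)), True


# ---------------------------------------------------------------------------
# sliding-window peak finding

class TestFindCandidatePeaks:
    def test_constant_series_has_no_peaks(self):
        s = make_series(np.full(300, 120.0))
        assert find_candidate_peaks(s) == []

    def test_single_bump_yields_the_apex(self):
        s, apex = triangular_bump()
        assert find_candidate_peaks(s) == [apex]

    def test_two_separated_bumps_in_time_order(self):
        base = np.full(800, 120.0)
        for at in (200, 500):
            base[at - 30:at] = np.linspace(120, 150, 31)[1:]
            base[at:at + 45] = np.linspace(150, 120, 46)[1:]
        s = make_series(base)
        peaks = find_candidate_peaks(s)
        assert len(peaks) == 2 and peaks[0] < peaks[1]

    def test_short_series_warns_and_returns_empty(self):
        s = make_series([120.0, 130.0, 120.0])
        with pytest.warns(UserWarning, match="shorter than"):
            assert find_candidate_peaks(s) == []

    def test_plateau_returns_earliest_tied_beat(self):
        sbp = np.r_[np.full(100, 120.0), [150.0] * 5, np.full(100, 120.0)]
        s = make_series(sbp)
        assert find_candidate_peaks(s) == [100]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(150, 400))
        t = np.cumsum(rng.uniform(0.5, 1.5, n))
        y = np.round(120 + rng.normal(0, 8, n), 1)
        quality = rng.choice(["valid", "valid", "valid", "artifact"], n)
        s = BeatSeries("rand", t, np.clip(y, 31, 299), quality=quality)
        cfg = DetectorConfig(window_s=float(rng.integers(20, 80)))
        assert find_candidate_peaks(s, cfg) == brute_peaks(s, cfg)


# ---------------------------------------------------------------------------
# start location

class TestLocateStart:
    def test_flat_then_steep_rise_starts_at_last_flat_beat(self):
        sbp = np.r_[np.full(60, 120.0), np.arange(130, 151, 10.0),
                    np.full(60, 120.0)]
        # beats 60,61,62 = 130,140,150: rise of 10 mmHg/beat
        s = make_series(sbp)
        res = locate_start(s, 62)
        assert res.index == 59 and not res.fallback

    def test_monotone_rise_from_onset_falls_back_to_minimum(self):
        sbp = np.r_[np.linspace(110, 160, 90), np.full(30, 160.0)]
        s = make_series(sbp)
        res = locate_start(s, 89)
        assert res.fallback
        assert s.sbp_mmHg[res.index] == s.sbp_mmHg[:89].min()

    def test_artifact_beat_in_plateau_is_transparent(self):
        sbp = np.r_[np.full(60, 120.0), np.arange(130, 151, 10.0),
                    np.full(60, 120.0)]
        clean = make_series(sbp)
        spiked = sbp.copy()
        spiked[50] = 210.0
        quality = np.full(sbp.size, "valid", dtype=object)
        quality[50] = "artifact"
        s = make_series(spiked, quality=quality)
        assert locate_start(s, 62).index == locate_start(clean, 62).index

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_backward_scan_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        y = 120 + rng.normal(0, 6, 300)
        y[200:220] += np.linspace(0, 30, 20)
        y[220] = y.max() + 5
        s = make_series(np.round(y, 1))
        got = locate_start(s, 220)
        want = brute_start(s, 220, DetectorConfig())
        assert (got.index, got.fallback) == want


# ---------------------------------------------------------------------------
# end location

class TestLocateEnd:
    def test_75_percent_decay_rule(self):
        # start 120, peak 140 -> amplitude 20 -> end at first beat <= 125
        sbp = np.r_[np.full(30, 120.0), [140.0],
                    np.linspace(139, 121, 19), np.full(30, 120.0)]
        s = make_series(sbp)
        res = locate_end(s, 29, 30)
        assert not res.fallback
        assert s.sbp_mmHg[res.index] <= 125.0
        assert np.all(s.sbp_mmHg[31:res.index] > 125.0)

    def test_immediate_crossing_at_next_beat(self):
        sbp = np.r_[np.full(30, 120.0), [140.0, 118.0], np.full(30, 120.0)]
        s = make_series(sbp)
        assert locate_end(s, 29, 30).index == 31

    def test_sustained_plateau_falls_back_to_minimum(self):
        sbp = np.r_[np.full(30, 120.0), [140.0], np.full(250, 138.0)]
        sbp[100] = 133.0
        s = make_series(sbp)
        res = locate_end(s, 29, 30)
        assert res.fallback and res.index == 100

    def test_peak_at_final_beat_raises(self):
        from secsurge.detect import TruncatedCandidateError
        sbp = np.r_[np.full(30, 120.0), [140.0]]
        s = make_series(sbp)
        with pytest.raises(TruncatedCandidateError):
            locate_end(s, 29, 30)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        y = 120 + rng.normal(0, 5, 300)
        y[100] = 155.0
        s = make_series(np.round(y, 1))
        got = locate_end(s, 60, 100)
        want = brute_end(s, 60, 100, DetectorConfig())
        assert (got.index, got.fallback) == want


# ---------------------------------------------------------------------------
# composition

class TestDetectCandidates:
    def test_noise_free_night_recovers_every_planted_peak(
            self, quiet_sim_config):
        series, labels, _ = generate_night(quiet_sim_config, seed=3)
        cands = detect_candidates(series)
        assert len(cands) == len(labels)
        assert [c.peak_idx for c in cands] == [a.peak_idx for a in labels]

    def test_subthreshold_bump_is_rejected(self):
        s, _ = triangular_bump(baseline=120, peak=128)  # amplitude 8 < 15
        assert detect_candidates(s) == []

    def test_empty_night_yields_nothing(self):
        s = make_series(np.full(600, 120.0))
        assert detect_candidates(s) == []

    def test_end_satisfies_decay_inequality_when_not_fallback(self):
        series, _, _ = generate_night(SimConfig(), seed=7)
        cfg = DetectorConfig()
        y = series.sbp_mmHg
        cands = detect_candidates(series, cfg)
        assert cands, "expected candidates on a default night"
        for c in cands:
            if not c.end_fallback:
                thr = y[c.peak_idx] - cfg.decay_fraction * c.amplitude_mmHg
                assert y[c.end_idx] <= thr

    def test_amplitudes_meet_the_floor(self):
        series, _, _ = generate_night(SimConfig(), seed=8)
        cfg = DetectorConfig()
        for c in detect_candidates(series, cfg):
            assert c.amplitude_mmHg >= cfg.min_amplitude_mmHg

    def test_candidates_do_not_overlap(self):
        series, _, _ = generate_night(SimConfig(), seed=9)
        cands = detect_candidates(series)
        for a, b in zip(cands, cands[1:]):
            assert a.end_idx <= b.start_idx

    def test_raising_amplitude_floor_never_adds_candidates(self):
        series, _, _ = generate_night(SimConfig(), seed=10)
        counts = [len(detect_candidates(
            series, DetectorConfig(min_amplitude_mmHg=m)))
            for m in (15.0, 20.0, 25.0, 30.0)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic(self):
        series, _, _ = generate_night(SimConfig(), seed=11)
        assert detect_candidates(series) == detect_candidates(series)
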