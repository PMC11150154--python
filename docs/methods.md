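# Methods

This note defines the algorithms implemented by `secsurge` precisely enough
to re-implement them. All pressures are systolic (SBP, mmHg), all times in
seconds; a *night* is a strictly time-ordered beat series with per-beat
quality flags (`valid`, `artifact`, `gap`). Every computation below uses
valid beats only; runs of valid beats separated by more than `gap_split_s`
(default 10 s) are treated as independent segments.

## 1. Candidate extraction

A candidate sec-surge is found in three steps, controlled by
`DetectorConfig`.

**Peak search.** A valid beat *i* is a candidate peak iff, among the valid
beats of its segment within ±`window_s`/2 (default ±30 s) of *i*, (a) no
beat is strictly higher, (b) no earlier beat ties it, and (c) at least one
beat is strictly lower. Condition (b) breaks plateau ties toward the
earliest beat; condition (c) makes a constant window yield nothing.
Windowed maxima are computed with a sparse-table range-maximum structure, so
the search is O(n log n) per night with time-based (not count-based)
windows.

**Start search.** From each peak the algorithm walks backward through the
valid beats of the segment, at most `max_lookback_s` (120 s), and takes the
*latest* beat *s* such that

1. `sbp[s] ≤ sbp[peak] − min_amplitude_mmHg` (the beat sits below the surge
   — without this qualifier the beats just under a smooth, flat-topped apex
   are themselves "stable" and the start would collapse onto the peak), and
2. the trailing `stability_beats` (10) valid beats ending at *s* span a
   range ≤ `stability_range_mmHg` (5 mmHg).

If no beat qualifies, the minimum-SBP beat in the lookback window is used
and the candidate is flagged `start_fallback`.

**End search.** The surge ends at the first valid beat after the peak, at
most `max_recovery_s` (180 s) ahead, with

`sbp[end] ≤ sbp[peak] − decay_fraction · (sbp[peak] − sbp[start])`,

i.e. a 75% amplitude decay by default. If SBP never decays that far, the
minimum-SBP beat in the recovery window is used and the candidate is flagged
`end_fallback`.

Candidates with amplitude `sbp[peak] − sbp[start]` below
`min_amplitude_mmHg` (15 mmHg) are discarded. When fallback boundaries make
one candidate swallow a neighbouring peak, or two candidate intervals
overlap, the smaller-amplitude candidate is dropped, so emitted candidates
are disjoint and time-ordered.

## 2. Features

Each candidate is summarized by exactly 48 features in 6 groups of 8:
**reactivity** (rise shape: onset slope, successive-difference SD, maximal
acceleration, times to 25%/75% amplitude and their ratio, reversal count,
pre-start range), **recovery** (the same shape metrics on the time-reversed
fall, plus undershoot below the start), **amplitude** (surge amplitude,
peak/start/end SBP, relative amplitude, maximal single-beat rise,
pressure-time area above the start, peak above the night median),
**upward** and **downward** (durations, mean/max/least-squares slopes, beat
counts, monotonicity fractions, areas, half-amplitude crossing times), and
**whole** (total duration, up/down ratio and symmetry, beat count, segment
mean/SD, interpolated time above half amplitude, mean beat interval). The
catalogue (`feature_catalogue()`) fixes names, definitions, and the
behaviour of every feature under time dilation and uniform pressure shifts;
the test suite enforces these covariances.

## 3. Rule learning

The classifier that separates true surges from blood-pressure-variability
look-alikes is a conjunction of 1–6 threshold conditions
(`X ≥ A` or `X ≤ A`, inclusive), with at most one condition per feature
group. Training data are candidates extracted from labelled nights, marked
positive iff they match an expert label (matcher of §4).

1. **Threshold sweep.** For each feature and direction, every distinct
   observed value is tried as a threshold and scored by
   F = 2TP / (2TP + FP + FN); ties prefer the smaller positive region.
   Implemented with a sort + cumulative sums, O(n log n) per feature.
2. **Feature selection.** Per group, the best (feature, direction) by swept
   F; groups whose best F falls below 0.5 are dropped; survivors are ranked
   by F and capped at 6.
3. **Joint grid search.** Each selected feature gets a threshold grid: its
   5th–95th percentile values at 19 evenly spaced quantile levels, plus a
   fully permissive sentinel (the training minimum) that lets the search
   deactivate the condition. The Cartesian product of grids is searched
   *exhaustively*: candidates are binned per grid, positives and negatives
   histogrammed on the joint bin lattice, and k-dimensional suffix sums
   yield TP and FP for every threshold combination simultaneously. The
   F-optimal combination wins; ties prefer more true positives, then the
   most permissive thresholds. Conditions left at the sentinel are pruned.
   If 6 groups survive, the grid is automatically coarsened (13 steps) to
   keep the search within a 10⁷-combination budget.

The result is a `DecisionRule` a reader can audit directly, e.g.
`amp_surge ≥ 17.6 AND whole_sbp_sd ≥ 4.3`.

## 4. Matching and evaluation

A detection matches a label when its **peak time** falls inside the label's
[start, end] interval widened by `tolerance_s` (10 s) on each side; matching
is greedy, one-to-one, in time order. Matched pairs are TP, unmatched
detections FP, unmatched labels FN; recall = TP/(TP+FN), precision =
TP/(TP+FP), and F is their harmonic mean (empty denominators score 1; F is 0
when P + R = 0). Peak containment rather than interval overlap is used
because start/end placement is the main point of disagreement between
algorithms and human labelers, while peak location is stable.

Cross-validation partitions **nights** (never beats or candidates) into k
near-equal folds after a seeded shuffle; for each fold the rule is re-fitted
on the remaining nights' pooled candidates and scored on the held-out
nights, pooling counts within the fold (sum TP/FP/FN, then ratio). The
report carries per-fold recall/precision and their mean ± sample SD.

## 5. Severity and conventional variables

Per night, detected (or labelled) surges are summarized by count, mean and
max peak SBP, mean amplitude, and mean upward/downward/total durations —
overall and split into **SA-related** vs **non-SA** surges. A surge is
SA-related iff an apnea, hypopnea, or desaturation PSG event overlaps the
window [start − 30 s, peak]. Conventional nocturnal variables computed from
intermittent cuff readings are the mean, SD, coefficient of variation
(100·SD/mean), and average real variability (mean absolute successive
difference).

## 6. Synthetic night generator

Clinical beat-by-beat recordings with expert labels are not freely
available, so the package ships a calibrated generator
(`generate_night(config, seed)`), deterministic given its seed:

- a ~1 Hz beat train with Gaussian interval jitter over 7 h;
- a sinusoidal baseline drift (amplitude 5 mmHg, period 90 min, random
  phase) around a 122.2 mmHg nocturnal baseline;
- planted surges with raised-cosine rise (10–40 s) and fall (15–60 s),
  amplitudes from a truncated Normal(26.0, 4.3) on [15, 60] mmHg — so the
  mean planted peak sits near 148.2 mmHg — with Poisson counts of
  SA-related (rate 19.5/night) and non-SA (16.4/night) surges; each
  SA surge is preceded by a PSG event ending 10 s before its onset;
- sub-threshold "confuser" bumps of the same shape (5–12 mmHg, 30/night)
  that the amplitude criterion must reject;
- per-beat Gaussian noise (SD 2 mmHg) and occasional 1–3-beat artifact
  spikes (±30–80 mmHg) flagged `artifact`.

Surge annotations (start/peak/end beat indices, SA class) are derived from
the clean, pre-noise signal, so the planted labels are exact. Events are
placed by rejection sampling with exclusion zones sized so surges do not
overlap each other's detection context; a pathologically dense draw raises
`NightTooCrowdedError` rather than emitting a distorted night. An
`generate_intermittent` helper derives every-30-min cuff-like readings as
windowed medians of the beat series.

## 7. Known limitations

- The start-search stability qualifier (§1) means surges rising out of a
  long monotone drift are assigned fallback starts; their amplitudes are
  conservative.
- The AND-rule family cannot express disjunctions; a surge class that needs
  "either fast rise or large area" is out of scope by design (auditability
  first).
- The generator plants at most one surge per exclusion zone, so compound
  (overlapping) surge complexes — which do occur physiologically — are not
  simulated.
- SA attribution is purely temporal (event within 30 s before the rise);
  no causal claim is made.
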