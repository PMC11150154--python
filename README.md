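# secsurge

Detection and quantification of **nocturnal blood-pressure surges in
seconds** ("sec-surges") from overnight beat-by-beat systolic blood-pressure
recordings.

## The problem

Continuous (beat-by-beat) blood-pressure measurement during sleep reveals
brief, acute BP elevations lasting several tens of seconds. These sec-surges
are typically triggered by obstructive sleep-apnea (OSA) episodes or
spontaneous sympathetic bursts, and their frequency and severity carry
cardiovascular-risk information that conventional every-30-minute cuff
readings cannot see. Finding them by eye in a 25,000-beat night is not
practical, so this package provides:

- **Candidate extraction** (`detect`): sliding-window local-maximum search
  for surge peaks, a backward search for the last stable pre-surge beat
  (the start), and a forward search for the first beat at which SBP has
  decayed by 75% of the surge amplitude (the end).
- **A 48-feature description** (`features`): every candidate is summarized
  by exactly 48 interpretable features in 6 groups of 8 — reactivity,
  recovery, amplitude, upward limb, downward limb, and whole event — each a
  one-line formula over the beats of the candidate.
- **Auditable rule learning** (`rulelearn`): from expert-labelled nights the
  package learns a conjunction ("AND-rule") of at most 6 per-feature
  threshold conditions, at most one per feature group, by per-feature
  F-measure threshold sweeps followed by an exhaustive grid search over
  joint threshold combinations. The resulting rule is a handful of
  physician-readable inequalities, not a black box.
- **Evaluation** (`evaluate`): greedy one-to-one matching of detected peaks
  to label intervals (±10 s tolerance), recall/precision/F, and night-level
  k-fold cross-validation.
- **Severity variables** (`variables`): per-night surge statistics (peak
  SBP, amplitude, durations) overall and split into sleep-apnea-related vs
  non-SA surges by temporal association with polysomnography (PSG) events,
  plus conventional nocturnal BP-variability metrics (mean, SD, CV, ARV)
  from intermittent cuff readings.
- **A calibrated synthetic-night generator** (`simulate`): deterministic,
  seed-driven overnight recordings with planted surges, PSG events,
  sub-threshold confuser bumps, beat noise, and flagged motion artifacts,
  so the whole pipeline is testable without clinical data.

See [docs/methods.md](docs/methods.md) for the precise algorithm
definitions.

## Worked example

```python
from secsurge import (SimConfig, categorize_sa, detect_candidates,
                      evaluate_nights, generate_night, surge_variables,
                      train_detector)

# 1. Three labelled synthetic training nights + one held-out night
train_nights = []
for seed in range(3):
    series, labels, events = generate_night(SimConfig(), seed)
    train_nights.append((series, labels))
test_series, test_labels, test_events = generate_night(SimConfig(), 3)
print(f"held-out night: {test_series.n_beats} beats, "
      f"{len(test_labels)} labelled surges, {len(test_events)} PSG events")

# 2. Candidate extraction alone (no classifier yet)
cands = detect_candidates(test_series)
print(f"candidate surges on the held-out night: {len(cands)}")

# 3. Train the AND-rule classifier on the three labelled nights
model = train_detector(train_nights)
print(f"learned rule (training F = {model.rule.training_f:.3f}):")
for c in model.rule.conditions:
    op = ">=" if c.direction == "ge" else "<="
    print(f"  {c.feature_name} {op} {c.threshold:.2f}")

# 4. Score the model on the held-out night
report = evaluate_nights(model, [(test_series, test_labels)])
print(f"held-out: TP={report.tp} FP={report.fp} FN={report.fn} "
      f"recall={report.recall:.3f} precision={report.precision:.3f}")

# 5. Severity variables, split by sleep-apnea association
surges = categorize_sa(test_labels, test_events, test_series)
sv = surge_variables(test_series, surges)
print(f"SA surges: n={sv.sa.n_surges} mean_peak={sv.sa.mean_peak:.1f} "
      f"mean_amplitude={sv.sa.mean_amplitude:.1f}")
print(f"non-SA surges: n={sv.non_sa.n_surges} "
      f"mean_peak={sv.non_sa.mean_peak:.1f} "
      f"mean_amplitude={sv.non_sa.mean_amplitude:.1f}")
```

Output (deterministic for these seeds):

```text
held-out night: 25192 beats, 31 labelled surges, 12 PSG events
candidate surges on the held-out night: 52
learned rule (training F = 0.995):
  amp_surge >= 17.63
  whole_sbp_sd >= 4.26
held-out: TP=30 FP=1 FN=1 recall=0.968 precision=0.968
SA surges: n=12 mean_peak=149.8 mean_amplitude=25.9
non-SA surges: n=19 mean_peak=147.1 mean_amplitude=25.4
```

## Command-line interface

The same pipeline is available as the `secsurge` command:

```bash
secsurge simulate --nights 20 --seed 0 --out-dir data/      # synthetic nights
secsurge train    --manifest data/manifest.json --out model.json
secsurge detect   --series data/sim-3.csv --model model.json --out det.tsv
secsurge evaluate --detections det.tsv --labels data/sim-3.labels.tsv \
                  --series data/sim-3.csv --out eval.json
secsurge crossval --manifest data/manifest.json --k 5 --out cv.json
secsurge variables --series data/sim-3.csv --detections det.tsv \
                   --psg data/sim-3.psg.tsv \
                   --intermittent data/sim-3.cuff.csv --out vars.json
```

Every command writes a `<out>.run.json` record (command, config hash, seed,
stage counts) next to its output for provenance. All stage parameters can be
overridden with a YAML config passed via `--config`; see
`secsurge.config.PipelineConfig` for the available keys and defaults.

## File formats

- **Beat series** (CSV): `time_s,sbp[,dbp][,quality]`; strictly increasing
  time, `quality ∈ {valid, artifact, gap}`.
- **Annotations / detections** (TSV): `night_id,start_s,peak_s,end_s[,class]`
  with times in seconds; they are snapped to the nearest valid beat on load.
- **PSG events** (TSV): `night_id,kind,start_s,end_s` with
  `kind ∈ {apnea, hypopnea, desaturation}`.
- **Intermittent cuff readings** (CSV): `time_s,sbp`.

## Reproduction

All tests and the acceptance report run entirely on synthetic data generated
at run time — no data files are needed.

```bash
pip install --no-build-isolation -e ".[test]"
python -m pytest -q tests/                 # full suite, ~1-2 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script trains and cross-validates the detector on a fresh
20-night synthetic benchmark and measures the generator's surge-severity
calibration over ≥ 200 planted sleep-apnea surges; it writes a JSON report
with mean cross-validated recall (`t2`) and precision (`t3`) and the mean
planted-surge amplitude (`t4`, mmHg) and peak SBP (`t5`, mmHg). Typical
values for `--seed 1`: recall ≈ 0.99, precision ≈ 0.99, amplitude ≈ 26.6,
peak ≈ 148.2. Everything is deterministic given the seed.
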