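"""Rule learning: threshold sweeps vs enumeration, exhaustive grid search vs
brute force, planted-rule recovery, and end-to-end training invariances."""

import itertools

import numpy as np
import pandas as pd
import pytest

from secsurge import (
    Condition,
    DecisionRule,
    SimConfig,
    apply_rule,
    feature_catalogue,
    generate_night,
    grid_search_rule,
    save_model,
    load_model,
    select_features,
    sweep_threshold,
    train_detector,
)
from secsurge.config import LearnerConfig
from secsurge.rulelearn import UnlearnableError, build_grids, fit_rule

_NAMES = [s.name for s in feature_catalogue()]


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_sweep(values, labels, direction):
    """Enumerate every distinct threshold; return the best F and the
    tie-broken threshold (smallest positive region)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    best = (-1.0, None)
    thr_candidates = np.unique(values)
    order = thr_candidates[::-1] if direction == "ge" else thr_candidates
    for thr in order:
        pred = values >= thr if direction == "ge" else values <= thr
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = int((~pred & labels).sum())
        denom = 2 * tp + fp + fn
        f = 2 * tp / denom if denom else 0.0
        if f > best[0]:
            best = (f, float(thr))
    return best[1], best[0]


def brute_grid(features, labels, selected, grids):
    """Enumerate the full Cartesian grid; return the maximal F."""
    labels = np.asarray(labels, bool)
    keys = []
    for name, direction in selected:
        key = features[name].to_numpy(float)
        keys.append(key if direction == "ge" else -key)
    best = -1.0
    for combo in itertools.product(*grids):
        pred = np.ones(labels.size, bool)
        for key, thr in zip(keys, combo):
            pred &= key >= thr
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = int(labels.sum()) - tp
        denom = 2 * tp + fp + fn
        f = 2 * tp / denom if denom else 0.0
        best = max(best, f)
    return best


def _random_frame(rng, n):
    """A 48-column frame of noise with a couple of structured columns."""
    return pd.DataFrame(rng.normal(size=(n, 48)), columns=_NAMES)


# ---------------------------------------------------------------------------
# threshold sweep

class TestSweepThreshold:
    def test_hand_example(self):
        # positives at 10,12,14,16; negatives at 1,2,3,11.
        # thr=10 captures 4 TP and 1 FP: F = 8/(8+1+0) = 8/9, the optimum.
        values = [10, 12, 14, 16, 1, 2, 3, 11]
        labels = [True] * 4 + [False] * 4
        thr, f = sweep_threshold(values, labels, "ge")
        assert thr == 10.0
        assert f == pytest.approx(8 / 9)

    def test_separable_reaches_f_one(self):
        values = [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]
        labels = [True] * 3 + [False] * 3
        thr, f = sweep_threshold(values, labels, "ge")
        assert f == 1.0 and 3.0 < thr <= 5.0

    def test_le_direction_mirrors_ge(self):
        values = [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]
        labels = [False] * 3 + [True] * 3
        thr, f = sweep_threshold(values, labels, "le")
        assert f == 1.0 and 3.0 <= thr < 5.0

    def test_no_positives_raises(self):
        with pytest.raises(UnlearnableError):
            sweep_threshold([1.0, 2.0], [False, False], "ge")

    def test_all_positive_trivial_threshold(self):
        thr, f = sweep_threshold([1.0, 2.0, 3.0], [True] * 3, "ge")
        assert f == 1.0 and thr <= 1.0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(5, 40))
        values = np.round(rng.normal(size=n), 2)  # force ties
        labels = rng.random(n) < 0.4
        if not labels.any():
            labels[0] = True
        for direction in ("ge", "le"):
            thr, f = sweep_threshold(values, labels, direction)
            _, f_oracle = brute_sweep(values, labels, direction)
            assert f == pytest.approx(f_oracle)
            # the returned threshold must achieve the optimum itself
            pred = values >= thr if direction == "ge" else values <= thr
            tp = int((pred & labels).sum())
            fp = int((pred & ~labels).sum())
            fn = int(labels.sum()) - tp
            assert 2 * tp / (2 * tp + fp + fn) == pytest.approx(f_oracle)


# ---------------------------------------------------------------------------
# feature selection

class TestSelectFeatures:
    def test_groups_unique_and_ranked(self):
        rng = np.random.default_rng(0)
        feats = _random_frame(rng, 300)
        labels = feats["amp_surge"].to_numpy() > 1.0
        feats.loc[labels, "up_duration"] += 3.0  # second informative group
        selected = select_features(feats, labels)
        names = [n for n, _ in selected]
        groups = [next(s.group for s in feature_catalogue() if s.name == n)
                  for n in names]
        assert len(set(groups)) == len(groups)
        assert "amp_surge" in names

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(1)
        feats = _random_frame(rng, 400)
        labels = rng.random(400) < 0.15  # independent of every column
        with pytest.raises(UnlearnableError, match="no discriminative"):
            select_features(feats, labels)


# ---------------------------------------------------------------------------
# grid search

class TestGridSearch:
    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(20, 80))
        feats = _random_frame(rng, n)
        labels = rng.random(n) < 0.35
        if not labels.any():
            labels[0] = True
        selected = [("amp_surge", "ge"), ("up_duration", "le")]
        config = LearnerConfig(grid_steps=5)
        rule = grid_search_rule(feats, labels, selected, config,
                                prune_inactive=False)
        grids = build_grids(feats, selected, config)
        assert rule.training_f == pytest.approx(
            brute_grid(feats, labels, selected, grids))

    def test_planted_two_condition_rule_recovered(self):
        rng = np.random.default_rng(7)
        n = 500
        feats = _random_frame(rng, n)
        feats["amp_surge"] = rng.uniform(0, 1, n)
        feats["up_duration"] = rng.uniform(0, 1, n)
        labels = ((feats["amp_surge"].to_numpy() >= 0.6)
                  & (feats["up_duration"].to_numpy() <= 0.4))
        rule = fit_rule(feats, labels)
        # quantile grids need not contain the exact planted thresholds,
        # so training F can fall just short of 1
        assert rule.training_f >= 0.95
        by_name = {c.feature_name: c for c in rule.conditions}
        assert set(by_name) == {"amp_surge", "up_duration"}
        # thresholds within one grid step (0.05 quantile spacing on U(0,1))
        step = 0.07
        amp = by_name["amp_surge"]
        dur = by_name["up_duration"]
        assert amp.direction == "ge" and abs(amp.threshold - 0.6) <= step
        assert dur.direction == "le" and abs(dur.threshold - 0.4) <= step

    def test_adding_a_condition_never_widens_the_rule(self):
        rng = np.random.default_rng(11)
        feats = _random_frame(rng, 200)
        one = DecisionRule([Condition("amp_surge", "ge", 0.0)])
        two = DecisionRule([Condition("amp_surge", "ge", 0.0),
                            Condition("up_duration", "le", 0.5)])
        assert not np.any(apply_rule(two, feats) & ~apply_rule(one, feats))

    def test_boundary_is_inclusive(self):
        feats = pd.DataFrame(np.zeros((3, 48)), columns=_NAMES)
        feats["amp_surge"] = [1.0, 2.0, 3.0]
        rule = DecisionRule([Condition("amp_surge", "ge", 2.0)])
        assert apply_rule(rule, feats).tolist() == [False, True, True]
        rule = DecisionRule([Condition("amp_surge", "le", 2.0)])
        assert apply_rule(rule, feats).tolist() == [True, True, False]

    def test_rule_construction_invariants(self):
        with pytest.raises(ValueError, match="between 1 and 6"):
            DecisionRule([])
        with pytest.raises(ValueError, match="duplicate"):
            DecisionRule([Condition("amp_surge", "ge", 1.0),
                          Condition("amp_peak_sbp", "ge", 1.0)])
        with pytest.raises(ValueError, match="unknown feature"):
            Condition("not_a_feature", "ge", 1.0)


# ---------------------------------------------------------------------------
# end-to-end training

def _short_nights(seeds, cfg=None):
    cfg = cfg or SimConfig(duration_s=10800.0, sa_surge_rate_per_night=5.0,
                           nonsa_surge_rate_per_night=4.0,
                           confuser_rate_per_night=6.0,
                           artifact_rate_per_night=2.0)
    out = []
    for seed in seeds:
        series, labels, _ = generate_night(cfg, seed)
        out.append((series, labels))
    return out


class TestTrainDetector:
    def test_deterministic_and_order_invariant(self):
        nights = _short_nights([31, 32, 33])
        a = train_detector(nights)
        b = train_detector(nights)
        c = train_detector(nights[::-1])
        assert a.rule == b.rule == c.rule

    def test_training_f_is_high_on_synthetic_nights(self):
        model = train_detector(_short_nights([41, 42, 43]))
        assert model.rule.training_f >= 0.8
        assert 1 <= len(model.rule.conditions) <= 6

    def test_no_labels_raises(self):
        cfg = SimConfig(duration_s=3600.0, sa_surge_rate_per_night=0.0,
                        nonsa_surge_rate_per_night=0.0,
                        confuser_rate_per_night=0.0,
                        artifact_rate_per_night=0.0)
        nights = _short_nights([51], cfg)
        with pytest.raises(ValueError, match="no labels"):
            train_detector(nights)

    def test_model_round_trip(self, tmp_path):
        model = train_detector(_short_nights([61, 62]))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.rule == model.rule
        assert back.detector == model.detector
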