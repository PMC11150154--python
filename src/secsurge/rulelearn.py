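"""Supervised acquisition of the AND-rule sec-surge classifier.

The classifier is a conjunction of per-feature threshold conditions
(``X >= A`` or ``X <= A``), at most one per feature group, kept deliberately
simple so a physician can audit the learned rule.  Learning proceeds in
three stages:

1. :func:`sweep_threshold` — for each feature, scan every distinct observed
   value as a threshold and score it by F-measure (the harmonic mean of
   recall and precision over labelled candidates);
2. :func:`select_features` — keep the best feature per group, dropping
   groups whose best F falls below a floor, so the rule covers distinct
   clinical perspectives without duplicating a category;
3. :func:`grid_search_rule` — exhaustively search the Cartesian product of
   per-feature quantile grids for the jointly F-optimal threshold
   combination.

The exhaustive search is made cheap by binning candidates onto the grids
and taking multi-dimensional suffix sums of the positive/negative
histograms, which yields TP and FP for *every* combination at once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DetectorConfig, LearnerConfig, MatchConfig
from .detect import detect_candidates
from .features import extract_feature_matrix, feature_catalogue, feature_group
from .types import BeatSeries, SurgeAnnotation

__all__ = [
    "Condition",
    "DecisionRule",
    "TrainedModel",
    "sweep_threshold",
    "select_features",
    "build_grids",
    "grid_search_rule",
    "apply_rule",
    "train_detector",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

_CATALOGUE_NAMES = [s.name for s in feature_catalogue()]


class UnlearnableError(ValueError):
    """No positive labels, or no feature clears the inclusion floor."""


class GridTooLargeError(ValueError):
    """The joint threshold grid exceeds the exhaustive-search budget."""


@dataclass(frozen=True)
class Condition:
    """One conjunct: ``feature >= threshold`` (ge) or ``feature <= threshold``
    (le), inclusive at the boundary."""

    feature_name: str
    direction: str           # "ge" | "le"
    threshold: float

    def __post_init__(self):
        if self.feature_name not in _CATALOGUE_NAMES:
            raise ValueError(f"unknown feature {self.feature_name!r}")
        if self.direction not in ("ge", "le"):
            raise ValueError(f"direction must be 'ge' or 'le'")

    def holds(self, values: np.ndarray) -> np.ndarray:
        if self.direction == "ge":
            return np.asarray(values) >= self.threshold
        return np.asarray(values) <= self.threshold


@dataclass
class DecisionRule:
    """Conjunction of 1-6 conditions with pairwise-distinct feature groups."""

    conditions: List[Condition]
    training_f: float = 0.0

    def __post_init__(self):
        if not 1 <= len(self.conditions) <= 6:
            raise ValueError("a rule needs between 1 and 6 conditions")
        groups = [feature_group(c.feature_name) for c in self.conditions]
        if len(set(groups)) != len(groups):
            raise ValueError("rule conditions must not duplicate a feature group")
        if not 0.0 <= self.training_f <= 1.0:
            raise ValueError("training_f must be in [0, 1]")


def _f_measure(tp: float, fp: float, fn: float) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def sweep_threshold(values: Sequence[float], labels: Sequence[bool],
                    direction: str) -> Tuple[float, float]:
    """Best single-feature threshold by F-measure.

    Every distinct observed value is a candidate threshold; the returned
    threshold maximizes F = 2PR/(P+R), ties resolved toward the smaller
    positive region (larger ge-threshold / smaller le-threshold).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.size != labels.size or values.size == 0:
        raise ValueError("values and labels must be equal-length, non-empty")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UnlearnableError("unlearnable feature: no positive labels")
    key = values if direction == "ge" else -values
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    # sort descending by key: prefix of the sorted order is the positive
    # region for threshold = k-th key
    order = np.argsort(-key, kind="stable")
    ks = key[order]
    ls = labels[order]
    cum_tp = np.cumsum(ls)
    cum_n = np.arange(1, ks.size + 1)
    # last index of each run of equal keys = inclusive-threshold region
    last = np.flatnonzero(np.r_[ks[1:] != ks[:-1], True])
    tp = cum_tp[last]
    npred = cum_n[last]
    fp = npred - tp
    fn = n_pos - tp
    f = 2 * tp / (2 * tp + fp + fn)
    best_f = f.max()
    # ties -> smallest positive region -> earliest in descending-key order
    i = int(np.argmax(f >= best_f))
    thr_key = ks[last[i]]
    thr = float(thr_key if direction == "ge" else -thr_key)
    return thr, float(best_f)


def select_features(features: pd.DataFrame, labels: Sequence[bool],
                    config: LearnerConfig | None = None
                    ) -> List[Tuple[str, str]]:
    """Per group, the single best (feature, direction) by swept F-measure.

    Groups below ``min_single_feature_f`` are dropped; the survivors are
    returned in descending-F order, capped at ``max_conditions``.
    """
    config = config or LearnerConfig()
    labels = np.asarray(labels, dtype=bool)
    best_per_group: Dict[str, Tuple[float, int, str, str]] = {}
    for idx, spec in enumerate(feature_catalogue()):
        vals = features[spec.name].to_numpy()
        scored = []
        for direction in ("ge", "le"):
            _, fm = sweep_threshold(vals, labels, direction)
            scored.append((fm, direction))
        fm, direction = max(scored, key=lambda s: (s[0], s[1] == "ge"))
        cur = best_per_group.get(spec.group)
        # higher F wins; ties go to the earlier catalogue entry
        if cur is None or fm > cur[0]:
            best_per_group[spec.group] = (fm, idx, spec.name, direction)
    kept = [v for v in best_per_group.values()
            if v[0] >= config.min_single_feature_f]
    if not kept:
        raise UnlearnableError(
            "no discriminative features: every group's best F is below "
            f"{config.min_single_feature_f}"
        )
    kept.sort(key=lambda v: (-v[0], v[1]))
    return [(name, direction) for _, _, name, direction in
            kept[:config.max_conditions]]


def build_grids(features: pd.DataFrame,
                selected: Sequence[Tuple[str, str]],
                config: LearnerConfig | None = None,
                grid_steps: int | None = None) -> List[np.ndarray]:
    """Per-feature threshold grids on the *key* scale (ge: value, le: -value).

    Each grid is the configured quantile levels of the key over training
    candidates, with a fully-permissive sentinel (the training minimum)
    prepended so the joint search can deactivate the condition; duplicates
    are removed.  Grids are ascending: index 0 is the most permissive.
    """
    config = config or LearnerConfig()
    steps = grid_steps if grid_steps is not None else config.grid_steps
    lo, hi = config.grid_quantile_range
    levels = np.linspace(lo, hi, steps)
    grids = []
    for name, direction in selected:
        key = features[name].to_numpy(dtype=float)
        if direction == "le":
            key = -key
        thr = np.quantile(key, levels)
        grid = np.unique(np.r_[key.min(), thr])
        grids.append(grid)
    return grids


def grid_search_rule(features: pd.DataFrame, labels: Sequence[bool],
                     selected: Sequence[Tuple[str, str]],
                     config: LearnerConfig | None = None,
                     grid_steps: int | None = None,
                     prune_inactive: bool = True) -> DecisionRule:
    """Exhaustive search over the Cartesian product of per-feature grids for
    the threshold combination maximizing the F-measure of the AND-rule.

    Tie-break: higher recall (more true positives), then the most
    permissive thresholds (lexicographically smallest grid indices).
    Conditions that come out at the fully-permissive sentinel are vacuous
    on the training data and are pruned unless ``prune_inactive=False``.
    """
    config = config or LearnerConfig()
    labels = np.asarray(labels, dtype=bool)
    if not selected:
        raise ValueError("empty feature selection")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UnlearnableError("unlearnable: no positive labels")
    grids = build_grids(features, selected, config, grid_steps)
    total = int(np.prod([g.size for g in grids]))
    if total > config.max_grid_combinations:
        raise GridTooLargeError(
            f"joint grid has {total} combinations "
            f"(> {config.max_grid_combinations}); use fewer conditions or a "
            "coarser grid"
        )
    # bin each candidate onto each grid: passes grid[j] iff bin > j
    bins = []
    for (name, direction), grid in zip(selected, grids):
        key = features[name].to_numpy(dtype=float)
        if direction == "le":
            key = -key
        bins.append(np.searchsorted(grid, key, side="right"))
    shape = tuple(g.size + 1 for g in grids)
    hist_pos = np.zeros(shape, dtype=np.int32)
    hist_neg = np.zeros(shape, dtype=np.int32)
    coords = tuple(b for b in bins)
    pos_coords = tuple(b[labels] for b in bins)
    neg_coords = tuple(b[~labels] for b in bins)
    np.add.at(hist_pos, pos_coords, 1)
    np.add.at(hist_neg, neg_coords, 1)
    for axis in range(len(grids)):       # suffix sums along every axis
        hist_pos = np.flip(np.cumsum(np.flip(hist_pos, axis), axis=axis), axis)
        hist_neg = np.flip(np.cumsum(np.flip(hist_neg, axis), axis=axis), axis)
    inner = tuple(slice(1, None) for _ in grids)
    tp = hist_pos[inner]
    fp = hist_neg[inner]
    fn = n_pos - tp
    with np.errstate(invalid="ignore"):
        f = np.where(2 * tp + fp + fn > 0,
                     2 * tp / np.maximum(2 * tp + fp + fn, 1), 0.0)
    best_f = f.max()
    mask = f == best_f
    best_tp = tp[mask].max()
    mask &= tp == best_tp
    flat = int(np.argmax(mask.ravel(order="C")))
    jstar = np.unravel_index(flat, f.shape)
    conditions = []
    for (name, direction), grid, j in zip(selected, grids, jstar):
        thr_key = float(grid[j])
        active = j > 0 or not prune_inactive
        if active:
            thr = thr_key if direction == "ge" else -thr_key
            conditions.append(Condition(name, direction, thr))
    if not conditions:
        # every condition vacuous (e.g. all candidates positive): keep the
        # top-ranked feature at its sentinel so the rule is well-formed
        name, direction = selected[0]
        thr_key = float(grids[0][jstar[0]])
        thr = thr_key if direction == "ge" else -thr_key
        conditions = [Condition(name, direction, thr)]
    return DecisionRule(conditions=conditions, training_f=float(best_f))


def apply_rule(rule: DecisionRule, features: pd.DataFrame) -> np.ndarray:
    """Boolean per-candidate classification by the AND of all conditions."""
    if not rule.conditions:
        raise ValueError("cannot apply an empty rule")
    out = np.ones(len(features), dtype=bool)
    for cond in rule.conditions:
        if cond.feature_name not in features.columns:
            raise ValueError(
                f"rule references unknown feature {cond.feature_name!r}"
            )
        out &= cond.holds(features[cond.feature_name].to_numpy(dtype=float))
    return out


# ---------------------------------------------------------------------------
# end-to-end training


@dataclass
class TrainedModel:
    """A fitted detector: candidate-extraction config plus decision rule."""

    detector: DetectorConfig
    rule: DecisionRule
    meta: dict = field(default_factory=dict)


def label_candidates(series: BeatSeries,
                     candidates: Sequence[SurgeAnnotation],
                     labels: Sequence[SurgeAnnotation],
                     match_config: MatchConfig | None = None) -> np.ndarray:
    """Mark each candidate positive iff it matches an expert label, using
    the same one-to-one peak-containment matcher as evaluation."""
    from .evaluate import match_detections

    match_config = match_config or MatchConfig()
    _, _, _, pairing = match_detections(list(candidates), list(labels),
                                        series, match_config)
    out = np.zeros(len(candidates), dtype=bool)
    for det_i, _ in pairing:
        out[det_i] = True
    return out


def _capped_grid_steps(n_conditions: int, config: LearnerConfig) -> int:
    """Largest per-feature step count whose joint grid (with sentinel) stays
    within the exhaustive-search budget."""
    steps = config.grid_steps
    while steps > 1 and (steps + 1) ** n_conditions > config.max_grid_combinations:
        steps -= 1
    return steps


def fit_rule(features: pd.DataFrame, labels: Sequence[bool],
             config: LearnerConfig | None = None) -> DecisionRule:
    """Feature selection followed by joint grid search, coarsening the grid
    if needed to keep the exhaustive search within budget."""
    config = config or LearnerConfig()
    selected = select_features(features, labels, config)
    steps = _capped_grid_steps(len(selected), config)
    if steps < config.grid_steps:
        log.info("coarsened threshold grid to %d steps for %d conditions",
                 steps, len(selected))
    return grid_search_rule(features, labels, selected, config,
                            grid_steps=steps)


def night_training_table(series: BeatSeries,
                         labels: Sequence[SurgeAnnotation],
                         detector: DetectorConfig | None = None,
                         matcher: MatchConfig | None = None):
    """Candidates, their feature matrix, and their label status for one
    night — the unit the trainer and cross-validator pool over."""
    detector = detector or DetectorConfig()
    cands = detect_candidates(series, detector)
    feats = extract_feature_matrix(series, cands)
    y = (label_candidates(series, cands, labels, matcher)
         if cands else np.zeros(0, dtype=bool))
    return cands, feats, y


def train_detector(nights: Sequence[Tuple[BeatSeries, Sequence[SurgeAnnotation]]],
                   detector: DetectorConfig | None = None,
                   learner: LearnerConfig | None = None,
                   matcher: MatchConfig | None = None) -> TrainedModel:
    """Fit the full model: extract candidates on every night, mark them
    against the expert labels, select features, and grid-search thresholds.
    """
    detector = detector or DetectorConfig()
    learner = learner or LearnerConfig()
    matcher = matcher or MatchConfig()
    if not nights:
        raise ValueError("no training nights")
    n_labels = sum(len(labels) for _, labels in nights)
    if n_labels == 0:
        raise ValueError("training nights contain no labels")
    frames, ys = [], []
    for series, labels in nights:
        _, feats, y = night_training_table(series, labels, detector, matcher)
        frames.append(feats)
        ys.append(y)
    features = pd.concat(frames, ignore_index=True)
    y = np.concatenate(ys) if ys else np.zeros(0, dtype=bool)
    if y.sum() == 0:
        raise ValueError(
            "detector misses all labels -- tune DetectorConfig"
        )
    rule = fit_rule(features, y, learner)
    meta = {
        "n_nights": len(nights),
        "n_candidates": int(len(features)),
        "n_positive": int(y.sum()),
        "n_labels": int(n_labels),
        "training_f": rule.training_f,
    }
    return TrainedModel(detector=detector, rule=rule, meta=meta)


# ---------------------------------------------------------------------------
# model (de)serialization


def save_model(model: TrainedModel, path) -> None:
    data = {
        "detector": asdict(model.detector),
        "rule": {
            "training_f": model.rule.training_f,
            "conditions": [asdict(c) for c in model.rule.conditions],
        },
        "meta": model.meta,
        "catalogue": _CATALOGUE_NAMES,
    }
    Path(path).write_text(json.dumps(data, indent=2))


def load_model(path) -> TrainedModel:
    data = json.loads(Path(path).read_text())
    if data.get("catalogue") != _CATALOGUE_NAMES:
        raise ValueError(f"{path}: model built against a different feature "
                         "catalogue")
    det = DetectorConfig(**data["detector"])
    rule = DecisionRule(
        conditions=[Condition(**c) for c in data["rule"]["conditions"]],
        training_f=data["rule"]["training_f"],
    )
    return TrainedModel(detector=det, rule=rule, meta=data.get("meta", {}))
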