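"""Detection-to-label matching, recall/precision/F, and night-level k-fold CV.

A detection matches a label when its peak time falls inside the label's
[start, end] interval widened by ``tolerance_s`` on each side; matching is
greedy, one-to-one, in time order.  Matched pairs are true positives,
unmatched detections false positives, unmatched labels false negatives.
Cross-validation partitions *nights* (never beats) into folds, trains the
rule on k-1 folds, and pools TP/FP/FN over the held-out nights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DetectorConfig, LearnerConfig, MatchConfig
from .types import BeatSeries, SurgeAnnotation

__all__ = [
    "EvalReport",
    "match_detections",
    "compute_metrics",
    "evaluate_nights",
    "cross_validate",
]

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """TP/FP/FN counts with the derived recall, precision, and F-measure;
    optionally per-fold metrics and their mean ± SD."""

    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f_measure: float
    per_fold: Optional[List[dict]] = None
    mean_sd: Optional[dict] = None

    def as_dict(self) -> dict:
        out = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "recall": self.recall, "precision": self.precision,
            "f_measure": self.f_measure,
        }
        if self.per_fold is not None:
            out["per_fold"] = self.per_fold
        if self.mean_sd is not None:
            out["mean_sd"] = self.mean_sd
        return out


def match_detections(detected: Sequence[SurgeAnnotation],
                     labels: Sequence[SurgeAnnotation],
                     series: BeatSeries,
                     config: MatchConfig | None = None
                     ) -> Tuple[int, int, int, List[Tuple[int, int]]]:
    """Greedy one-to-one matching of detections to labels on one night.

    Returns ``(tp, fp, fn, pairing)`` where pairing holds (detection-index,
    label-index) pairs into the *input* sequences.
    """
    config = config or MatchConfig()
    config.validate()
    for ann in list(detected) + list(labels):
        if ann.night_id != series.night_id:
            raise ValueError(
                f"annotation from night {ann.night_id!r} does not belong to "
                f"series {series.night_id!r}"
            )
    t = series.time_s
    tol = config.tolerance_s
    det_order = sorted(range(len(detected)),
                       key=lambda i: t[detected[i].peak_idx])
    lab_order = sorted(range(len(labels)),
                       key=lambda j: t[labels[j].start_idx])
    matched_labels = set()
    pairing: List[Tuple[int, int]] = []
    for i in det_order:
        peak_t = t[detected[i].peak_idx]
        for j in lab_order:
            if j in matched_labels:
                continue
            lo = t[labels[j].start_idx] - tol
            hi = t[labels[j].end_idx] + tol
            if lo <= peak_t <= hi:
                matched_labels.add(j)
                pairing.append((i, j))
                break
    tp = len(pairing)
    fp = len(detected) - tp
    fn = len(labels) - tp
    return tp, fp, fn, pairing


def compute_metrics(tp: int, fp: int, fn: int) -> EvalReport:
    """Recall = TP/(TP+FN), precision = TP/(TP+FP), F their harmonic mean.

    Empty denominators follow the usual conventions: recall and precision
    default to 1 when they have nothing to miss, F to 0 when P + R = 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    recall = tp / (tp + fn) if tp + fn > 0 else 1.0
    precision = tp / (tp + fp) if tp + fp > 0 else 1.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    return EvalReport(tp=tp, fp=fp, fn=fn, recall=recall,
                      precision=precision, f_measure=f)


def evaluate_nights(model,
                    nights: Sequence[Tuple[BeatSeries, Sequence[SurgeAnnotation]]],
                    matcher: MatchConfig | None = None) -> EvalReport:
    """Run a trained model over nights and pool TP/FP/FN against labels."""
    from .detect import detect_candidates
    from .features import extract_feature_matrix
    from .rulelearn import apply_rule

    matcher = matcher or MatchConfig()
    tp = fp = fn = 0
    for series, labels in nights:
        cands = detect_candidates(series, model.detector)
        if cands:
            feats = extract_feature_matrix(series, cands)
            keep = apply_rule(model.rule, feats)
            detections = [c for c, k in zip(cands, keep) if k]
        else:
            detections = []
        a, b, c, _ = match_detections(detections, list(labels), series, matcher)
        tp, fp, fn = tp + a, fp + b, fn + c
    return compute_metrics(tp, fp, fn)


def _fold_split(n: int, k: int, seed: int) -> List[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [f for f in np.array_split(perm, k)]


def cross_validate(nights: Sequence[Tuple[BeatSeries, Sequence[SurgeAnnotation]]],
                   k: int = 5, seed: int = 0,
                   detector: DetectorConfig | None = None,
                   learner: LearnerConfig | None = None,
                   matcher: MatchConfig | None = None) -> EvalReport:
    """k-fold cross-validation over nights.

    Nights are shuffled by ``seed`` and split into k near-equal folds
    (sizes differ by at most 1).  Each fold is scored with the rule trained
    on the other folds, pooling counts within the fold; the report carries
    per-fold recall/precision plus their mean ± SD (sample SD over folds).
    """
    from .rulelearn import fit_rule, night_training_table, apply_rule

    detector = detector or DetectorConfig()
    learner = learner or LearnerConfig()
    matcher = matcher or MatchConfig()
    n = len(nights)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    # candidate extraction and feature computation are fold-independent
    tables = [night_training_table(series, labels, detector, matcher)
              for series, labels in nights]
    folds = _fold_split(n, k, seed)
    per_fold: List[dict] = []
    tot_tp = tot_fp = tot_fn = 0
    for fold_id, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train_feats = pd.concat(
            [tables[i][1] for i in range(n) if i not in test_set],
            ignore_index=True)
        train_y = np.concatenate(
            [tables[i][2] for i in range(n) if i not in test_set])
        rule = fit_rule(train_feats, train_y, learner)
        tp = fp = fn = 0
        for i in sorted(test_set):
            series, labels = nights[i]
            cands, feats, _ = tables[i]
            if cands:
                keep = apply_rule(rule, feats)
                detections = [c for c, m in zip(cands, keep) if m]
            else:
                detections = []
            a, b, c, _ = match_detections(detections, list(labels), series,
                                          matcher)
            tp, fp, fn = tp + a, fp + b, fn + c
        rep = compute_metrics(tp, fp, fn)
        entry = {
            "fold": fold_id, "tp": tp, "fp": fp, "fn": fn,
            "recall": rep.recall if tp + fn > 0 else None,
            "precision": rep.precision if tp + fp > 0 else None,
            "training_f": rule.training_f,
        }
        if tp + fn == 0:
            warnings.warn(f"fold {fold_id} has no labels; excluded from "
                          "recall mean/SD")
        per_fold.append(entry)
        tot_tp, tot_fp, tot_fn = tot_tp + tp, tot_fp + fp, tot_fn + fn
    report = compute_metrics(tot_tp, tot_fp, tot_fn)
    recalls = [e["recall"] for e in per_fold if e["recall"] is not None]
    precisions = [e["precision"] for e in per_fold if e["precision"] is not None]

    def _ms(xs):
        if not xs:
            return None, None
        arr = np.asarray(xs, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    rm, rsd = _ms(recalls)
    pm, psd = _ms(precisions)
    report.per_fold = per_fold
    report.mean_sd = {
        "recall_mean": rm, "recall_sd": rsd,
        "precision_mean": pm, "precision_sd": psd,
    }
    return report
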