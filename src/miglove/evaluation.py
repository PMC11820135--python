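"""Binary classification metrics for the fist-vs-rest decoder.

F1 (positive class = fist, the minority/actionable class), Cohen's Kappa,
accuracy, ROC and AUC, and the 2x2 confusion matrix — all implemented
directly from their definitions so they can be verified against brute-force
oracles.  AUC uses trapezoidal integration of the threshold ROC, which
equals the probability that a random fist score exceeds a random rest score
with ties counted 1/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABELS", "MetricsReport", "confusion_matrix", "roc_curve",
    "summary_metrics", "mean_over_subjects",
]

LABELS = ("rest", "fist")   # row/column order of the confusion matrix


@dataclass
class MetricsReport:
    f1: float
    kappa: float
    accuracy: float
    auc: float | None
    confusion: np.ndarray                     # rows truth, cols prediction
    roc: list[tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "f1": self.f1, "kappa": self.kappa, "accuracy": self.accuracy,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "labels": list(LABELS),
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.roc, columns=["fpr", "tpr", "threshold"])


def _as_labels(seq: Sequence) -> list[str]:
    out = []
    for s in seq:
        s = str(s)
        if s not in LABELS:
            raise ValueError(f"label {s!r} not in {LABELS}")
        out.append(s)
    return out


def confusion_matrix(truth: Sequence, predicted: Sequence) -> np.ndarray:
    """2x2 counts, ``counts[t][p]``, rows/cols ordered (rest, fist)."""
    truth, predicted = _as_labels(truth), _as_labels(predicted)
    if len(truth) != len(predicted):
        raise ValueError(
            f"{len(truth)} truth labels vs {len(predicted)} predictions"
        )
    counts = np.zeros((2, 2), dtype=np.int64)
    idx = {l: i for i, l in enumerate(LABELS)}
    for t, p in zip(truth, predicted):
        counts[idx[t], idx[p]] += 1
    return counts


def roc_curve(scores: Sequence[float],
              truth: Sequence) -> list[tuple[float, float, float]]:
    """ROC points ``(fpr, tpr, threshold)`` from P(fist) scores.

    One point per distinct threshold, anchored at (0, 0) and (1, 1); both
    coordinates are non-decreasing.
    """
    truth = _as_labels(truth)
    scores = np.asarray(scores, dtype=np.float64)
    y = np.array([1 if t == "fist" else 0 for t in truth])
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes in the truth labels")
    order = np.argsort(-scores, kind="stable")
    points = [(0.0, 0.0, np.inf)]
    tp = fp = 0
    i = 0
    while i < len(order):
        thr = scores[order[i]]
        while i < len(order) and scores[order[i]] == thr:
            if y[order[i]] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((fp / n_neg, tp / n_pos, float(thr)))
    return points


def _auc_from_roc(roc: list[tuple[float, float, float]]) -> float:
    fpr = np.array([p[0] for p in roc])
    tpr = np.array([p[1] for p in roc])
    return float(np.trapezoid(tpr, fpr))


def summary_metrics(confusion: np.ndarray,
                    scores: Sequence[float] | None = None,
                    truth: Sequence | None = None) -> MetricsReport:
    """Full metric suite from a confusion matrix and (optionally) scores.

    Without scores the ROC/AUC are omitted (``auc=None``).  With a
    single-class truth the AUC is undefined and likewise reported as None.
    """
    confusion = np.asarray(confusion, dtype=np.int64)
    if confusion.shape != (2, 2) or np.any(confusion < 0):
        raise ValueError("confusion must be a non-negative 2x2 count matrix")
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    if scores is not None:
        if truth is None or len(scores) != len(truth):
            raise ValueError("scores and truth must be given together, "
                             "same length")
        if len(truth) != total:
            raise ValueError(
                f"confusion totals {total} but {len(truth)} scores given"
            )
    tn, fp_ = confusion[0]
    fn, tp = confusion[1]
    accuracy = (tn + tp) / total
    precision = tp / (tp + fp_) if tp + fp_ > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    p_o = accuracy
    marg_truth = confusion.sum(axis=1) / total
    marg_pred = confusion.sum(axis=0) / total
    p_e = float(marg_truth @ marg_pred)
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 0.0
    roc: list[tuple[float, float, float]] = []
    auc = None
    if scores is not None:
        truth_labels = _as_labels(truth)
        if len(set(truth_labels)) == 2:
            roc = roc_curve(scores, truth_labels)
            auc = _auc_from_roc(roc)
    return MetricsReport(float(f1), float(kappa), float(accuracy), auc,
                         confusion, roc)


def evaluate_predictions(truth: Sequence, predicted: Sequence,
                         scores: Sequence[float] | None = None) -> MetricsReport:
    """Convenience wrapper: confusion + summary in one call."""
    return summary_metrics(confusion_matrix(truth, predicted), scores, truth)


def mean_over_subjects(reports: Sequence[MetricsReport]) -> dict[str, float]:
    """Arithmetic mean of each scalar metric across per-subject reports."""
    if len(reports) == 0:
        raise ValueError("need at least one report to average")
    out: dict[str, float] = {}
    for key in ("f1", "kappa", "accuracy"):
        out[key] = float(np.mean([getattr(r, key) for r in reports]))
    aucs = [r.auc for r in reports if r.auc is not None]
    out["auc"] = float(np.mean(aucs)) if aucs else float("nan")
    return out
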