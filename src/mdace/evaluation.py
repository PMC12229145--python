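"""Classification metrics, ROC/AUC, and the fixed-specificity operating point.

Metrics follow the standard confusion-matrix definitions:

    Acc = (TP+TN) / (TP+TN+FP+FN)      Sn = TP / (TP+FN)
    Sp  = TN / (TN+FP)                 Pre = TP / (TP+FP)
    F1  = 2 * Pre * Sn / (Pre + Sn)

Predictions use the >=-threshold rule (score >= threshold => positive).
Ratios with a zero denominator are reported as 0 and flagged.  AUC is the
trapezoidal ROC integral (ties credited 1/2), equal to the probability that
a random positive outranks a random negative.

The fixed-specificity operating point picks the *smallest observed score*
whose achieved specificity is at least the target (default 0.900), i.e.
maximum sensitivity subject to the specificity constraint, with no
interpolation between ROC points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    """Threshold-level metrics plus AUC for one evaluated score set."""

    AUC: float
    Acc: float
    Sn: float
    Sp: float
    Pre: float
    F1: float
    threshold: float
    n_pos: int
    n_neg: int
    zero_denominator_flags: list[str]
    tie_handling: str = "trapezoid (ties credited 1/2)"

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _validate(labels, scores):
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise EvaluationError(f"length mismatch: {y.shape} labels vs {s.shape} scores")
    if not np.all(np.isfinite(s)):
        raise EvaluationError("scores must be finite")
    if not np.all((y == 0) | (y == 1)):
        raise EvaluationError("labels must be binary")
    return y, s


def confusion_counts(labels, scores, threshold: float) -> ConfusionCounts:
    """Count TP/TN/FP/FN under prediction = (score >= threshold)."""
    y, s = _validate(labels, scores)
    pred = s >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def metrics_from_counts(counts: ConfusionCounts) -> tuple[dict[str, float], list[str]]:
    """(Acc, Sn, Sp, Pre, F1) from counts; zero-denominator ratios -> 0, flagged."""
    if counts.total == 0:
        raise EvaluationError("all counts are zero")
    flags: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    acc = (counts.TP + counts.TN) / counts.total
    sn = ratio(counts.TP, counts.TP + counts.FN, "Sn")
    sp = ratio(counts.TN, counts.TN + counts.FP, "Sp")
    pre = ratio(counts.TP, counts.TP + counts.FP, "Pre")
    f1 = ratio(2 * pre * sn, pre + sn, "F1")
    return {"Acc": acc, "Sn": sn, "Sp": sp, "Pre": pre, "F1": f1}, flags


def roc_auc(labels, scores) -> float:
    """Trapezoidal ROC AUC; ties between classes credited 1/2."""
    y, s = _validate(labels, scores)
    if len(np.unique(y)) < 2:
        raise EvaluationError("AUC requires both classes present")
    return float(roc_auc_score(y, s))


def report_at_threshold(labels, scores, threshold: float) -> MetricReport:
    y, s = _validate(labels, scores)
    counts = confusion_counts(y, s, threshold)
    metrics, flags = metrics_from_counts(counts)
    return MetricReport(AUC=roc_auc(y, s), threshold=float(threshold),
                        n_pos=int(np.sum(y == 1)), n_neg=int(np.sum(y == 0)),
                        zero_denominator_flags=flags, **metrics)


def threshold_at_specificity(labels, scores,
                             target_sp: float = 0.900) -> tuple[float, MetricReport]:
    """Operating point with maximum sensitivity subject to Sp >= target_sp.

    Candidate thresholds are the observed score values (no interpolation).
    Among feasible thresholds the one maximizing Sn is chosen; Sn ties are
    broken toward higher achieved Sp, then toward the smaller threshold.
    Raises if no observed score reaches the target, naming the best
    achievable Sp.
    """
    if not (0 < target_sp < 1):
        raise EvaluationError("target specificity must lie in (0, 1)")
    y, s = _validate(labels, scores)
    if len(np.unique(y)) < 2:
        raise EvaluationError("need both classes present")
    neg = s[y == 0]
    pos = s[y == 1]
    best = None  # (Sn, Sp, -threshold)
    best_sp = -1.0
    for t in np.unique(s):
        sp = float(np.mean(neg < t))
        best_sp = max(best_sp, sp)
        if sp >= target_sp:
            sn = float(np.mean(pos >= t))
            key = (sn, sp, -float(t))
            if best is None or key > best:
                best = key
    if best is None:
        raise EvaluationError(
            f"specificity {target_sp} unreachable at observed scores; "
            f"max achievable Sp = {best_sp:.4f}")
    threshold = -best[2]
    return float(threshold), report_at_threshold(y, s, float(threshold))


def roc_points(labels, scores) -> np.ndarray:
    """(threshold, FPR, TPR) rows over all unique score thresholds, for CSV dumps."""
    y, s = _validate(labels, scores)
    rows = []
    for t in np.unique(s)[::-1]:
        c = confusion_counts(y, s, float(t))
        m, _ = metrics_from_counts(c)
        rows.append((float(t), 1.0 - m["Sp"], m["Sn"]))
    return np.array(rows)
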