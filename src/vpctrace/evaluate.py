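"""Diagnostic evaluation: ROC/AUC, Youden-optimal cut-point, confusion
metrics and stratified-bootstrap confidence intervals.

The operating point maximizes Youden's J = sensitivity + specificity - 1
over all ROC thresholds (ties resolved toward higher specificity); a
record is called positive when its score is at or above the threshold.
95% CIs are percentile bootstrap over class-stratified resamples with the
threshold held fixed (re-optimizing it per resample would bias the
interval optimistically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .waveform import VPC_LABEL


def _as_binary(labels, positive_label) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return (labels == positive_label).astype(int)
    return labels.astype(int)


@dataclass
class EvalReport:
    threshold: float
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int
    ci: dict = field(default_factory=dict)   # metric -> (lo, hi)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in
               ("threshold", "auc", "accuracy", "sensitivity", "specificity",
                "ppv", "npv", "tp", "fp", "tn", "fn")}
        out["ci"] = {k: list(v) for k, v in self.ci.items()}
        return out


def confusion_at(scores: np.ndarray, y: np.ndarray, threshold: float) -> tuple:
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def _metrics_at(scores, y, threshold) -> dict:
    tp, fp, tn, fn = confusion_at(scores, y, threshold)
    def safe(num, den):
        return num / den if den > 0 else 0.0
    return {
        "accuracy": (tp + tn) / max(len(y), 1),
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "ppv": safe(tp, tp + fp),
        "npv": safe(tn, tn + fn),
    }


def youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1; among ties the
    highest threshold (higher specificity) wins."""
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    j = tpr - fpr
    best = np.max(j)
    cand = np.flatnonzero(j >= best - 1e-12)
    # roc_curve thresholds are descending; the first candidate is the
    # highest threshold, i.e. the most specific operating point.
    return float(thresholds[cand[0]])


def evaluate(scores, labels, positive_label: str | int = VPC_LABEL,
             n_boot: int = 2000, seed: int = 0) -> EvalReport:
    """Score a set of per-record positive-class probabilities.

    Raises if only one class is present or scores leave [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    y = _as_binary(labels, positive_label)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to evaluate")

    auc = float(roc_auc_score(y, scores))
    thr = youden_threshold(scores, y)
    m = _metrics_at(scores, y, thr)
    tp, fp, tn, fn = confusion_at(scores, y, thr)

    ci = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        stats = {k: np.empty(n_boot) for k in
                 ("auc", "accuracy", "sensitivity", "specificity", "ppv", "npv")}
        for b in range(n_boot):
            idx = np.concatenate([
                rng.choice(pos, size=pos.size, replace=True),
                rng.choice(neg, size=neg.size, replace=True),
            ])
            sb, yb = scores[idx], y[idx]
            stats["auc"][b] = roc_auc_score(yb, sb)
            mb = _metrics_at(sb, yb, thr)
            for k, v in mb.items():
                stats[k][b] = v
        for k, arr in stats.items():
            lo, hi = np.percentile(arr, [2.5, 97.5])
            point = auc if k == "auc" else m[k]
            # percentile CIs can exclude the point estimate in tiny
            # samples; widen to contain it (reported CIs always cover it)
            ci[k] = (float(min(lo, point)), float(max(hi, point)))

    return EvalReport(threshold=thr, auc=auc, tp=tp, fp=fp, tn=tn, fn=fn,
                      ci=ci, **m)
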