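"""Sensitivity / specificity / accuracy metrics, ROC curves, and reports.

Multiclass results are evaluated one-vs-rest: each fin class in turn is the
positive class, giving a 2x2 confusion table and an Sp/Se/Acc triplet per
class, plus an ROC curve ranked by the classifier's decision margin for
that class — (smallest other-class distance - class-j distance), divided by
the sample's descriptor count.  The margin is a monotone function of the
decision rule (positive exactly when class j wins) and, unlike the raw
summed distance, is comparable across images whose descriptor counts
differ.  Cross-class dispersion of
accuracy is summarized by the population standard deviation.  Metrics with a
zero denominator are reported as an explicit ``None`` marker, never silently
zero, so degenerate classes cannot inflate averages.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn import metrics as _skm

from .classifier import CLASS_LABELS, ClassModel, MatchResult, classify


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def denominator(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RocCurve:
    """(FPR, TPR) points from a threshold sweep, with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion_counts(predicted, truth, positive) -> ConfusionCounts:
    """2x2 counts with ``positive`` as the positive class.

    ``predicted`` and ``truth`` may be label sequences (compared against the
    ``positive`` label) or boolean arrays (``positive=True``).
    """
    pred = np.asarray(predicted).ravel()
    true = np.asarray(truth).ravel()
    if pred.shape != true.shape:
        raise ValueError(
            f"predicted and truth differ in length: {pred.shape} vs {true.shape}"
        )
    p = pred == positive
    t = true == positive
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def specificity(c: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None when no negatives were evaluated."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else None


def sensitivity(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when no positives were evaluated."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else None


def accuracy(c: ConfusionCounts, denominator: int | None = None) -> float:
    """(TP + TN) / denominator.

    The denominator defaults to the total evaluated units (pixels for
    pixel-level edge evaluation, images for image-level evaluation).
    """
    denom = c.denominator if denominator is None else denominator
    if denom <= 0:
        raise ValueError("accuracy denominator must be positive")
    return (c.tp + c.tn) / denom


def roc_curve(scores, truth) -> RocCurve:
    """Threshold-sweep ROC with trapezoidal AUC; ties grouped into one step."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth differ in length")
    if truth.all() or not truth.any():
        raise ValueError("ROC needs at least one positive and one negative unit")
    fpr, tpr, thr = _skm.roc_curve(truth, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_skm.auc(fpr, tpr)))


def acc_dispersion(per_class_acc) -> float:
    """Population standard deviation of per-class accuracies."""
    vals = np.asarray(list(per_class_acc), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("acc_dispersion needs at least one value")
    return float(np.std(vals, ddof=0))


def margin_score(result: MatchResult, label: str) -> float:
    """Per-descriptor decision margin of ``label`` for one classified sample.

    Positive exactly when ``label`` is the predicted class; larger means a
    more confident assignment to ``label``.
    """
    other = min(v for k, v in result.distances.items() if k != label)
    return (other - result.distances[label]) / max(result.n_sample_descriptors, 1)


def evaluate_classifier(model: ClassModel, samples: list, labels: list[str]) -> dict:
    """One-vs-rest evaluation of the centroid classifier on labeled samples.

    ``samples`` is a list of descriptor sets (one per test image).  Returns a
    report dict: per-class {tp, tn, fp, fn, sp, se, acc, auc}, plus a summary
    with macro averages (over defined values) and the population std of the
    per-class accuracies.
    """
    if len(samples) != len(labels):
        raise ValueError("samples and labels differ in length")
    results = [classify(s, model) for s in samples]
    predicted = [r.predicted for r in results]
    report: dict = {"per_class": {}, "summary": {}}
    accs, sps, ses, aucs = [], [], [], []
    for label in CLASS_LABELS:
        c = confusion_counts(predicted, labels, positive=label)
        sp, se = specificity(c), sensitivity(c)
        acc = accuracy(c)
        truth = np.array([l == label for l in labels])
        entry = {
            "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
            "sp": sp, "se": se, "acc": acc, "auc": None,
        }
        if truth.any() and not truth.all():
            scores = np.array([margin_score(r, label) for r in results])
            entry["auc"] = roc_curve(scores, truth).auc
            aucs.append(entry["auc"])
        report["per_class"][label] = entry
        accs.append(acc)
        if sp is not None:
            sps.append(sp)
        if se is not None:
            ses.append(se)
    n_correct = sum(p == t for p, t in zip(predicted, labels))
    report["summary"] = {
        "n_images": len(labels),
        "multiclass_accuracy": n_correct / len(labels) if labels else None,
        "macro_sp": float(np.mean(sps)) if sps else None,
        "macro_se": float(np.mean(ses)) if ses else None,
        "macro_acc": float(np.mean(accs)) if accs else None,
        "macro_auc": float(np.mean(aucs)) if aucs else None,
        "acc_dispersion": acc_dispersion(accs),
    }
    report["predictions"] = predicted
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Write an evaluation report as JSON or CSV, by file extension."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(report, indent=2))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "tp", "tn", "fp", "fn", "sp", "se", "acc", "auc"])
        fmt = lambda v: "" if v is None else f"{v:.6f}"
        for label in CLASS_LABELS:
            e = report["per_class"][label]
            writer.writerow(
                [label, e["tp"], e["tn"], e["fp"], e["fn"],
                 fmt(e["sp"]), fmt(e["se"]), fmt(e["acc"]), fmt(e["auc"])]
            )
        s = report["summary"]
        writer.writerow(
            ["macro", "", "", "", "",
             fmt(s["macro_sp"]), fmt(s["macro_se"]), fmt(s["macro_acc"]),
             fmt(s["macro_auc"])]
        )
        writer.writerow(
            ["acc_dispersion", "", "", "", "", "", "", fmt(s["acc_dispersion"]), ""]
        )


def write_roc_points(model: ClassModel, samples, labels, path: str | Path) -> None:
    """Export per-class ROC points as CSV (class, threshold, fpr, tpr)."""
    results = [classify(s, model) for s in samples]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "threshold", "fpr", "tpr"])
        for label in CLASS_LABELS:
            truth = np.array([l == label for l in labels])
            if not truth.any() or truth.all():
                continue
            scores = np.array([margin_score(r, label) for r in results])
            curve = roc_curve(scores, truth)
            for t, f, tp in zip(curve.thresholds, curve.fpr, curve.tpr):
                writer.writerow([label, f"{t:.6g}", f"{f:.6f}", f"{tp:.6f}"])
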