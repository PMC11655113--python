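"""ROI-scoped pixel-wise evaluation: confusion counts, scalar metrics and
ROC-AUC, per class and pooled across images.

A true positive is a pixel inside the region of interest whose predicted
class equals the evaluated class and whose ground-truth class does too —
one-vs-rest at pixel granularity.  Undefined ratios (0/0) are reported as
NaN with a warning, never silently coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import ValidationError
from .masks_io import LabelMask

__all__ = [
    "ConfusionTable",
    "MetricReport",
    "confusion",
    "scalar_metrics",
    "roc_auc",
    "evaluate_pair",
    "report_to_jsonable",
]


@dataclass(frozen=True)
class ConfusionTable:
    """One-vs-rest pixel counts for one class inside an ROI."""

    class_id: int
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        if self.class_id != other.class_id:
            raise ValidationError("cannot pool tables for different classes")
        return ConfusionTable(
            self.class_id,
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricReport:
    """Scalar metrics for one class; `auc` stays None when no soft scores
    were supplied."""

    class_id: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    iou: float
    auc: float | None = None


def _roi_array(roi, shape) -> np.ndarray:
    if roi is None:
        return np.ones(shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != tuple(shape):
        raise ValidationError(f"ROI shape {roi.shape} != raster shape {shape}")
    if not roi.any():
        raise ValidationError("ROI selects no pixels")
    return roi


def confusion(
    pred: LabelMask,
    truth: LabelMask,
    roi: np.ndarray | None = None,
    class_id: int = 1,
) -> ConfusionTable:
    """Count one-vs-rest TP/FP/TN/FN over the ROI (full frame if absent)."""
    if pred.shape != truth.shape:
        raise ValidationError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    if class_id >= truth.n_classes:
        raise ValidationError(f"class_id {class_id} >= n_classes {truth.n_classes}")
    sel = _roi_array(roi, pred.shape)
    p = pred.labels[sel] == class_id
    t = truth.labels[sel] == class_id
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionTable(class_id, tp, fp, tn, fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (0/0) — reported as NaN", stacklevel=3)
        return float("nan")
    return num / den


def scalar_metrics(t: ConfusionTable) -> MetricReport:
    """Accuracy, precision, recall, F1 (harmonic mean) and IoU from counts.

    IoU for a one-vs-rest class is tp / (tp + fp + fn): the intersection of
    the predicted and true pixel sets over their union.
    """
    if t.total == 0:
        raise ValidationError("empty confusion table")
    acc = (t.tp + t.tn) / t.total
    prec = _ratio(t.tp, t.tp + t.fp, "precision")
    rec = _ratio(t.tp, t.tp + t.fn, "recall")
    if np.isnan(prec) or np.isnan(rec):
        f1 = float("nan")
    elif prec + rec == 0:
        warnings.warn("F1 undefined (precision = recall = 0) — reported as NaN",
                      stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * prec * rec / (prec + rec)
    iou = _ratio(t.tp, t.tp + t.fp + t.fn, "IoU")
    return MetricReport(t.class_id, acc, prec, rec, f1, iou)


def roc_auc(
    scores: np.ndarray,
    truth: LabelMask,
    roi: np.ndarray | None = None,
    class_id: int = 1,
) -> float:
    """Area under the ROC curve for per-pixel scores of one class.

    Equivalent to the Mann-Whitney statistic with ties counted one half;
    requires at least one positive and one negative pixel in the ROI.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != truth.shape:
        raise ValidationError(f"scores shape {scores.shape} != truth {truth.shape}")
    sel = _roi_array(roi, truth.shape)
    y = (truth.labels[sel] == class_id).astype(np.int8)
    if y.min() == y.max():
        raise ValidationError("ROC needs both positive and negative pixels in the ROI")
    return float(roc_auc_score(y, scores[sel]))


def _as_list(x):
    if x is None:
        return None
    return list(x) if isinstance(x, (list, tuple)) else [x]


def evaluate_pair(
    preds: LabelMask | Sequence[LabelMask],
    truths: LabelMask | Sequence[LabelMask],
    scores: np.ndarray | Sequence[np.ndarray] | None = None,
    rois: np.ndarray | Sequence[np.ndarray] | None = None,
    pooling: str = "pixel",
) -> dict:
    """Evaluate one or more prediction/truth pairs, per class and pooled.

    ``pooling="pixel"`` sums confusion counts across images before taking
    ratios (the default); ``pooling="per_image"`` averages per-image
    metrics instead, NaN-aware.  When `scores` are given they are the soft
    score of the *occlusion* interpretation per pixel and drive AUC for
    each class id via one-vs-rest truth labels only when scores are 3-D
    (per-class); a 2-D score raster is used for class 1 alone.
    """
    preds = _as_list(preds)
    truths = _as_list(truths)
    scores = _as_list(scores)
    rois = _as_list(rois)
    if len(preds) != len(truths):
        raise ValidationError("need as many predictions as truths")
    if pooling not in ("pixel", "per_image"):
        raise ValidationError(f"unknown pooling {pooling!r}")
    n_classes = truths[0].n_classes
    if any(t.n_classes != n_classes for t in truths) or any(
        p.n_classes != n_classes for p in preds
    ):
        raise ValidationError("inconsistent class counts across images")

    per_image: list[dict[int, MetricReport]] = []
    tables: list[dict[int, ConfusionTable]] = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        roi = rois[i] if rois else None
        img_tables = {
            c: confusion(p, t, roi, class_id=c) for c in range(1, n_classes)
        }
        reports = {}
        for c, tab in img_tables.items():
            rep = scalar_metrics(tab)
            if scores is not None:
                rep = _with_auc(rep, scores[i], t, roi, c)
            reports[c] = rep
        tables.append(img_tables)
        per_image.append(reports)

    pooled: dict[int, MetricReport] = {}
    for c in range(1, n_classes):
        if pooling == "pixel":
            summed = tables[0][c]
            for tabs in tables[1:]:
                summed = summed + tabs[c]
            rep = scalar_metrics(summed)
            if scores is not None:
                rep = _pooled_auc(rep, scores, truths, rois, c)
        else:
            fields = ("accuracy", "precision", "recall", "f1", "iou", "auc")
            means = {}
            for f in fields:
                vals = [getattr(r[c], f) for r in per_image]
                vals = [v for v in vals if v is not None]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    means[f] = float(np.nanmean(vals)) if vals else None
            rep = MetricReport(c, means["accuracy"], means["precision"],
                               means["recall"], means["f1"], means["iou"],
                               means["auc"])
        pooled[c] = rep

    return {
        "per_image": per_image,
        "pooled": pooled,
        "protocol": {"pooling": pooling, "roi": "explicit" if rois else "full_frame"},
    }


def _score_plane(score: np.ndarray, class_id: int) -> np.ndarray:
    score = np.asarray(score, dtype=np.float64)
    if score.ndim == 3:
        return score[..., class_id]
    return score


def _with_auc(rep: MetricReport, score, truth, roi, class_id) -> MetricReport:
    try:
        auc = roc_auc(_score_plane(score, class_id), truth, roi, class_id)
    except ValidationError:
        auc = float("nan")
    return MetricReport(rep.class_id, rep.accuracy, rep.precision, rep.recall,
                        rep.f1, rep.iou, auc)


def _pooled_auc(rep, scores, truths, rois, class_id) -> MetricReport:
    ys, ss = [], []
    for i, t in enumerate(truths):
        sel = _roi_array(rois[i] if rois else None, t.shape)
        ys.append((t.labels[sel] == class_id).astype(np.int8))
        ss.append(_score_plane(scores[i], class_id)[sel])
    y = np.concatenate(ys)
    s = np.concatenate(ss)
    auc = float(roc_auc_score(y, s)) if y.min() != y.max() else float("nan")
    return MetricReport(rep.class_id, rep.accuracy, rep.precision, rep.recall,
                        rep.f1, rep.iou, auc)


def report_to_jsonable(report: dict) -> dict:
    """Convert an evaluate_pair result to JSON-safe types (NaN -> None)."""

    def clean(rep: MetricReport) -> dict:
        d = asdict(rep)
        for k, v in d.items():
            if isinstance(v, float) and np.isnan(v):
                d[k] = None
        return d

    return {
        "per_image": [
            {str(c): clean(r) for c, r in img.items()} for img in report["per_image"]
        ],
        "pooled": {str(c): clean(r) for c, r in report["pooled"].items()},
        "protocol": report["protocol"],
    }
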