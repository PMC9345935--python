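"""Thematic accuracy assessment.

The root object is the error (confusion) matrix — reference classes in rows,
predicted classes in columns — built either from ground-truth point samples or
from a reference raster. From it derive overall accuracy, the kappa
coefficient, and per-class precision (= user's accuracy), recall (= producer's
accuracy) and F1 score:

    OA    = trace / total
    p_e   = sum_k (row_k * col_k) / total^2
    kappa = (OA - p_e) / (1 - p_e)

Ratios with empty denominators (a class never predicted, or absent from the
reference) are reported as ``None`` — an explicit undefined flag — rather than
silently coerced to zero, so averages are not distorted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, UsageError
from .network import binarize_labels
from .raster import LabelRaster, Legend, PointSamples

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "confusion_from_points",
    "confusion_from_rasters",
    "compute_metrics",
    "binary_metrics",
]


@dataclass
class ConfusionMatrix:
    """K x K counts; ``counts[ref, pred]``, class order = legend order."""

    counts: np.ndarray
    legend: Legend

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = self.legend.num_classes
        if self.counts.shape != (k, k):
            raise UsageError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise UsageError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path=None) -> str:
        names = [self.legend.name_of(c) for c in self.legend.class_ids]
        buf = io.StringIO()
        buf.write("reference\\predicted," + ",".join(names) + "\n")
        for name, row in zip(names, self.counts):
            buf.write(name + "," + ",".join(str(int(v)) for v in row) + "\n")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class scores; ``None`` marks an undefined ratio."""

    precision: float | None  # user's accuracy
    recall: float | None  # producer's accuracy
    f1: float | None

    @property
    def user_accuracy(self):
        return self.precision

    @property
    def producer_accuracy(self):
        return self.recall


@dataclass(frozen=True)
class MetricsReport:
    overall_accuracy: float
    kappa: float | None
    per_class: dict  # class_id -> ClassMetrics
    legend: Legend = None

    def to_text(self) -> str:
        lines = [
            f"overall accuracy: {self.overall_accuracy:.4f}",
            "kappa: " + (f"{self.kappa:.4f}" if self.kappa is not None else "undefined"),
            "class                     precision  recall     f1",
        ]
        for cid, m in self.per_class.items():
            name = self.legend.name_of(cid) if self.legend else str(cid)
            fmt = lambda v: f"{v:.4f}" if v is not None else "undef "
            lines.append(f"{name:<25} {fmt(m.precision):>9}  {fmt(m.recall):>9}  {fmt(m.f1):>5}")
        if any(
            m.precision is None or m.recall is None or m.f1 is None
            for m in self.per_class.values()
        ):
            lines.append("note: 'undef' marks ratios with an empty denominator")
        return "\n".join(lines)

    def to_csv(self, path=None) -> str:
        buf = io.StringIO()
        buf.write("class,precision,recall,f1\n")
        for cid, m in self.per_class.items():
            name = self.legend.name_of(cid) if self.legend else str(cid)
            vals = ",".join("" if v is None else f"{v:.6f}" for v in (m.precision, m.recall, m.f1))
            buf.write(f"{name},{vals}\n")
        buf.write(f"overall_accuracy,{self.overall_accuracy:.6f},,\n")
        kap = "" if self.kappa is None else f"{self.kappa:.6f}"
        buf.write(f"kappa,{kap},,\n")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def confusion_from_points(pred: LabelRaster, samples: PointSamples) -> ConfusionMatrix:
    """Tally reference-vs-predicted counts at ground-truth point locations.

    Samples falling on nodata predictions are dropped (with a logged count);
    if every sample lands on nodata that is a data error.
    """
    samples.validate(pred.shape, pred.legend)
    pred_at = pred.labels[samples.y, samples.x]
    keep = pred_at != pred.legend.nodata_id
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d samples on nodata predictions", dropped)
    if not keep.any():
        raise DataError("all samples fall on nodata predictions")
    k = pred.legend.num_classes
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (samples.class_id[keep], pred_at[keep]), 1)
    return ConfusionMatrix(counts, pred.legend)


def confusion_from_rasters(pred: LabelRaster, reference: LabelRaster) -> ConfusionMatrix:
    """Raster-wide tally over all jointly valid pixels."""
    if pred.shape != reference.shape:
        raise DataError(f"shape mismatch: {pred.shape} vs {reference.shape}")
    valid = pred.valid & reference.valid
    if not valid.any():
        raise DataError("no jointly valid pixels")
    k = pred.legend.num_classes
    r = reference.labels[valid]
    p = pred.labels[valid]
    counts = np.bincount(r * k + p, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts, pred.legend)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Overall accuracy, kappa, and per-class precision/recall/F1."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise UsageError("empty confusion matrix")
    diag = np.diag(counts).astype(np.float64)
    row = counts.sum(axis=1).astype(np.float64)  # reference totals
    col = counts.sum(axis=0).astype(np.float64)  # predicted totals
    oa = float(diag.sum() / total)
    p_e = float((row * col).sum() / total**2)
    kappa = None if p_e >= 1.0 else float((oa - p_e) / (1.0 - p_e))
    per_class = {}
    for i, cid in enumerate(cm.legend.class_ids):
        precision = None if col[i] == 0 else float(diag[i] / col[i])
        recall = None if row[i] == 0 else float(diag[i] / row[i])
        if precision is None or recall is None:
            f1 = None
        elif precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        per_class[cid] = ClassMetrics(precision, recall, f1)
    return MetricsReport(oa, kappa, per_class, legend=cm.legend)


def binary_metrics(pred: LabelRaster, reference, target_class: int) -> MetricsReport:
    """Foreground/background (2x2) assessment of one class.

    ``reference`` may be a LabelRaster or a PointSamples set; both sides are
    collapsed to {background, target} before the metrics are computed. This is
    the evaluation applied to each one-vs-rest model.
    """
    if target_class not in pred.legend.class_ids:
        raise UsageError(f"target class {target_class} not in legend")
    bin_pred = pred if set(pred.legend.class_ids) == {0, 1} else binarize_labels(
        pred, target_class
    )
    if isinstance(reference, PointSamples):
        recs = reference.records.copy()
        recs[:, 2] = (recs[:, 2] == target_class).astype(np.int64)
        cm = confusion_from_points(bin_pred, PointSamples(recs))
    else:
        bin_ref = (
            reference
            if set(reference.legend.class_ids) == {0, 1}
            else binarize_labels(reference, target_class)
        )
        cm = confusion_from_rasters(bin_pred, bin_ref)
    return compute_metrics(cm)
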