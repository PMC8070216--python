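"""Classification and segmentation evaluation.

Implements the metrics reported for the three-class (normal / benign /
malignant) classification task and the two-class pixel segmentation task:

* confusion matrix (rows = truth, columns = predicted),
* overall Accuracy,
* Mean ± std Accuracy: the mean and population standard deviation of the
  per-class recalls — under heavy class imbalance the mean recall exposes
  minority-class failures that overall accuracy hides,
* macro-averaged F1,
* per-class IoU and MeanIoU, aggregated over the evaluation set (sum of
  intersections over sum of unions, per class) by default; a per-image-mean
  mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = ["EvalReport", "confusion_matrix", "classification_report", "iou_report"]


@dataclass
class EvalReport:
    """Container for everything the evaluation stage reports."""

    confusion: np.ndarray | None = None
    accuracy: float | None = None
    mean_accuracy: float | None = None
    std_accuracy: float | None = None
    f1: float | None = None
    per_class_iou: list | None = None
    mean_iou: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.confusion is not None:
            d["confusion"] = np.asarray(self.confusion).tolist()
        return d


def confusion_matrix(truth, predicted, n_classes: int) -> np.ndarray:
    """Count matrix C where C[i, j] = #items with true label i predicted as j."""
    t = np.asarray(truth).ravel()
    p = np.asarray(predicted).ravel()
    if t.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {t.shape[0]} vs {p.shape[0]}")
    if t.size and (min(t.min(), p.min()) < 0 or max(t.max(), p.max()) >= n_classes):
        raise ValueError(f"labels out of range [0, {n_classes})")
    return np.bincount(t * n_classes + p, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )


def classification_report(confusion: np.ndarray) -> EvalReport:
    """Accuracy, mean±std of per-class recalls, and macro F1 from a confusion matrix.

    Classes absent from the truth (zero row sum) are excluded from the recall
    mean with a warning. F1 for a class with P + R = 0 is taken as 0.
    """
    cm = np.asarray(confusion, dtype=float)
    n = cm.sum()
    if n == 0:
        raise ValueError("confusion matrix is all zeros")
    accuracy = float(np.trace(cm) / n)

    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    present = row > 0
    if not present.all():
        warnings.warn(
            f"classes {np.flatnonzero(~present).tolist()} absent from truth; "
            "excluded from mean accuracy",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, np.diag(cm) / np.where(row > 0, row, 1), np.nan)
        precision = np.where(col > 0, np.diag(cm) / np.where(col > 0, col, 1), 0.0)
    recalls = recall[present]
    mean_acc = float(recalls.mean())
    std_acc = float(recalls.std())  # population std, matching a mean±spread report

    f1s = []
    for c in range(cm.shape[0]):
        if not present[c]:
            continue
        p_c, r_c = precision[c], recall[c]
        f1s.append(0.0 if (p_c + r_c) == 0 else 2 * p_c * r_c / (p_c + r_c))
    macro_f1 = float(np.mean(f1s))

    return EvalReport(
        confusion=np.asarray(confusion),
        accuracy=accuracy,
        mean_accuracy=mean_acc,
        std_accuracy=std_acc,
        f1=macro_f1,
    )


def iou_report(
    truth_masks: Sequence[np.ndarray],
    predicted_masks: Sequence[np.ndarray],
    n_classes: int = 2,
    aggregate: str = "dataset",
) -> EvalReport:
    """Per-class IoU and their mean over a set of label masks.

    ``aggregate="dataset"`` (default) sums intersections and unions over all
    images before dividing; ``"image"`` computes IoU per image and averages.
    Classes whose union is zero everywhere are excluded with a warning.
    """
    if len(truth_masks) != len(predicted_masks):
        raise ValueError("truth and prediction mask lists differ in length")
    if aggregate not in ("dataset", "image"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    inter = np.zeros(n_classes)
    union = np.zeros(n_classes)
    per_image = []
    for i, (t, p) in enumerate(zip(truth_masks, predicted_masks)):
        t = np.asarray(t)
        p = np.asarray(p)
        if t.shape != p.shape:
            raise ValueError(f"mask shape mismatch at image {i}: {t.shape} vs {p.shape}")
        img_iou = np.full(n_classes, np.nan)
        for c in range(n_classes):
            tc = t == c
            pc = p == c
            ic = np.logical_and(tc, pc).sum()
            uc = np.logical_or(tc, pc).sum()
            inter[c] += ic
            union[c] += uc
            if uc > 0:
                img_iou[c] = ic / uc
        per_image.append(img_iou)

    if aggregate == "dataset":
        valid = union > 0
        iou = np.full(n_classes, np.nan)
        iou[valid] = inter[valid] / union[valid]
    else:
        stacked = np.stack(per_image)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            iou = np.nanmean(stacked, axis=0)
        valid = ~np.isnan(iou)

    if not valid.all():
        warnings.warn(
            f"classes {np.flatnonzero(~valid).tolist()} have empty union; excluded from MeanIoU",
            stacklevel=2,
        )
    per_class = [float(v) if np.isfinite(v) else None for v in iou]
    mean_iou = float(np.nanmean(iou[valid])) if valid.any() else float("nan")
    return EvalReport(per_class_iou=per_class, mean_iou=mean_iou)
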