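"""Defuzzification, label alignment and segmentation-accuracy metrics.

Cluster indices from an unsupervised fit are arbitrary, so before comparing
a predicted label map with a reference the labels are permuted by the
assignment that maximizes pixel agreement (Hungarian algorithm on the
confusion matrix). Overall accuracy is the fraction of correctly labeled
pixels; per-class accuracy is the Jaccard index of the class's pixel sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "defuzzify",
    "confusion_matrix",
    "optimal_label_mapping",
    "align_labels",
    "segmentation_accuracy",
    "per_class_accuracy",
    "AccuracyReport",
    "evaluate",
]


def defuzzify(u: np.ndarray, grid_shape=None) -> np.ndarray:
    """Hard labels by per-datum argmax; ties go to the lowest cluster index."""
    u = np.asarray(u, dtype=float)
    labels = np.argmax(u, axis=1)
    if grid_shape is not None:
        h, w = grid_shape
        if u.shape[0] != h * w:
            raise ValueError(f"membership rows {u.shape[0]} != grid pixels {h * w}")
        labels = labels.reshape(h, w)
    return labels


def _check_same_shape(pred: np.ndarray, ref: np.ndarray) -> None:
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")


def confusion_matrix(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Square count matrix C[p, r] = #pixels with pred=p and ref=r."""
    pred = np.asarray(pred).ravel()
    ref = np.asarray(ref).ravel()
    k = int(max(pred.max(), ref.max())) + 1
    return np.bincount(pred * k + ref, minlength=k * k).reshape(k, k)


def optimal_label_mapping(pred: np.ndarray, ref: np.ndarray) -> dict:
    """Permutation of predicted labels maximizing total pixel agreement."""
    _check_same_shape(np.asarray(pred), np.asarray(ref))
    conf = confusion_matrix(pred, ref)
    rows, cols = linear_sum_assignment(-conf)
    return {int(p): int(r) for p, r in zip(rows, cols)}


def align_labels(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Relabel ``pred`` by the agreement-maximizing permutation."""
    pred = np.asarray(pred)
    mapping = optimal_label_mapping(pred, ref)
    lut = np.arange(max(mapping) + 1)
    for p, r in mapping.items():
        lut[p] = r
    return lut[pred]


def segmentation_accuracy(pred: np.ndarray, ref: np.ndarray) -> float:
    """Fraction of correctly classified pixels (labels assumed aligned)."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    _check_same_shape(pred, ref)
    return float(np.mean(pred == ref))


def per_class_accuracy(pred: np.ndarray, ref: np.ndarray, cls: int) -> float:
    """Jaccard index of the pixel sets {pred == cls} and {ref == cls}.

    Defined as 1.0 when both sets are empty (vacuous agreement).
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    _check_same_shape(pred, ref)
    n_classes = int(max(pred.max(), ref.max())) + 1
    if not (0 <= cls < n_classes):
        raise ValueError(f"class {cls} outside [0, {n_classes})")
    a = pred == cls
    b = ref == cls
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


@dataclass
class AccuracyReport:
    """Overall and per-class accuracy plus the label mapping used."""

    sa: float
    per_class: list
    mapping: dict

    def summary(self) -> str:
        lines = [f"segmentation accuracy: {self.sa:.4f}"]
        for j, v in enumerate(self.per_class):
            lines.append(f"  class {j} Jaccard: {v:.4f}")
        lines.append(f"  label mapping: {self.mapping}")
        return "\n".join(lines)


def evaluate(pred: np.ndarray, ref: np.ndarray) -> AccuracyReport:
    """Align predicted labels to the reference and compute all metrics."""
    mapping = optimal_label_mapping(pred, ref)
    aligned = align_labels(pred, ref)
    n_classes = int(max(np.max(aligned), np.max(ref))) + 1
    per_class = [per_class_accuracy(aligned, ref, j) for j in range(n_classes)]
    return AccuracyReport(sa=segmentation_accuracy(aligned, ref), per_class=per_class, mapping=mapping)
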