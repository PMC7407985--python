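"""Multiclass evaluation: accuracy, confusion matrices, report container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ParameterError

__all__ = ["accuracy", "confusion_matrix", "row_normalize", "EvaluationReport"]


def _check_pair(preds, truth) -> tuple[np.ndarray, np.ndarray]:
    preds = np.asarray(preds)
    truth = np.asarray(truth)
    if preds.shape != truth.shape or preds.ndim != 1:
        raise ParameterError(
            f"preds/truth: need equal-length 1-D label lists, got {preds.shape} vs {truth.shape}"
        )
    if len(preds) < 1:
        raise ParameterError("preds/truth: need at least one sample")
    return preds, truth


def accuracy(preds, truth) -> float:
    """Fraction of matching labels, in [0, 1]."""
    preds, truth = _check_pair(preds, truth)
    return float(np.mean(preds == truth))


def confusion_matrix(preds, truth, n_classes: int) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    preds, truth = _check_pair(preds, truth)
    for name, arr in (("preds", preds), ("truth", truth)):
        bad = np.flatnonzero((arr < 0) | (arr >= n_classes))
        if bad.size:
            raise ParameterError(
                f"{name}: label {arr[bad[0]]} at sample index {bad[0]} is outside [0, {n_classes})"
            )
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (truth, preds), 1)
    return cm


def row_normalize(cm: np.ndarray) -> np.ndarray:
    """Row-normalized view (per-class recall on the diagonal); empty rows stay 0."""
    cm = np.asarray(cm, dtype=np.float64)
    sums = cm.sum(axis=1, keepdims=True)
    return np.divide(cm, sums, out=np.zeros_like(cm), where=sums > 0)


@dataclass
class EvaluationReport:
    """Test-set evaluation of one decoder: accuracy, confusion, recalls."""

    family: str
    accuracy: float
    confusion: np.ndarray
    n_samples: int = 0
    manifest_ref: str = ""

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=np.int64)
        if self.n_samples == 0:
            self.n_samples = int(self.confusion.sum())

    @classmethod
    def from_predictions(cls, family: str, preds, truth, n_classes: int) -> "EvaluationReport":
        cm = confusion_matrix(preds, truth, n_classes)
        return cls(family=family, accuracy=accuracy(preds, truth), confusion=cm)

    @property
    def per_class_recall(self) -> np.ndarray:
        return np.diag(row_normalize(self.confusion))

    def validate(self) -> None:
        """Internal consistency: trace/total identity and row sums."""
        total = int(self.confusion.sum())
        if total != self.n_samples:
            raise ParameterError("confusion total does not match sample count")
        if not np.isclose(np.trace(self.confusion) / total, self.accuracy):
            raise ParameterError("accuracy does not equal trace/total of the confusion matrix")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "accuracy": self.accuracy,
            "n_samples": self.n_samples,
            "confusion": self.confusion.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "manifest_ref": self.manifest_ref,
        }
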