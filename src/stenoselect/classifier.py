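"""Maximum-margin classifier contract used as the wrapper-fitness evaluator.

The selection loop scores feature subsets with a fast linear SVM; once the
search finishes, a fine-tuned polynomial kernel (order 5, scale 2, offset
0.3569) is applied for the final evaluation.  The polynomial kernel takes the
form ``(<x, x'> / scale + offset) ** order``.  Features are standardized to
zero mean / unit variance using training-split statistics only, since filter
response features span orders of magnitude.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.svm import SVC, LinearSVC

from .data import LabeledDataset, PartitionSpec
from .metrics import ConfusionCounts, confusion

__all__ = [
    "KernelSpec",
    "TrainedClassifier",
    "EmptyMaskError",
    "train_classifier",
    "evaluate_subset",
]


class EmptyMaskError(ValueError):
    """The candidate feature subset selects no columns."""


@dataclass(frozen=True)
class KernelSpec:
    kind: Literal["linear", "polynomial"] = "linear"
    poly_order: int = 5
    kernel_scale: float = 2.0
    kernel_offset: float = 0.3569

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial":
            if self.poly_order < 1:
                raise ValueError("polynomial order must be >= 1")
            if self.kernel_scale <= 0:
                raise ValueError("kernel scale must be positive")

    @classmethod
    def fine_tuned_polynomial(cls) -> "KernelSpec":
        """The fine-tuned final-evaluation kernel: order 5, scale 2, offset 0.3569."""
        return cls(kind="polynomial", poly_order=5, kernel_scale=2.0, kernel_offset=0.3569)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "poly_order": self.poly_order,
            "kernel_scale": self.kernel_scale,
            "kernel_offset": self.kernel_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


@dataclass
class TrainedClassifier:
    """A fitted decision function thresholded at zero (predict 1 iff score >= 0)."""

    _model: object
    _mean: np.ndarray
    _scale: np.ndarray
    spec: KernelSpec
    mask: np.ndarray | None = None
    training_fingerprint: str = ""

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        Z = (X - self._mean) / self._scale
        return np.asarray(self._model.decision_function(Z), dtype=np.float64)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(np.int64)

    def metadata(self) -> dict:
        return {
            "kernel": self.spec.to_dict(),
            "mask": None if self.mask is None else [int(b) for b in self.mask],
            "training_fingerprint": self.training_fingerprint,
        }

    def metadata_json(self) -> str:
        return json.dumps(self.metadata())


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_classifier(
    X: np.ndarray, y: np.ndarray, spec: KernelSpec = KernelSpec()
) -> TrainedClassifier:
    """Fit the SVM on standardized features.  Deterministic for fixed inputs.

    The regularization constant is fixed at C = 1 so the wrapper fitness
    landscape stays stable across subsets.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise EmptyMaskError("X must have at least one feature column")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0  # constant columns carry no information
    Z = (X - mean) / scale
    if spec.kind == "linear":
        model = LinearSVC(C=1.0, dual=False, tol=1e-5, max_iter=5000)
    else:
        model = SVC(
            kernel="poly",
            degree=spec.poly_order,
            gamma=1.0 / spec.kernel_scale,
            coef0=spec.kernel_offset,
            C=1.0,
        )
    model.fit(Z, y)
    return TrainedClassifier(
        _model=model,
        _mean=mean,
        _scale=scale,
        spec=spec,
        training_fingerprint=_fingerprint(X, y),
    )


def evaluate_subset(
    ds: LabeledDataset,
    part: PartitionSpec,
    mask: np.ndarray,
    spec: KernelSpec = KernelSpec(),
    eval_split: Literal["validation", "test"] = "validation",
) -> tuple[ConfusionCounts, float]:
    """Train on the train split restricted to ``mask`` columns, score a holdout.

    Returns the holdout confusion counts and accuracy.  An empty mask raises
    :class:`EmptyMaskError`; the optimizer maps that to fitness 0.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != (ds.n_features,):
        raise ValueError("mask length must equal the number of features")
    if not mask.any():
        raise EmptyMaskError("feature subset is empty")
    if eval_split not in ("validation", "test"):
        raise ValueError(f"unknown eval split {eval_split!r}")
    cols = np.flatnonzero(mask)
    Xtr = ds.features[np.ix_(part.train_idx, cols)]
    ytr = ds.labels[part.train_idx]
    clf = train_classifier(Xtr, ytr, spec)
    clf.mask = mask.copy()
    eval_idx = part.split(eval_split)
    y_pred = clf.predict(ds.features[np.ix_(eval_idx, cols)])
    counts = confusion(ds.labels[eval_idx], y_pred)
    return counts, (counts.tp + counts.tn) / counts.total
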