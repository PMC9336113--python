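"""Multilabel metrics, dataset statistics and cross-validation harnesses.

Frame-level predictions are scored in the 5-slot one-hot space (four
compensation labels plus the exclusive Normal slot) with micro-averaged
precision, recall and F1 — pooling true/false positive and negative
counts across all label slots before forming the ratios, so rare labels
are diluted among frequent ones — and the Hamming loss, the fraction of
mispredicted label slots.

Generalisation across people and tasks is probed with
leave-one-subject-out (LOSO) and leave-one-exercise-out (LOEO)
cross-validation; fold metrics are averaged unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import hamming_loss, precision_recall_fscore_support

from .labels import LabelSet, N_LABEL_SLOTS, to_onehot


@dataclass(frozen=True)
class MLCMetrics:
    precision: float
    recall: float
    f1: float
    hamming: float

    def as_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, "hamming": self.hamming}


def mlc_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MLCMetrics:
    """Micro precision/recall/F1 and Hamming loss on (N, 5) indicators.

    Zero-division (no predicted or no true positives) yields 0 with a
    warning rather than an error.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    if y_true.ndim != 2 or y_true.shape[1] != N_LABEL_SLOTS:
        raise ValueError(f"expected (N, {N_LABEL_SLOTS}) indicators")
    if not np.any(y_pred) or not np.any(y_true):
        warnings.warn("no positive labels on one side; zero-division -> 0")
    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, average="micro", zero_division=0)
    h = hamming_loss(y_true, y_pred)
    return MLCMetrics(precision=float(p), recall=float(r), f1=float(f),
                      hamming=float(h))


def mlc_metrics_labelsets(y_true: Iterable[LabelSet],
                          y_pred: Iterable[LabelSet]) -> MLCMetrics:
    return mlc_metrics(to_onehot(list(y_true)), to_onehot(list(y_pred)))


@dataclass(frozen=True)
class DatasetStats:
    """Label-multiset structure of a frame-labeled dataset.

    ``p_min`` is the fraction of frames carrying exactly one label slot
    (Normal counts as a label); ``irlbl`` maps each occurring label slot
    to the ratio between the most frequent slot's count and its own, so
    the modal label has ratio 1 and rarer labels larger ratios.
    """

    p_min: float
    irlbl: dict

    @property
    def multi_label_fraction(self) -> float:
        return 1.0 - self.p_min


def dataset_stats(labelsets: Sequence[LabelSet]) -> DatasetStats:
    if not labelsets:
        raise ValueError("empty label list")
    onehot = to_onehot(list(labelsets))
    per_frame = onehot.sum(axis=1)
    p_min = float(np.mean(per_frame == 1))
    counts = onehot.sum(axis=0)
    top = counts.max()
    irlbl = {int(lab): float(top / counts[lab])
             for lab in range(N_LABEL_SLOTS) if counts[lab] > 0}
    return DatasetStats(p_min=p_min, irlbl=irlbl)


@dataclass(frozen=True)
class FoldResult:
    key: str
    metrics: MLCMetrics
    n_frames: int


@dataclass(frozen=True)
class CVResult:
    """Per-fold metrics with their unweighted mean and SD."""

    folds: tuple[FoldResult, ...]

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f.metrics, metric)
                              for f in self.folds]))

    def std(self, metric: str) -> float:
        return float(np.std([getattr(f.metrics, metric)
                             for f in self.folds]))

    def summary(self) -> dict:
        out = {}
        for m in ("precision", "recall", "f1", "hamming"):
            out[m] = {"mean": self.mean(m), "std": self.std(m)}
        out["folds"] = {f.key: f.metrics.as_dict() for f in self.folds}
        return out


#: fit_predict(X_train, y_train, X_test) -> predicted LabelSets for X_test.
#: y values are lists of LabelSet aligned with X rows.
FitPredict = Callable[[np.ndarray, list, np.ndarray], list]


def loso_cv(groups: Mapping[str, tuple[np.ndarray, list]],
            fit_predict: FitPredict) -> CVResult:
    """Leave-one-subject-out: one fold per subject, never trained on.

    ``groups`` maps subject id -> (features, labelsets) with aligned
    rows. Folds partition the data: each subject's frames appear in
    exactly one test set.
    """
    if len(groups) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    folds = []
    for held_out in sorted(groups):
        X_tr = np.vstack([groups[s][0] for s in sorted(groups)
                          if s != held_out])
        y_tr = [ls for s in sorted(groups) if s != held_out
                for ls in groups[s][1]]
        X_te, y_te = groups[held_out]
        y_hat = fit_predict(X_tr, y_tr, X_te)
        folds.append(FoldResult(key=held_out,
                                metrics=mlc_metrics_labelsets(y_te, y_hat),
                                n_frames=len(y_te)))
    return CVResult(folds=tuple(folds))


def loeo_cv(dataset_e1: tuple[np.ndarray, list],
            dataset_e2: tuple[np.ndarray, list],
            fit_predict: FitPredict,
            scenarios: tuple[str, str] = ("S1", "S1")) -> CVResult:
    """Leave-one-exercise-out across two same-scenario exercises.

    Two folds: train on one exercise, test on the other, both ways.
    The exercises must share the positioning scenario — features are
    only comparable under the same camera placement.
    """
    if scenarios[0] != scenarios[1]:
        raise ValueError(
            f"LOEO requires a shared scenario, got {scenarios}")
    folds = []
    pairs = [("E2", dataset_e1, dataset_e2), ("E1", dataset_e2, dataset_e1)]
    for test_key, train, test in pairs:
        y_hat = fit_predict(train[0], train[1], test[0])
        folds.append(FoldResult(key=test_key,
                                metrics=mlc_metrics_labelsets(test[1], y_hat),
                                n_frames=len(test[1])))
    return CVResult(folds=tuple(folds))
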