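"""Two-stage neural compensation classifier.

Normal frames vastly outnumber any single compensation pattern, so the
learned approach splits the problem: a binary gate C1 decides whether a
frame shows any compensation at all, and a one-vs-rest multilabel stage
C2 — trained only on compensation frames — decides which patterns. Both
stages are small multilayer perceptrons (C1 ReLU, C2 tanh) trained with
Adam, mini-batches of 5 and at most 550 epochs; features are the
normalized, mirrored 2D keypoints so that the affected limb always lies
on the same side.

Per-exercise default architectures (selected by grid search over 1-3
layers, 16-512 units and initial learning rates 1e-4 to 0.1):

========  =========  =========
exercise  C1         C2
========  =========  =========
E1        1x16 @1e-3  1x64 @1e-3
E2        1x16 @1e-3  1x16 @1e-2
E3        1x96 @1e-2  1x16 @1e-3
========  =========  =========
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier

from . import body25
from .labels import COMPENSATION_LABELS, LabelSet
from .normalization import NormalizedSequence


def default_feature_joints(affected_side: str) -> tuple[int, ...]:
    """Keypoints fed to the learned classifiers, in fixed column order.

    Spine (nose, neck, mid-hip), both shoulders, the affected elbow and
    wrist, and both hips — resolved per sequence so that the affected
    side always occupies the same columns.
    """
    opp = body25.other_side(affected_side)
    return (body25.NOSE, body25.NECK, body25.MID_HIP,
            body25.shoulder(affected_side), body25.shoulder(opp),
            body25.elbow(affected_side), body25.wrist(affected_side),
            body25.hip(affected_side), body25.hip(opp))


FEATURE_COLUMNS = ("nose", "neck", "mid_hip", "shoulder_aff",
                   "shoulder_unaff", "elbow_aff", "wrist_aff",
                   "hip_aff", "hip_unaff")


def encode_features(seq: NormalizedSequence) -> np.ndarray:
    """(T, 18) matrix of (x, y) pairs of the selected keypoints.

    Requires a mirrored sequence: mirroring is what makes left- and
    right-affected subjects comparable. Confidences are never features.
    """
    if not seq.mirrored:
        raise ValueError("NN features require a mirrored sequence")
    joints = default_feature_joints(seq.affected_side)
    return seq.xy[:, joints, :].reshape(seq.n_frames, -1).copy()


@dataclass(frozen=True)
class Hyperparams:
    """Architecture and optimization settings for the two stages."""

    c1_layers: tuple[int, ...] = (16,)
    c1_lr_init: float = 0.001
    c2_layers: tuple[int, ...] = (64,)
    c2_lr_init: float = 0.001
    batch_size: int = 5
    max_iter: int = 550

    @classmethod
    def for_exercise(cls, exercise_id: str) -> "Hyperparams":
        table = {
            "E1": cls(c1_layers=(16,), c1_lr_init=0.001,
                      c2_layers=(64,), c2_lr_init=0.001),
            "E2": cls(c1_layers=(16,), c1_lr_init=0.001,
                      c2_layers=(16,), c2_lr_init=0.01),
            "E3": cls(c1_layers=(96,), c1_lr_init=0.01,
                      c2_layers=(16,), c2_lr_init=0.001),
        }
        return table[exercise_id]


EXPLORED_UNITS = (16, 24, 32, 48, 64, 96, 128, 192, 256, 384, 512)
EXPLORED_LR = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1)


@dataclass
class TwoStageModel:
    """Fitted gate + identifier pair with its feature layout."""

    c1: MLPClassifier
    c2: OneVsRestClassifier
    hp: Hyperparams
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS
    cutoff: float = 0.5

    @property
    def n_features(self) -> int:
        return 2 * len(self.feature_columns)


def train_two_stage(features: np.ndarray, labelsets: list[LabelSet],
                    hp: Hyperparams | None = None,
                    seed: int = 0) -> TwoStageModel:
    """Fit the gate on all frames and the identifier on compensation frames.

    ``features`` rows align 1:1 with ``labelsets``. Deterministic given
    ``seed``. Raises if only one gate class is present or if no frame
    carries a compensation label (nothing for C2 to learn).
    """
    if hp is None:
        hp = Hyperparams()
    X = np.asarray(features, dtype=float)
    if X.shape[0] != len(labelsets):
        raise ValueError("features and labels misaligned")
    any_comp = np.array([0 if ls.normal else 1 for ls in labelsets])
    if len(np.unique(any_comp)) < 2:
        raise ValueError(
            "need both Normal and compensation frames to train the gate")
    comp_mask = any_comp == 1
    y_multi = np.array(
        [[1 if lab in ls else 0 for lab in COMPENSATION_LABELS]
         for ls in labelsets])[comp_mask]
    if not np.any(y_multi):
        raise ValueError("no compensation labels for the identifier stage")
    c1 = MLPClassifier(hidden_layer_sizes=hp.c1_layers, activation="relu",
                       solver="adam", learning_rate="adaptive",
                       learning_rate_init=hp.c1_lr_init,
                       batch_size=hp.batch_size, max_iter=hp.max_iter,
                       random_state=seed)
    c2_base = MLPClassifier(hidden_layer_sizes=hp.c2_layers,
                            activation="tanh", solver="adam",
                            learning_rate="adaptive",
                            learning_rate_init=hp.c2_lr_init,
                            batch_size=hp.batch_size, max_iter=hp.max_iter,
                            random_state=seed + 1)
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        c1.fit(X, any_comp)
        c2 = OneVsRestClassifier(c2_base).fit(X[comp_mask], y_multi)
    return TwoStageModel(c1=c1, c2=c2, hp=hp)


def predict(model: TwoStageModel, features: np.ndarray) -> list[LabelSet]:
    """Gate then identify: Normal frames never reach the identifier.

    Gated-positive frames take every label whose one-vs-rest score
    reaches the cutoff; if none does, the top-scoring label is assigned
    so a detected-compensation frame is never left unlabeled.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got {X.shape[1]}")
    gate = model.c1.predict(X)
    out = [LabelSet.normal_set()] * X.shape[0]
    pos = np.nonzero(gate == 1)[0]
    if pos.size:
        scores = model.c2.predict_proba(X[pos])
        for row, sc in zip(pos, scores):
            active = frozenset(
                int(COMPENSATION_LABELS[j])
                for j in np.nonzero(sc >= model.cutoff)[0])
            if not active:
                active = frozenset({int(COMPENSATION_LABELS[
                    int(np.argmax(sc))])})
            out[row] = LabelSet(active)
    return out
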