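"""End-to-end assessment pipelines over raw keypoint sequences.

Thin compositions of the stage modules: cleansing → normalization →
(kinematic variables → rules) or (mirroring → features → two-stage NN).
These are what the CLI, the examples and the evaluation harness call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cleansing import CleansingConfig, CleansingReport, clean_sequence
from .evaluation import CVResult, loeo_cv, loso_cv
from .kinematics import KinematicSeries, compute_series
from .labels import LabelSet
from .nn_classifier import (Hyperparams, encode_features, predict,
                            train_two_stage)
from .normalization import mirror_to_reference, scale_by_spine
from .pose_io import RawSequence
from .rb_classifier import ThresholdSet, classify_sequence
from .synthetic_data import Trial


@dataclass
class AssessmentResult:
    """Frame-aligned labels plus the intermediate artifacts."""

    labels: list[LabelSet]
    frame_numbers: tuple[int, ...]
    series: KinematicSeries | None
    report: CleansingReport


def assess_rb(seq: RawSequence, thresholds: ThresholdSet | None = None,
              cleansing: CleansingConfig | None = None,
              *, window: int = 5,
              trunk_priority: bool = False) -> AssessmentResult:
    """Rule-based assessment of a raw sequence."""
    cleaned, report = clean_sequence(seq, cleansing)
    norm = scale_by_spine(cleaned)
    series = compute_series(norm, window=window)
    labels = classify_sequence(series, thresholds,
                               trunk_priority=trunk_priority)
    return AssessmentResult(labels=labels,
                            frame_numbers=norm.frame_numbers,
                            series=series, report=report)


def nn_features(seq: RawSequence,
                cleansing: CleansingConfig | None = None
                ) -> tuple[np.ndarray, tuple[int, ...], CleansingReport]:
    """Cleansed, normalized, mirrored feature matrix for the NN path."""
    cleaned, report = clean_sequence(seq, cleansing)
    norm = mirror_to_reference(scale_by_spine(cleaned))
    return encode_features(norm), norm.frame_numbers, report


def trials_to_groups(trials: list[Trial], *, by: str = "subject"
                     ) -> dict[str, tuple[np.ndarray, list[LabelSet]]]:
    """Stack per-trial NN features and ground truth, grouped for CV.

    Ground-truth labels are realigned by frame number in case cleansing
    dropped frames.
    """
    feats: dict[str, list[np.ndarray]] = {}
    labs: dict[str, list[LabelSet]] = {}
    for trial in trials:
        seq = trial.sequence
        key = seq.subject_id if by == "subject" else seq.exercise_id
        X, frame_numbers, _ = nn_features(seq)
        truth_by_t = dict(zip(seq.frame_numbers, trial.truth))
        y = [truth_by_t[t] for t in frame_numbers]
        feats.setdefault(key, []).append(X)
        labs.setdefault(key, []).append(y)
    return {k: (np.vstack(feats[k]), [ls for block in labs[k]
                                      for ls in block])
            for k in sorted(feats)}


def nn_fit_predict(hp: Hyperparams, seed: int = 0):
    """A LOSO/LOEO callback training the two-stage model per fold."""
    def _fit_predict(X_tr, y_tr, X_te):
        model = train_two_stage(X_tr, list(y_tr), hp, seed=seed)
        return predict(model, X_te)
    return _fit_predict


def rb_loso(trials: list[Trial],
            thresholds: ThresholdSet | None = None) -> CVResult:
    """LOSO evaluation of the rule-based path (no training involved:
    each held-out subject is simply assessed with the fixed rules)."""
    groups: dict[str, tuple[list[LabelSet], list[LabelSet]]] = {}
    for trial in trials:
        seq = trial.sequence
        res = assess_rb(seq, thresholds)
        truth_by_t = dict(zip(seq.frame_numbers, trial.truth))
        y = [truth_by_t[t] for t in res.frame_numbers]
        pred, true = groups.setdefault(seq.subject_id, ([], []))
        pred.extend(res.labels)
        true.extend(y)
    if len(groups) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    from .evaluation import FoldResult, mlc_metrics_labelsets
    folds = [FoldResult(key=s,
                        metrics=mlc_metrics_labelsets(groups[s][1],
                                                      groups[s][0]),
                        n_frames=len(groups[s][1]))
             for s in sorted(groups)]
    return CVResult(folds=tuple(folds))


def nn_loso(trials: list[Trial], hp: Hyperparams | None = None,
            seed: int = 0) -> CVResult:
    """LOSO evaluation of the two-stage NN path."""
    exercise = trials[0].sequence.exercise_id
    if hp is None:
        hp = Hyperparams.for_exercise(exercise)
    groups = trials_to_groups(trials, by="subject")
    return loso_cv(groups, nn_fit_predict(hp, seed=seed))


def nn_loeo(trials_e1: list[Trial], trials_e2: list[Trial],
            hp: Hyperparams | None = None, seed: int = 0) -> CVResult:
    """LOEO across two frontal-scenario exercises for the NN path."""
    if hp is None:
        hp = Hyperparams.for_exercise("E1")
    g1 = trials_to_groups(trials_e1, by="exercise")
    g2 = trials_to_groups(trials_e2, by="exercise")
    (d1,) = g1.values()
    (d2,) = g2.values()
    scen = (trials_e1[0].sequence.scenario, trials_e2[0].sequence.scenario)
    return loeo_cv(d1, d2, nn_fit_predict(hp, seed=seed), scenarios=scen)
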