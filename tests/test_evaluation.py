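"""Multilabel metrics, dataset statistics and CV harnesses."""

import numpy as np
import pytest

import compens2d as c2
from compens2d.evaluation import FoldResult, mlc_metrics
from compens2d.labels import LabelSet, to_onehot


def brute_force_metrics(y_true, y_pred):
    """Element-by-element TP/FP/FN tally, written independently of the
    implementation path."""
    tp = fp = fn = wrong = 0
    n, L = y_true.shape
    for i in range(n):
        for j in range(L):
            t, p = y_true[i, j], y_pred[i, j]
            if t == 1 and p == 1:
                tp += 1
            elif t == 0 and p == 1:
                fp += 1
                wrong += 1
            elif t == 1 and p == 0:
                fn += 1
                wrong += 1
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1, wrong / (n * L)


def random_labelsets(rng, n):
    out = []
    for _ in range(n):
        if rng.random() < 0.5:
            out.append(LabelSet.normal_set())
        else:
            k = int(rng.integers(1, 5))
            out.append(LabelSet(frozenset(
                int(x) for x in rng.choice(4, size=k, replace=False))))
    return out


class TestMlcMetrics:
    def test_perfect_prediction(self, rng):
        y = to_onehot(random_labelsets(rng, 50))
        m = mlc_metrics(y, y)
        assert (m.precision, m.recall, m.f1, m.hamming) == (1, 1, 1, 0)

    def test_complement_prediction_has_zero_f1(self):
        y_true = to_onehot([LabelSet.of(0), LabelSet.of(1)])
        y_pred = 1 - y_true
        m = mlc_metrics(y_true, y_pred)
        assert m.f1 == 0.0

    def test_matches_brute_force_tally(self, rng):
        for _ in range(200):
            y_true = to_onehot(random_labelsets(rng, 40))
            y_pred = to_onehot(random_labelsets(rng, 40))
            m = mlc_metrics(y_true, y_pred)
            p, r, f, h = brute_force_metrics(y_true, y_pred)
            assert m.precision == pytest.approx(p, abs=1e-12)
            assert m.recall == pytest.approx(r, abs=1e-12)
            assert m.f1 == pytest.approx(f, abs=1e-12)
            assert m.hamming == pytest.approx(h, abs=1e-12)

    def test_f1_is_harmonic_mean(self, rng):
        y_true = to_onehot(random_labelsets(rng, 100))
        y_pred = to_onehot(random_labelsets(rng, 100))
        m = mlc_metrics(y_true, y_pred)
        if m.precision + m.recall > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall))

    def test_zero_hamming_iff_exact_match(self, rng):
        y_true = to_onehot(random_labelsets(rng, 30))
        assert mlc_metrics(y_true, y_true.copy()).hamming == 0.0
        y_pred = y_true.copy()
        y_pred[3, 2] ^= 1
        assert mlc_metrics(y_true, y_pred).hamming > 0.0

    def test_invariant_to_frame_permutation(self, rng):
        y_true = to_onehot(random_labelsets(rng, 60))
        y_pred = to_onehot(random_labelsets(rng, 60))
        perm = rng.permutation(60)
        a = mlc_metrics(y_true, y_pred)
        b = mlc_metrics(y_true[perm], y_pred[perm])
        assert a == b

    def test_single_label_rows_make_micro_p_equal_r(self, rng):
        """On single-label data micro precision = recall = accuracy."""
        y_true = [LabelSet.of(int(rng.integers(0, 4))) for _ in range(80)]
        y_pred = [LabelSet.of(int(rng.integers(0, 4))) for _ in range(80)]
        m = c2.mlc_metrics_labelsets(y_true, y_pred)
        acc = np.mean([t == p for t, p in zip(y_true, y_pred)])
        assert m.precision == pytest.approx(m.recall)
        assert m.precision == pytest.approx(acc)

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError):
            mlc_metrics(np.zeros((3, 5)), np.zeros((4, 5)))


class TestDatasetStats:
    def test_imbalance_ratio_from_known_counts(self):
        labels = ([LabelSet.normal_set()] * 100
                  + [LabelSet.of(2)] * 50 + [LabelSet.of(0)] * 25)
        stats = c2.dataset_stats(labels)
        assert stats.irlbl[4] == 1.0
        assert stats.irlbl[2] == 2.0
        assert stats.irlbl[0] == 4.0

    def test_multilabel_fraction(self):
        labels = [LabelSet.of(0), LabelSet.of(1), LabelSet.normal_set(),
                  LabelSet.of(0, 2)]
        stats = c2.dataset_stats(labels)
        assert stats.p_min == 0.75
        assert stats.multi_label_fraction == pytest.approx(0.25)

    def test_all_normal(self):
        stats = c2.dataset_stats([LabelSet.normal_set()] * 10)
        assert stats.p_min == 1.0
        assert stats.irlbl == {4: 1.0}

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            c2.dataset_stats([])


def _toy_groups(rng, subjects=3, n=40):
    groups = {}
    for s in range(subjects):
        X = rng.normal(size=(n, 4)) + s   # subject-specific offset
        y = [LabelSet.of(0) if x[0] > s else LabelSet.normal_set()
             for x in X]
        groups[f"P{s}"] = (X, y)
    return groups


class TestLosoCV:
    def test_folds_partition_the_dataset(self, rng):
        groups = _toy_groups(rng)
        seen = []

        def fit_predict(X_tr, y_tr, X_te):
            seen.append(len(X_te))
            assert len(X_tr) == len(y_tr)
            return [LabelSet.normal_set()] * len(X_te)

        result = c2.loso_cv(groups, fit_predict)
        assert len(result.folds) == 3
        assert sum(seen) == sum(len(g[1]) for g in groups.values())

    def test_held_out_subject_never_in_training(self, rng):
        groups = _toy_groups(rng)
        X_all = {s: groups[s][0] for s in groups}

        def fit_predict(X_tr, y_tr, X_te):
            held = next(s for s, X in X_all.items()
                        if np.array_equal(X, X_te))
            # training rows come exactly from the other subjects
            others = np.vstack([X_all[s] for s in X_all if s != held])
            np.testing.assert_array_equal(np.sort(X_tr, axis=0),
                                          np.sort(others, axis=0))
            return [LabelSet.normal_set()] * len(X_te)

        c2.loso_cv(groups, fit_predict)

    def test_memorizer_scores_lower_out_of_subject(self, rng):
        """A lookup classifier is perfect in-sample but only as good as
        chance structure allows across subjects."""
        groups = _toy_groups(rng, subjects=4, n=60)

        def memorizer(X_tr, y_tr, X_te):
            table = {tuple(x): y for x, y in zip(X_tr, y_tr)}
            return [table.get(tuple(x), LabelSet.normal_set())
                    for x in X_te]

        loso = c2.loso_cv(groups, memorizer)
        in_sample = []
        for s, (X, y) in groups.items():
            in_sample.append(
                c2.mlc_metrics_labelsets(y, memorizer(X, y, X)).f1)
        assert np.mean(in_sample) == 1.0
        assert loso.mean("f1") < 1.0

    def test_single_subject_is_error(self, rng):
        with pytest.raises(ValueError):
            c2.loso_cv(dict(list(_toy_groups(rng).items())[:1]),
                       lambda *a: [])

    def test_mean_and_std_over_folds(self):
        m = c2.MLCMetrics
        folds = (FoldResult("a", m(1.0, 1.0, 1.0, 0.0), 10),
                 FoldResult("b", m(0.5, 0.5, 0.5, 0.2), 10))
        cv = c2.CVResult(folds=folds)
        assert cv.mean("f1") == pytest.approx(0.75)
        assert cv.std("f1") == pytest.approx(0.25)


class TestLoeoCV:
    def test_two_symmetric_folds(self, rng):
        d1 = (rng.normal(size=(30, 4)),
              [LabelSet.normal_set()] * 30)
        d2 = (rng.normal(size=(25, 4)),
              [LabelSet.normal_set()] * 25)

        def fit_predict(X_tr, y_tr, X_te):
            return [LabelSet.normal_set()] * len(X_te)

        result = c2.loeo_cv(d1, d2, fit_predict)
        assert len(result.folds) == 2
        assert {f.key for f in result.folds} == {"E1", "E2"}
        assert result.mean("f1") == 1.0

    def test_scenario_mismatch_rejected(self, rng):
        d = (rng.normal(size=(10, 4)), [LabelSet.normal_set()] * 10)
        with pytest.raises(ValueError, match="scenario"):
            c2.loeo_cv(d, d, lambda *a: [], scenarios=("S1", "S2"))
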