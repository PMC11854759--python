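"""Tests of confusion-matrix metrics and cross-validated evaluation."""

import numpy as np
import pytest

from mseeg import (
    ClassifierSpec,
    ConfusionCounts,
    DEFAULT_CLASSIFIERS,
    FeatureMatrix,
    crossvalidate,
    metrics_from_counts,
)
from mseeg.classify import NearestTieKNN, make_estimator

from _oracles import metrics_oracle


class TestMetricsFromCounts:
    def test_perfect_classifier_all_ones(self):
        m = metrics_from_counts(ConfusionCounts(50, 0, 0, 50))
        assert all(v == 1.0 for v in m.values())

    def test_symmetric_chance_all_half(self):
        m = metrics_from_counts(ConfusionCounts(25, 25, 25, 25))
        assert all(v == 0.5 for v in m.values())

    def test_direct_substitution(self):
        m = metrics_from_counts(ConfusionCounts(90, 10, 20, 80))
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["sensitivity"] == pytest.approx(90 / 110)
        assert m["specificity"] == pytest.approx(80 / 90)
        assert m["f1"] == pytest.approx(180 / 210)

    def test_thousand_random_quadruples_match_oracle(self, rng):
        for _ in range(1000):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 200, 4))
            if tp + fp + fn + tn == 0:
                continue
            got = metrics_from_counts(ConfusionCounts(tp, fp, fn, tn))
            want = metrics_oracle(tp, fp, fn, tn)
            for k in got:
                if np.isnan(want[k]):
                    assert np.isnan(got[k])
                else:
                    assert got[k] == pytest.approx(want[k], abs=1e-12)

    def test_f1_equals_one_iff_no_errors(self, rng):
        assert metrics_from_counts(ConfusionCounts(10, 0, 0, 5))["f1"] == 1.0
        for fp, fn in [(1, 0), (0, 1), (3, 2)]:
            m = metrics_from_counts(ConfusionCounts(10, fp, fn, 5))
            assert m["f1"] < 1.0

    def test_undefined_denominator_flagged_nan(self):
        m = metrics_from_counts(ConfusionCounts(0, 0, 0, 10))
        assert np.isnan(m["sensitivity"]) and np.isnan(m["f1"])
        assert m["accuracy"] == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(ConfusionCounts(0, 0, 0, 0))
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 5)


def make_matrix(X, y, scale=1):
    n = X.shape[1]
    cols = [f"c{i}_RCMSE" for i in range(n // 2)] + \
           [f"c{i}_RCMPE" for i in range(n // 2)]
    return FeatureMatrix(X, np.asarray(y, dtype=object),
                         np.array([f"s{i}" for i in range(len(X))],
                                  dtype=object), scale, cols)


class TestCrossValidate:
    def _separable(self, rng, n=60):
        X = np.vstack([rng.normal(0, 0.1, (n, 4)),
                       rng.normal(5, 0.1, (n, 4))])
        y = ["HC"] * n + ["MDD"] * n
        return make_matrix(X, y)

    @pytest.mark.parametrize("spec", DEFAULT_CLASSIFIERS,
                             ids=lambda s: s.kind)
    def test_separable_clusters_perfect_accuracy(self, rng, spec):
        fm = self._separable(rng)
        res = crossvalidate(fm, spec, k=10, seed=0)
        assert res["accuracy"] == 1.0
        assert res["f1"] == 1.0

    def test_permuted_labels_near_chance(self, rng):
        accs = []
        for seed in range(3):
            X = rng.standard_normal((400, 6))
            y = np.array(["HC", "MDD"] * 200, dtype=object)
            rng.shuffle(y)
            fm = make_matrix(X, y)
            res = crossvalidate(fm, ClassifierSpec("LDA"), k=10, seed=seed)
            accs.append(res["accuracy"])
        assert all(abs(a - 0.5) <= 0.08 for a in accs)

    def test_seeded_cv_bit_reproducible(self, rng):
        fm = self._separable(rng, n=30)
        spec = ClassifierSpec("RBF-SVM")
        assert crossvalidate(fm, spec, seed=3) == \
            crossvalidate(fm, spec, seed=3)

    def test_every_sample_in_exactly_one_test_fold(self, rng):
        from sklearn.model_selection import StratifiedKFold
        y = np.array([0] * 25 + [1] * 25)
        X = rng.standard_normal((50, 3))
        seen = np.zeros(50, dtype=int)
        for _, test in StratifiedKFold(10, shuffle=True,
                                       random_state=1).split(X, y):
            seen[test] += 1
        assert (seen == 1).all()

    def test_single_class_rejected(self, rng):
        fm = make_matrix(rng.standard_normal((30, 4)), ["HC"] * 30)
        with pytest.raises(ValueError):
            crossvalidate(fm, ClassifierSpec("LDA"))

    def test_subject_grouped_mode_keeps_subjects_together(self, rng):
        X = rng.standard_normal((40, 4))
        y = ["HC"] * 20 + ["MDD"] * 20
        fm = make_matrix(X, y)
        fm.subject_ids = np.array([f"subj{i // 4}" for i in range(40)],
                                  dtype=object)
        res = crossvalidate(fm, ClassifierSpec("LDA"), k=5, seed=0,
                            subject_grouped=True)
        assert 0.0 <= res["accuracy"] <= 1.0


class TestKNNTieBreak:
    def test_tie_falls_to_nearest_neighbour(self):
        # 2 neighbours, one of each class; nearest is class 1
        X = np.array([[0.1], [0.9]])
        y = np.array([1, 0])
        clf = NearestTieKNN(k=2).fit(X, y)
        assert clf.predict([[0.2]])[0] == 1
        assert clf.predict([[0.8]])[0] == 0

    def test_majority_wins_when_no_tie(self):
        X = np.array([[0.0], [1.0], [1.1], [1.2]])
        y = np.array([1, 0, 0, 0])
        clf = NearestTieKNN(k=4).fit(X, y)
        assert clf.predict([[0.05]])[0] == 0


class TestEstimators:
    def test_rbf_gamma_follows_kernel_scale_convention(self):
        est = make_estimator(ClassifierSpec("RBF-SVM", svm_kernel_scale=6.2))
        assert est.gamma == pytest.approx(1 / 6.2**2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("MLP")


class TestScaleScan:
    def test_grid_shape_four_classifiers_by_tau_max(self,
                                                    small_cohort_epochs):
        from mseeg import EntropyConfig, scale_scan
        _, epochs = small_cohort_epochs
        table = scale_scan(epochs, EntropyConfig(tau_max=10), seed=0)
        assert table.grid("accuracy").shape == (4, 10)
        assert set(table.df["classifier"]) == {"LDA", "LR", "RBF-SVM",
                                               "KNN"}
        avg = table.classifier_average()
        assert avg.shape == (10, 4)
        assert ((table.df[["accuracy", "sensitivity", "specificity",
                           "f1"]] >= 0).all().all())
        assert ((table.df[["accuracy", "sensitivity", "specificity",
                           "f1"]] <= 1).all().all())
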