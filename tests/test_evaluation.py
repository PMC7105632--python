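"""Metric identities, AUC conventions, jackknife evaluation and grid search."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phagehydro as ph
from phagehydro.evaluation import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, cv_accuracy
from phagehydro.exceptions import ConfigError, PhageHydroError


def mcc_as_label_correlation(tp, tn, fp, fn):
    """Oracle: MCC equals the Pearson correlation of predicted/true labels."""
    y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
    y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
    if y_true.std() == 0 or y_pred.std() == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1])


class TestComputeMetrics:
    def test_hand_computed_example(self):
        r = ph.compute_metrics(3, 3, 1, 1)
        assert r.sn == pytest.approx(0.75)
        assert r.sp == pytest.approx(0.75)
        assert r.ac == pytest.approx(0.75)
        assert r.mcc == pytest.approx(0.5)

    def test_perfect_classifier(self):
        r = ph.compute_metrics(5, 5, 0, 0)
        assert (r.sn, r.sp, r.ac, r.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_predictor_has_zero_mcc(self):
        # everything called positive on a balanced set
        r = ph.compute_metrics(5, 0, 5, 0)
        assert r.mcc == 0.0
        assert r.ac == 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(PhageHydroError):
            ph.compute_metrics(-1, 3, 1, 1)

    @given(
        st.tuples(
            st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
        ).filter(lambda t: sum(t) > 0)
    )
    def test_mcc_equals_label_correlation(self, counts):
        tp, tn, fp, fn = counts
        r = ph.compute_metrics(tp, tn, fp, fn)
        assert r.mcc == pytest.approx(mcc_as_label_correlation(tp, tn, fp, fn), abs=1e-12)
        assert -1.0 <= r.mcc <= 1.0
        assert r.n == tp + tn + fp + fn


class TestRocAuc:
    def test_perfect_ordering(self):
        assert ph.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_reversed_ordering(self):
        assert ph.roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_all_tied_is_half(self):
        assert ph.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_negation_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]  # both classes guaranteed
        assert ph.roc_auc(scores, labels) == pytest.approx(1 - ph.roc_auc(-scores, labels))

    def test_single_class_errors(self):
        with pytest.raises(PhageHydroError):
            ph.roc_auc([0.1, 0.2], [1, 1])


class TestJackknife:
    def test_separable_blobs_are_perfect(self, separable_matrix):
        report = ph.jackknife_evaluate(separable_matrix, ph.ClassifierSpec())
        assert report.ac == 1.0
        assert report.auc == 1.0

    def test_confusion_counts_account_for_every_sample(self, random_labelled_matrix):
        report = ph.jackknife_evaluate(random_labelled_matrix, ph.ClassifierSpec())
        assert report.n == random_labelled_matrix.n_samples

    def test_permuted_labels_destroy_signal(self, separable_matrix):
        rng = np.random.default_rng(0)
        m = separable_matrix
        permuted = ph.FeatureMatrix(m.sample_ids, m.names, m.values, rng.permutation(m.labels))
        report = ph.jackknife_evaluate(permuted, ph.ClassifierSpec())
        assert 0.3 <= report.ac <= 0.7

    def test_bit_reproducible_for_deterministic_kinds(self, random_labelled_matrix):
        r1 = ph.jackknife_evaluate(random_labelled_matrix, ph.ClassifierSpec())
        r2 = ph.jackknife_evaluate(random_labelled_matrix, ph.ClassifierSpec())
        assert (r1.tp, r1.tn, r1.fp, r1.fn) == (r2.tp, r2.tn, r2.fp, r2.fn)
        assert r1.per_sample_scores == r2.per_sample_scores

    def test_stochastic_kinds_reproducible_given_seed(self, separable_matrix):
        spec = ph.ClassifierSpec("random-forest", {"n_estimators": 20}, seed=5)
        r1 = ph.jackknife_evaluate(separable_matrix, spec)
        r2 = ph.jackknife_evaluate(separable_matrix, spec)
        assert r1.per_sample_scores == r2.per_sample_scores

    def test_unlabelled_matrix_rejected(self, random_labelled_matrix):
        m = random_labelled_matrix
        unlabelled = ph.FeatureMatrix(m.sample_ids, m.names, m.values)
        with pytest.raises(PhageHydroError):
            ph.jackknife_evaluate(unlabelled, ph.ClassifierSpec())


class TestGridSearch:
    def test_single_point_grid_returned(self, separable_matrix):
        spec = ph.grid_search_hyperparameters(
            separable_matrix, c_grid=[2.0], gamma_grid=[0.5], cv=5
        )
        assert spec.hyperparameters == {"C": 2.0, "gamma": 0.5}

    def test_empty_grid_rejected(self, separable_matrix):
        with pytest.raises(ConfigError):
            ph.grid_search_hyperparameters(separable_matrix, c_grid=[], cv=5)

    def test_winner_beats_every_grid_point(self, random_labelled_matrix):
        m = random_labelled_matrix
        c_grid, gamma_grid = [0.5, 8.0], [0.01, 1.0]
        best = ph.grid_search_hyperparameters(m, c_grid=c_grid, gamma_grid=gamma_grid, cv=5)
        best_acc = cv_accuracy(
            m.values, m.labels, best, cv=5
        )
        for c in c_grid:
            for gamma in gamma_grid:
                spec = ph.ClassifierSpec("svm-rbf", {"C": c, "gamma": gamma})
                assert best_acc >= cv_accuracy(m.values, m.labels, spec, cv=5)

    def test_ties_resolve_to_smallest_c_then_gamma(self, separable_matrix):
        # fully separable: every grid point reaches accuracy 1.0
        best = ph.grid_search_hyperparameters(
            separable_matrix, c_grid=[1.0, 4.0], gamma_grid=[0.1, 0.5], cv=5
        )
        assert best.hyperparameters == {"C": 1.0, "gamma": 0.1}

    def test_default_grids_are_log2_spaced(self):
        assert DEFAULT_C_GRID[0] == 2.0**-5 and DEFAULT_C_GRID[-1] == 2.0**15
        assert DEFAULT_GAMMA_GRID[0] == 2.0**-15 and DEFAULT_GAMMA_GRID[-1] == 2.0**3


class TestCompareClassifiers:
    def test_four_kind_table_layout(self, separable_matrix):
        specs = [
            ph.ClassifierSpec("k-nearest-neighbor"),
            ph.ClassifierSpec("random-forest", {"n_estimators": 20}, seed=1),
            ph.ClassifierSpec("svm-rbf"),
            ph.ClassifierSpec("multilayer-perceptron", {"max_iter": 200}, seed=1),
        ]
        table = ph.compare_classifiers(separable_matrix, specs)
        assert list(table.columns) == ["classifier", "Sn", "Sp", "Ac", "MCC", "AUC"]
        assert len(table) == 4
        svm_row = table[table.classifier == "svm-rbf"].iloc[0]
        assert svm_row.Ac >= 0.9

    def test_identical_specs_give_identical_rows(self, separable_matrix):
        spec = ph.ClassifierSpec("random-forest", {"n_estimators": 20}, seed=3)
        table = ph.compare_classifiers(separable_matrix, [spec, spec])
        assert table.iloc[0].equals(table.iloc[1])

    def test_empty_spec_list_rejected(self, separable_matrix):
        with pytest.raises(ConfigError):
            ph.compare_classifiers(separable_matrix, [])


def test_invalid_svm_hyperparameters_rejected():
    with pytest.raises(ConfigError):
        ph.ClassifierSpec("svm-rbf", {"C": -1.0})
    with pytest.raises(ConfigError):
        ph.ClassifierSpec("svm-rbf", {"gamma": 0.0})
    with pytest.raises(ConfigError):
        ph.ClassifierSpec("boosted-stump")
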