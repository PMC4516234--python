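import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytopred.cohort import VariableSpec
from cytopred.models import (
    ConfusionCounts,
    DegenerateTrainingError,
    KernelRanges,
    KernelSpec,
    UndefinedBCRError,
    bcr,
    clinical_kernel_matrix,
    clinical_kernel_value,
    combined_kernel_matrix,
    confusion,
    fit_kernel_ranges,
    train_predict,
)


class TestBCR:
    def test_hand_counted_confusion(self):
        """TP=3 FN=1 TN=2 FP=2: Se 0.75, Sp 0.50, BCR 0.625."""
        assert bcr(ConfusionCounts(3, 1, 2, 2)) == pytest.approx(0.625)

    def test_perfect_predictions(self):
        assert bcr(ConfusionCounts(5, 0, 7, 0)) == 1.0

    def test_constant_positive_predictor(self):
        assert bcr(ConfusionCounts(5, 0, 0, 7)) == 0.5

    def test_role_swap_invariance(self):
        a = bcr(ConfusionCounts(3, 1, 2, 2))
        b = bcr(ConfusionCounts(2, 2, 3, 1))  # classes and (Se,Sp) swapped
        assert a == pytest.approx(b)

    def test_absent_truth_class_undefined(self):
        with pytest.raises(UndefinedBCRError):
            bcr(ConfusionCounts(0, 0, 4, 1))

    def test_confusion_counts_from_vectors(self):
        c = confusion([1, 1, 1, 1, 0, 0, 0, 0], [1, 1, 1, 0, 1, 1, 0, 0])
        assert (c.tp, c.fn, c.tn, c.fp) == (3, 1, 2, 2)


VT = ("continuous", "binary")


class TestClinicalKernel:
    def test_identical_profiles_give_one(self):
        assert clinical_kernel_value([2.0, 1.0], [2.0, 1.0], VT,
                                     [0.0, 0.0], [10.0, 1.0]) == 1.0

    def test_range_extremes_give_zero(self):
        assert clinical_kernel_value([0.0], [10.0], ("continuous",),
                                     [0.0], [10.0]) == 0.0

    def test_hand_evaluated_mixed_pair(self):
        """Continuous on [0,10] with |2-4| -> 0.8, equal nominal -> 1;
        unweighted mean 0.9."""
        v = clinical_kernel_value([2.0, 1.0], [4.0, 1.0],
                                  ("continuous", "nominal"), [0.0, 0.0],
                                  [10.0, 1.0])
        assert v == pytest.approx(0.9)

    def test_zero_range_contributes_one(self):
        assert clinical_kernel_value([3.0], [3.0], ("ordinal",), [3.0], [3.0]) == 1.0

    def test_out_of_range_test_values_clipped(self):
        v = clinical_kernel_value([-50.0], [5.0], ("continuous",), [0.0], [10.0])
        assert v == 0.0

    def test_missing_values_are_a_contract_violation(self):
        with pytest.raises(ValueError):
            clinical_kernel_value([np.nan], [1.0], ("continuous",), [0.0], [1.0])

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        A = np.column_stack([rng.uniform(0, 10, 4), rng.integers(0, 2, 4)])
        lo, hi = A.min(axis=0), A.max(axis=0)
        K = clinical_kernel_matrix(A, A, VT, lo, hi)
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)
        assert (K >= -1e-12).all() and (K <= 1 + 1e-12).all()


class TestCombinedKernel:
    def _blocks(self, seed=0, n=5):
        rng = np.random.default_rng(seed)
        cyto = rng.normal(size=(n, 3))
        clin = np.column_stack([rng.uniform(0, 4, n), rng.integers(0, 2, n)])
        return cyto, clin

    def test_clinical_only_reduces_to_clinical_kernel(self):
        cyto, clin = self._blocks()
        ranges = fit_kernel_ranges(cyto, clin, VT)
        K = combined_kernel_matrix(cyto, cyto, clin, clin,
                                   KernelSpec("clinical_only"), ranges)
        ref = clinical_kernel_matrix(clin, clin, VT, ranges.clin_min,
                                     ranges.clin_max)
        assert np.allclose(K, ref)

    def test_train_gram_symmetric_unit_diagonal(self):
        cyto, clin = self._blocks(seed=1)
        ranges = fit_kernel_ranges(cyto, clin, VT)
        K = combined_kernel_matrix(cyto, cyto, clin, clin,
                                   KernelSpec("average"), ranges)
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)

    @pytest.mark.parametrize("combination",
                             ["average", "cytokine_only", "clinical_only"])
    def test_positive_semidefinite_on_random_samples(self, combination):
        for seed in range(5):
            cyto, clin = self._blocks(seed=seed)
            ranges = fit_kernel_ranges(cyto, clin, VT)
            K = combined_kernel_matrix(cyto, cyto, clin, clin,
                                       KernelSpec(combination), ranges)
            eig = np.linalg.eigvalsh((K + K.T) / 2)
            assert eig.min() >= -1e-10

    def test_zero_variance_cytokine_feature_warns_and_excluded(self):
        cyto, clin = self._blocks(seed=2)
        cyto[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            ranges = fit_kernel_ranges(cyto, clin, VT)
        assert np.isnan(ranges.cyto_sd[1])
        K = combined_kernel_matrix(cyto, cyto, clin, clin,
                                   KernelSpec("cytokine_only"), ranges)
        assert np.isfinite(K).all()


def _specs(n_cyto, clin_types=()):
    specs = [VariableSpec(name=f"c{i}", vtype="continuous", provenance="cytokine",
                          cytokine="IL2", stimulation="LPS", duration_h=24,
                          timepoint="CB")
             for i in range(n_cyto)]
    specs += [VariableSpec(name=f"k{i}", vtype=vt, provenance="clinical")
              for i, vt in enumerate(clin_types)]
    return specs


class TestClassifiers:
    def test_one_nn_returns_nearest_training_label(self):
        specs = _specs(0, ("continuous",))
        X_train = np.array([[0.0], [10.0]])
        y = np.array([0, 1])
        pred = train_predict("one_nn", X_train, y, np.array([[10.0]]), specs)
        assert pred.tolist() == [1]

    def test_one_nn_tie_goes_to_smallest_training_index(self):
        specs = _specs(0, ("continuous",))
        X_train = np.array([[0.0], [4.0]])
        y = np.array([1, 0])
        # test point equidistant from both training points
        pred = train_predict("one_nn", X_train, y, np.array([[2.0]]), specs)
        assert pred.tolist() == [1]
        # and with the labels attached the other way round
        pred = train_predict("one_nn", X_train, y[::-1].copy(),
                             np.array([[2.0]]), specs)
        assert pred.tolist() == [0]

    @pytest.mark.parametrize("classifier", ["random_forest", "svm", "one_nn"])
    def test_separable_feature_gives_perfect_bcr(self, classifier):
        """All positives above all negatives with a clear margin: every
        classifier separates held-out points from the same supports."""
        rng = np.random.default_rng(5)
        lo = rng.uniform(0.0, 1.0, 20)
        hi = rng.uniform(5.0, 6.0, 20)
        X_train = np.concatenate([lo, hi])[:, None]
        y_train = np.repeat([0, 1], 20)
        X_test = np.concatenate([rng.uniform(0, 1, 10),
                                 rng.uniform(5, 6, 10)])[:, None]
        y_test = np.repeat([0, 1], 10)
        pred = train_predict(classifier, X_train, y_train, X_test, _specs(1),
                             seed=0)
        from cytopred.models import bcr, confusion
        assert bcr(confusion(y_test, pred)) == 1.0

    def test_random_forest_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        T = rng.normal(size=(10, 3))
        a = train_predict("random_forest", X, y, T, _specs(3), seed=42)
        b = train_predict("random_forest", X, y, T, _specs(3), seed=42)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("classifier", ["random_forest", "svm", "one_nn"])
    def test_training_order_permutation_invariance(self, classifier):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, 30)
        T = rng.normal(size=(8, 3))
        perm = rng.permutation(30)
        a = train_predict(classifier, X, y, T, _specs(3), seed=9)
        b = train_predict(classifier, X[perm], y[perm], T, _specs(3), seed=9)
        assert np.array_equal(a, b)

    def test_mixed_signature_uses_averaged_kernel(self):
        rng = np.random.default_rng(8)
        n = 24
        X = np.column_stack([rng.normal(size=n), rng.uniform(0, 3, n),
                             rng.integers(0, 2, n)])
        y = rng.integers(0, 2, n)
        specs = _specs(1, ("continuous", "binary"))
        pred = train_predict("svm", X[:20], y[:20], X[20:], specs, seed=0)
        assert set(pred.tolist()) <= {0, 1}

    def test_single_class_training_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            train_predict("one_nn", np.zeros((3, 1)), np.array([1, 1, 1]),
                          np.zeros((1, 1)), _specs(1))

    def test_incomplete_matrices_rejected(self):
        X = np.array([[np.nan], [1.0]])
        with pytest.raises(ValueError):
            train_predict("one_nn", X, np.array([0, 1]), np.zeros((1, 1)),
                          _specs(1))
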