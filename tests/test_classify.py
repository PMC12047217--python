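"""SVM decision function, one-vs-rest voting and Cohen's kappa."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score
from sklearn.svm import SVC

import reefplan as rp
from reefplan.classify import (
    classification_demo,
    confusion_matrix,
    from_sklearn,
    segments_to_dataframe,
)


class TestDecisionFunction:
    def test_empty_support_set_returns_bias(self):
        model = rp.SVMModel(
            support_vectors=np.empty((0, 3)), dual_weights=np.empty(0),
            bias=-0.7, kernel="linear",
        )
        assert rp.svm_decision([1.0, 2.0, 3.0], model) == pytest.approx(-0.7)

    def test_linear_kernel_hand_example(self):
        # one SV (1, 0) with weight 2 and bias -1: f((1,1)) = 2*1 - 1 = 1
        model = rp.SVMModel(
            support_vectors=np.array([[1.0, 0.0]]),
            dual_weights=np.array([2.0]), bias=-1.0, kernel="linear",
        )
        assert rp.svm_decision([1.0, 1.0], model) == pytest.approx(1.0)

    def test_rbf_at_support_vector_returns_weight(self):
        model = rp.SVMModel(
            support_vectors=np.array([[0.3, -0.2, 1.1]]),
            dual_weights=np.array([2.5]), bias=0.0, kernel="rbf",
        )
        assert rp.svm_decision([0.3, -0.2, 1.1], model) == pytest.approx(2.5)

    def test_dimension_mismatch_rejected(self):
        model = rp.SVMModel(
            support_vectors=np.ones((2, 4)), dual_weights=np.ones(2), bias=0.0
        )
        with pytest.raises(ValueError, match="dimension"):
            rp.svm_decision([1.0, 2.0], model)

    @pytest.mark.parametrize("kernel", ["linear", "rbf"])
    def test_matches_sklearn_decision_function(self, kernel):
        """Dual-form evaluation agrees with the trainer's own on new points."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, 1, -1)
        svc = SVC(kernel=kernel, gamma=0.25 if kernel == "rbf" else "scale")
        svc.fit(X, y)
        model = from_sklearn(svc)
        X_new = rng.normal(size=(20, 4))
        ours = np.array([rp.svm_decision(x, model) for x in X_new])
        theirs = svc.decision_function(X_new)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    @settings(derandomize=True, max_examples=30)
    @given(c=st.floats(0.1, 10), x0=st.floats(-2, 2), x1=st.floats(-2, 2))
    def test_linear_in_dual_weights(self, c, x0, x1):
        sv = np.array([[0.5, -1.0], [1.5, 0.25]])
        w = np.array([1.2, -0.8])
        m1 = rp.SVMModel(sv, w, bias=0.4, kernel="rbf", gamma=0.5)
        m2 = rp.SVMModel(sv, c * w, bias=c * 0.4, kernel="rbf", gamma=0.5)
        f1 = rp.svm_decision([x0, x1], m1)
        f2 = rp.svm_decision([x0, x1], m2)
        assert f2 == pytest.approx(c * f1, rel=1e-9, abs=1e-12)


class TestMulticlassVoting:
    def _bias_models(self, biases):
        return {
            name: rp.SVMModel(
                support_vectors=np.empty((0, 2)),
                dual_weights=np.empty(0), bias=b, kernel="linear",
            )
            for name, b in biases.items()
        }

    def test_argmax_of_scores(self):
        models = self._bias_models(
            {"coral": 2.0, "seagrass": -1.0, "mangrove": 0.5}
        )
        assert rp.svm_classify_multiclass([0.0, 0.0], models) == "coral"

    def test_tie_broken_by_class_order(self):
        models = self._bias_models({"coral": 1.0, "seagrass": 1.0})
        assert rp.svm_classify_multiclass([0.0, 0.0], models) == "coral"

    def test_opposite_biases_reduce_to_higher_bias(self):
        models = self._bias_models({"a": -0.5, "b": 0.5})
        assert rp.svm_classify_multiclass([0.0, 0.0], models) == "b"

    def test_invariant_to_constant_score_shift(self):
        rng = np.random.default_rng(3)
        sv = rng.normal(size=(3, 2))
        base = {
            name: rp.SVMModel(sv, rng.normal(size=3), bias=float(b))
            for name, b in [("a", 0.1), ("b", -0.2), ("c", 0.4)]
        }
        shifted = {
            name: rp.SVMModel(
                m.support_vectors, m.dual_weights, m.bias + 5.0,
                kernel=m.kernel, gamma=m.gamma,
            )
            for name, m in base.items()
        }
        for _ in range(10):
            x = rng.normal(size=2)
            assert rp.svm_classify_multiclass(x, base) == \
                rp.svm_classify_multiclass(x, shifted)

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            rp.svm_classify_multiclass([0.0], self._bias_models({"a": 1.0}))


class TestCohenKappa:
    def test_perfect_diagonal_is_one(self):
        assert rp.cohen_kappa(np.diag([5, 9, 3])) == pytest.approx(1.0)

    def test_hand_example(self):
        # p_o = 70/100, p_e = (50*60 + 50*40)/100^2 = 0.5 -> kappa 0.4
        assert rp.cohen_kappa([[40, 10], [20, 30]]) == pytest.approx(0.4)

    def test_uniform_matrix_is_chance_level(self):
        assert rp.cohen_kappa(np.full((3, 3), 7)) == pytest.approx(0.0, abs=1e-12)

    def test_empty_or_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            rp.cohen_kappa(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            rp.cohen_kappa(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            rp.cohen_kappa([[1, 2, 3], [4, 5, 6]])

    @settings(derandomize=True, max_examples=50)
    @given(
        cm=st.lists(
            st.lists(st.integers(0, 50), min_size=3, max_size=3),
            min_size=3, max_size=3,
        ).filter(lambda m: sum(map(sum, m)) > 0)
    )
    def test_bounded_and_matches_sklearn(self, cm):
        cm = np.array(cm)
        k = rp.cohen_kappa(cm)
        assert -1.0 - 1e-9 <= k <= 1.0 + 1e-9
        # independent oracle: expand the matrix back into label pairs
        y_true, y_pred = [], []
        for i in range(3):
            for j in range(3):
                y_true += [i] * cm[i, j]
                y_pred += [j] * cm[i, j]
        if len(set(y_true)) > 1 or len(set(y_pred)) > 1:
            assert k == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-9
            )


class TestSyntheticSegments:
    def test_empty_when_n_zero(self):
        X, y = rp.synthetic_segments(0, seed=1)
        assert len(X) == 0 and len(y) == 0

    def test_same_seed_reproduces(self):
        X1, y1 = rp.synthetic_segments(20, seed=7)
        X2, y2 = rp.synthetic_segments(20, seed=7)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)

    def test_invalid_covariance_rejected(self):
        means = {"a": np.zeros(2), "b": np.ones(2)}
        bad = {"a": np.array([[1.0, 2.0], [0.0, 1.0]]), "b": np.eye(2)}
        with pytest.raises(ValueError, match="symmetric"):
            rp.synthetic_segments(5, means, bad, seed=0)
        neg = {"a": -np.eye(2), "b": np.eye(2)}
        with pytest.raises(ValueError, match="semidefinite"):
            rp.synthetic_segments(5, means, neg, seed=0)

    def test_dataframe_layout(self):
        X, y = rp.synthetic_segments(4, seed=0)
        df = segments_to_dataframe(X, y)
        assert list(df.columns[:2]) == ["segment_id", "band_1"]
        assert df.shape == (12, 1 + X.shape[1] + 1)

    @pytest.mark.parametrize("kernel", ["linear", "rbf"])
    def test_separable_classes_reach_high_kappa(self, kernel):
        """Well-separated spectra give kappa at the accuracy level typical
        of shallow-water habitat maps (>= 0.8) on a held-out split."""
        result = classification_demo(n_per_class=100, kernel=kernel, seed=0)
        assert result["kappa"] >= 0.8

    def test_confusion_matrix_orientation(self):
        cm = confusion_matrix(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
        assert cm.loc["a", "b"] == 1  # reference a predicted as b
        assert cm.loc["b", "a"] == 0
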