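"""Kernels, binary soft-margin machines, and the one-against-others ensemble."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import SVC

from pcgclassify import (
    BinarySVM,
    Genome,
    InputError,
    InvalidGenomeError,
    KernelSpec,
    TrainingError,
    count_support_vectors,
    fixed_kernel_genome,
    kernel_eval,
    kernel_matrix,
    predict,
    train_binary_svm,
    train_ovr_ensemble,
)
from pcgclassify.genome import ClassifierGenes
from pcgclassify.svm import OvREnsemble, load_model, save_model

KERNELS = [
    KernelSpec("linear"),
    KernelSpec("quadratic"),
    KernelSpec("polynomial", u=3),
    KernelSpec("rbf", sigma=0.7),
]

vectors = st.lists(st.floats(-5, 5), min_size=3, max_size=3).map(np.array)


class TestKernels:
    def test_reference_values(self):
        assert kernel_eval(KernelSpec("linear"), [1, 2], [3, 4]) == pytest.approx(11.0)
        # x.y = 2 -> (2+1)^2 = 9 for the quadratic kind
        assert kernel_eval(KernelSpec("quadratic"), [2, 0], [1, 5]) == pytest.approx(9.0)
        assert kernel_eval(KernelSpec("polynomial", u=3), [1, 0], [1, 0]) == pytest.approx(8.0)
        assert kernel_eval(KernelSpec("rbf", sigma=2.0), [1, 1], [1, 1]) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(x=vectors, y=vectors, kernel=st.sampled_from(KERNELS))
    def test_symmetry(self, x, y, kernel):
        assert kernel_eval(kernel, x, y) == pytest.approx(kernel_eval(kernel, y, x))

    @settings(max_examples=50, deadline=None)
    @given(x=vectors, y=vectors)
    def test_rbf_bounds(self, x, y):
        v = kernel_eval(KernelSpec("rbf", sigma=1.0), x, y)
        assert 0 < v <= 1
        assert (v == pytest.approx(1.0)) == bool(np.allclose(x, y))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            kernel_eval(KernelSpec("linear"), [1, 2], [1, 2, 3])

    def test_invalid_spec_rejected(self):
        with pytest.raises(InputError):
            KernelSpec("rbf")  # missing sigma
        with pytest.raises(InputError):
            KernelSpec("polynomial")  # missing degree


class TestBinarySVM:
    def test_max_margin_on_two_points(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = [-1, 1]
        model = train_binary_svm(X, y, KernelSpec("linear"), C=1000.0)
        assert model.n_support == 2
        d = model.decision(X)
        assert d[0] < 0 < d[1]
        # the margin boundary passes midway between the two points
        assert model.decision([[0.5, 0.5]])[0] == pytest.approx(0.0, abs=1e-6)

    def test_xor_needs_a_nonlinear_kernel(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([1, 1, -1, -1])
        lin = train_binary_svm(X, y, KernelSpec("linear"), C=1000.0)
        assert np.sum(np.sign(lin.decision(X)) != y) >= 1
        rbf = train_binary_svm(X, y, KernelSpec("rbf", sigma=0.5), C=1000.0)
        assert np.all(np.sign(rbf.decision(X)) == y)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError, match="0 negative"):
            train_binary_svm(np.eye(3), [1, 1, 1], KernelSpec("linear"), C=1.0)

    @pytest.mark.parametrize("kernel", KERNELS, ids=lambda k: k.kind)
    def test_decision_reconstruction_matches_libsvm(self, kernel, rng):
        """Stored SVs + dual coefficients reproduce SVC's decision function."""
        X = rng.standard_normal((40, 6))
        y = np.where(X[:, 0] + 0.3 * X[:, 1] ** 2 > 0.2, 1, -1)
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        model = train_binary_svm(X, y, kernel, C=10.0)
        params = {
            "linear": {"kernel": "linear"},
            "quadratic": {"kernel": "poly", "degree": 2, "gamma": 1.0, "coef0": 1.0},
            "polynomial": {"kernel": "poly", "degree": 3, "gamma": 1.0, "coef0": 1.0},
            "rbf": {"kernel": "rbf", "gamma": 1 / (2 * 0.7**2)},
        }[kernel.kind]
        ref = SVC(C=10.0, **params).fit(X, y)
        T = rng.standard_normal((15, 6))
        np.testing.assert_allclose(model.decision(T), ref.decision_function(T), atol=1e-6)


class TestOvREnsemble:
    def test_twelve_class_ensemble(self, small_feature_set):
        X, y = small_feature_set
        genome = fixed_kernel_genome(12, kind="rbf", sigma=1.0, C=10.0)
        ens = train_ovr_ensemble(X, y, genome)
        assert ens.n_classes == 12
        assert [m.positive_class for m in ens.members] == ens.class_order

    def test_interpolation_regime_fits_training_set(self, small_feature_set):
        # tiny sigma + huge C: every distinct point becomes its own island
        X, y = small_feature_set
        genome = fixed_kernel_genome(12, kind="rbf", sigma=0.05, C=1e4)
        ens = train_ovr_ensemble(X, y, genome)
        assert ens.predict(X) == list(y)

    def test_two_class_decisions_anticorrelate(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (10, 4)), rng.normal(3, 0.3, (10, 4))])
        y = ["a"] * 10 + ["b"] * 10
        genome = fixed_kernel_genome(2, kind="linear", C=1.0, n_features=4)
        ens = train_ovr_ensemble(X, y, genome)
        D = ens.decision_values(X)
        assert np.corrcoef(D[:, 0], D[:, 1])[0, 1] < -0.9

    def test_empty_mask_rejected(self, small_feature_set):
        X, y = small_feature_set
        genome = Genome(
            mask=(False,) * 24,
            classifiers=(ClassifierGenes(kind="linear", C=1.0),) * 12,
        )
        with pytest.raises(InvalidGenomeError):
            train_ovr_ensemble(X, y, genome)

    def test_tie_breaks_to_lowest_class_index(self):
        def constant_member(bias, label):
            return BinarySVM(
                support_vectors=np.zeros((1, 2)),
                dual_coef=np.zeros(1),
                bias=bias,
                kernel=KernelSpec("linear"),
                C=1.0,
                positive_class=label,
            )

        ens = OvREnsemble(
            members=[constant_member(0.3, "a"), constant_member(0.3, "b"), constant_member(-1.0, "c")],
            class_order=["a", "b", "c"],
            feature_mask=(True, True),
        )
        assert predict(ens, np.zeros(2)) == "a"

    def test_wrong_dimension_rejected(self, small_feature_set):
        X, y = small_feature_set
        ens = train_ovr_ensemble(X, y, fixed_kernel_genome(12, kind="linear", C=1.0))
        with pytest.raises(InputError):
            ens.predict(np.zeros((1, 7)))

    def test_support_vector_count_bounds(self, small_feature_set):
        X, y = small_feature_set
        ens = train_ovr_ensemble(X, y, fixed_kernel_genome(12, kind="rbf", sigma=1.0, C=10.0))
        assert count_support_vectors(ens) >= 2 * ens.n_classes  # >=1 SV per side

    def test_two_point_margin_has_two_support_vectors(self):
        model = train_binary_svm(
            np.array([[0.0, 0.0], [1.0, 1.0]]), [-1, 1], KernelSpec("linear"), C=1000.0
        )
        assert model.n_support == 2


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, small_feature_set, tmp_path, rng):
        X, y = small_feature_set
        genome = fixed_kernel_genome(12, kind="rbf", sigma=0.5, C=100.0)
        ens = train_ovr_ensemble(X, y, genome)
        path = tmp_path / "model.json"
        save_model(ens, path, metadata={"lpc_order": 24})
        back, meta = load_model(path)
        assert meta["lpc_order"] == 24
        T = X + rng.normal(0, 0.01, X.shape)
        assert back.predict(T) == ens.predict(T)
        np.testing.assert_allclose(
            back.decision_values(T), ens.decision_values(T), atol=1e-12
        )
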