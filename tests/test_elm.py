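"""Regularized ELM: hidden layer, encoding, ridge solution, decoding."""

import numpy as np
import pytest

from ecgelm import elm
from ecgelm.elm import (
    ElmModel,
    encode_labels,
    decode_targets,
    hidden_output,
    init_hidden,
    load_model,
    predict_labels,
    predict_scores,
    save_model,
    train,
)


class TestInitHidden:
    def test_same_seed_identical_draw(self):
        A1, b1 = init_hidden(20, 50, seed=7)
        A2, b2 = init_hidden(20, 50, seed=7)
        np.testing.assert_array_equal(A1, A2)
        np.testing.assert_array_equal(b1, b2)

    def test_support_and_shape(self):
        A, b = init_hidden(20, 3000, seed=0)
        assert A.shape == (3000, 20) and b.shape == (3000,)
        assert np.all(A >= -1) and np.all(A <= 1)
        assert np.all(b >= -1) and np.all(b <= 1)

    def test_empirical_mean_near_zero(self):
        """U[-1,1] entries: mean within 4 sd / sqrt(count) of zero."""
        A, b = init_hidden(200, 500, seed=3)
        values = np.concatenate([A.ravel(), b])
        tol = 4 * (1 / np.sqrt(3)) / np.sqrt(values.size)
        assert abs(values.mean()) < tol

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            init_hidden(0, 5, seed=0)
        with pytest.raises(ValueError):
            init_hidden(5, 0, seed=0)


class TestHiddenOutput:
    def test_zero_input_zero_bias_gives_half(self):
        H = hidden_output(np.zeros((1, 3)), np.ones((2, 3)), np.zeros(2))
        np.testing.assert_allclose(H, 0.5)

    def test_hand_computed_preactivation(self):
        # a.x + b = 1*2 + (-0.5)*2 + (-1) = 0 -> sigmoid = 0.5
        A = np.array([[1.0, -0.5]])
        b = np.array([-1.0])
        H = hidden_output(np.array([[2.0, 2.0]]), A, b)
        np.testing.assert_allclose(H, 0.5)

    def test_matches_scalar_double_loop(self, rng):
        X = rng.normal(size=(5, 4))
        A, b = init_hidden(4, 6, seed=1)
        H = hidden_output(X, A, b)
        for i in range(5):
            for j in range(6):
                z = float(A[j] @ X[i] + b[j])
                assert H[i, j] == pytest.approx(1 / (1 + np.exp(-z)), rel=1e-12)

    def test_entries_strictly_in_unit_interval(self, rng):
        H = hidden_output(rng.normal(size=(10, 4)) * 5, *init_hidden(4, 8, seed=2))
        assert np.all(H > 0) and np.all(H < 1)

    def test_shape_mismatch_is_error(self, rng):
        A, b = init_hidden(4, 6, seed=1)
        with pytest.raises(ValueError, match="dimension"):
            hidden_output(rng.normal(size=(5, 3)), A, b)


class TestLabelEncoding:
    def test_single_label_row(self):
        T = encode_labels(["c2"], ["c1", "c2", "c3"])
        np.testing.assert_array_equal(T, [[-1.0, 1.0, -1.0]])

    def test_round_trip(self, rng):
        classes = ["N", "V", "A", "/"]
        labels = [classes[k] for k in rng.integers(0, 4, size=60)]
        assert decode_targets(encode_labels(labels, classes), classes) == labels

    def test_row_sums_are_two_minus_m(self, rng):
        classes = [f"c{k}" for k in range(7)]
        labels = [classes[k] for k in rng.integers(0, 7, size=40)]
        T = encode_labels(labels, classes)
        np.testing.assert_array_equal(T.sum(axis=1), np.full(40, 2.0 - 7))

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="'zz'"):
            encode_labels(["zz"], ["c1"])


class TestTrain:
    def test_scalar_closed_form(self):
        """N=L=m=1: beta = h t / (1/C + h^2)."""
        X = np.array([[0.3]])
        C = 2.0
        model = train(X, ["c1"], C=C, L=1, seed=5)
        h = float(hidden_output(X, model.A, model.b)[0, 0])
        assert model.beta[0, 0] == pytest.approx(h * 1.0 / (1 / C + h * h), rel=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_generic_ridge_oracle(self, trial):
        """beta equals an independent ridge regression on (H, T)."""
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(100 + trial)
        N, L, m = rng.integers(10, 50), rng.integers(2, 30), rng.integers(2, 4)
        X = rng.normal(size=(N, 5))
        classes = [f"c{k}" for k in range(m)]
        labels = [classes[k] for k in rng.integers(0, m, size=N)]
        C = 10.0 ** rng.integers(-2, 3)
        model = train(X, labels, C=C, L=int(L), seed=int(trial), classes=classes)
        H = hidden_output(X, model.A, model.b)
        T = encode_labels(labels, classes)
        oracle = Ridge(alpha=1 / C, fit_intercept=False).fit(H, T)
        np.testing.assert_allclose(model.beta, oracle.coef_.T, atol=1e-8)

    def test_primal_and_dual_forms_agree(self, rng):
        X = rng.normal(size=(8, 5))
        labels = ["a", "b"] * 4
        kw = dict(C=1.0, L=20, seed=9)
        primal = train(X, labels, solver="primal", **kw)
        dual = train(X, labels, solver="dual", **kw)
        np.testing.assert_allclose(primal.beta, dual.beta, atol=1e-8)

    def test_gradient_of_objective_vanishes_at_solution(self, rng):
        X = rng.normal(size=(40, 6))
        labels = [f"c{k % 3}" for k in range(40)]
        C = 0.5
        model = train(X, labels, C=C, L=15, seed=4)
        H = hidden_output(X, model.A, model.b)
        T = encode_labels(labels, model.classes)
        gradient = model.beta - C * H.T @ (T - H @ model.beta)
        assert np.abs(gradient).max() < 1e-6 * np.abs(H.T @ T).max()

    def test_perturbation_increases_objective(self, rng):
        X = rng.normal(size=(30, 4))
        labels = [f"c{k % 2}" for k in range(30)]
        C = 1.0
        model = train(X, labels, C=C, L=10, seed=6)
        H = hidden_output(X, model.A, model.b)
        T = encode_labels(labels, model.classes)

        def objective(beta):
            return 0.5 * np.sum(beta**2) + 0.5 * C * np.sum((T - H @ beta) ** 2)

        base = objective(model.beta)
        for _ in range(5):
            assert objective(model.beta + 1e-3 * rng.normal(size=model.beta.shape)) > base

    def test_min_norm_limit_as_C_grows(self, rng):
        """beta approaches the pseudoinverse solution monotonically in C."""
        X = rng.normal(size=(40, 6))
        labels = [f"c{k % 3}" for k in range(40)]
        seed = 11
        model0 = train(X, labels, C=1.0, L=12, seed=seed)  # N >= L, full column rank
        H = hidden_output(X, model0.A, model0.b)
        T = encode_labels(labels, model0.classes)
        target = np.linalg.pinv(H) @ T
        gaps = []
        for C in (1e2, 1e4, 1e6, 1e8):
            model = train(X, labels, C=C, L=12, seed=seed)
            gaps.append(np.linalg.norm(model.beta - target))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-6 * np.linalg.norm(target)

    def test_beta_norm_nondecreasing_in_C(self, rng):
        X = rng.normal(size=(25, 4))
        labels = [f"c{k % 2}" for k in range(25)]
        norms = [
            np.linalg.norm(train(X, labels, C=C, L=8, seed=2).beta)
            for C in (1e-3, 1e-1, 1e1, 1e3)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_determinism(self, rng):
        X = rng.normal(size=(20, 3))
        labels = [f"c{k % 2}" for k in range(20)]
        m1 = train(X, labels, C=1.0, L=10, seed=3)
        m2 = train(X, labels, C=1.0, L=10, seed=3)
        np.testing.assert_array_equal(m1.beta, m2.beta)

    def test_invalid_inputs(self, rng):
        X = rng.normal(size=(5, 2))
        labels = ["a", "b", "a", "b", "a"]
        with pytest.raises(ValueError, match="C"):
            train(X, labels, C=0.0, L=4, seed=0)
        X_bad = X.copy()
        X_bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train(X_bad, labels, C=1.0, L=4, seed=0)


class TestPredict:
    def test_interpolating_fit_reproduces_targets(self, rng):
        """Large C and L >= N: training scores sit on the +-1 targets."""
        X = rng.normal(size=(15, 4))
        labels = [f"c{k % 3}" for k in range(15)]
        model = train(X, labels, C=1e8, L=40, seed=8)
        scores = predict_scores(model, X)
        T = encode_labels(labels, model.classes)
        np.testing.assert_allclose(scores, T, atol=1e-3)

    def test_empty_input_gives_empty_scores(self, rng):
        X = rng.normal(size=(10, 3))
        labels = [f"c{k % 2}" for k in range(10)]
        model = train(X, labels, C=1.0, L=5, seed=1)
        assert predict_scores(model, np.empty((0, 3))).shape == (0, 2)
        assert predict_labels(model, np.empty((0, 3))) == []

    def test_invariant_under_training_row_permutation(self, rng):
        X = rng.normal(size=(30, 4))
        labels = [f"c{k % 3}" for k in range(30)]
        classes = ["c0", "c1", "c2"]
        perm = rng.permutation(30)
        m1 = train(X, labels, C=1.0, L=12, seed=5, classes=classes)
        m2 = train(X[perm], [labels[i] for i in perm], C=1.0, L=12, seed=5, classes=classes)
        probe = rng.normal(size=(6, 4))
        np.testing.assert_allclose(
            predict_scores(m1, probe), predict_scores(m2, probe), atol=1e-9
        )

    def test_argmax_decoding(self):
        model = ElmModel(
            A=np.zeros((2, 1)), b=np.zeros(2), C=1.0,
            classes=["c1", "c2", "c3"], seed=0,
            beta=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
        )
        # bypass the network: check the decoding rule directly on scores
        scores = np.array([[-0.9, 0.8, -1.0]])
        assert model.classes[int(np.argmax(scores))] == "c2"

    def test_exact_tie_takes_first_class(self, rng):
        """Two identical output columns: the lower class index wins."""
        X = rng.normal(size=(10, 2))
        labels = ["a", "b"] * 5
        model = train(X, labels, C=1.0, L=4, seed=0)
        model.beta = np.zeros_like(model.beta)  # all scores tie at 0
        assert predict_labels(model, X) == ["a"] * 10

    def test_untrained_model_refuses_to_score(self):
        model = ElmModel(A=np.zeros((2, 3)), b=np.zeros(2), C=1.0,
                         classes=["a", "b"], seed=0)
        with pytest.raises(ValueError, match="trained"):
            predict_scores(model, np.zeros((1, 3)))

    def test_separable_three_class_problem_fits_exactly(self):
        """200 well-separated samples: 100% training accuracy at L=200, C=1."""
        rng = np.random.default_rng(42)
        centers = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        X = np.vstack([rng.normal(c, 0.3, size=(67, 2)) for c in centers])[:200]
        labels = (["c0"] * 67 + ["c1"] * 67 + ["c2"] * 67)[:200]
        model = train(X, labels, C=1.0, L=200, seed=0)
        assert predict_labels(model, X) == labels


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        from ecgelm.features import Standardizer

        X = rng.normal(size=(20, 3))
        labels = [f"c{k % 2}" for k in range(20)]
        scaler = Standardizer(mu=np.zeros(3), sigma=np.ones(3))
        model = train(X, labels, C=0.5, L=7, seed=13, scaler=scaler)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.beta, model.beta)
        np.testing.assert_array_equal(back.A, model.A)
        assert back.classes == model.classes
        assert back.C == model.C and back.seed == model.seed
        np.testing.assert_allclose(
            predict_scores(back, X), predict_scores(model, X), atol=1e-12
        )

    def test_untrained_model_not_serializable(self, tmp_path):
        model = ElmModel(A=np.zeros((2, 3)), b=np.zeros(2), C=1.0,
                         classes=["a", "b"], seed=0)
        with pytest.raises(ValueError):
            save_model(model, tmp_path / "m.npz")
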