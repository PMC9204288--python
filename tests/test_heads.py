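import numpy as np
import pytest
import scipy.linalg

from randheads.heads import (
    ElmModel,
    FeatureMatrix,
    RandomHiddenLayer,
    RvflModel,
    SnnModel,
    TargetMatrix,
    hidden_output,
    load_model,
    make_hidden_layer,
    predict,
    save_model,
    sigmoid,
    train_elm,
    train_rvfl,
    train_snn,
)


def _sigmoid_loop(W, d, X):
    """Independent scalar-loop oracle for the hidden activation matrix."""
    N, V = X.shape[0], W.shape[0]
    out = np.empty((N, V))
    for i in range(N):
        for j in range(V):
            z = float(np.dot(W[j], X[i]) + d[j])
            out[i, j] = 1.0 / (1.0 + np.exp(-z))
    return out


def _lstsq_oracle(A, Y):
    """Independent minimum-norm least-squares solve (LAPACK gelsd via scipy)."""
    beta, *_ = scipy.linalg.lstsq(A, Y, lapack_driver="gelsd")
    return beta


class TestMakeHiddenLayer:
    def test_deterministic_under_fixed_seed(self):
        a = make_hidden_layer(2, 3, seed=7)
        b = make_hidden_layer(2, 3, seed=7)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.d, b.d)

    def test_default_hidden_node_count_shapes(self):
        layer = make_hidden_layer(1, 400, seed=0)
        assert layer.W.shape == (400, 1)
        assert layer.d.shape == (400,)

    @pytest.mark.parametrize("n,V", [(2, 0), (0, 3), (-1, 4), (2, -2)])
    def test_nonpositive_dims_rejected(self, n, V):
        with pytest.raises(ValueError):
            make_hidden_layer(n, V, seed=0)

    def test_entries_within_unit_range(self):
        layer = make_hidden_layer(4, 50, seed=3)
        assert np.all(np.abs(layer.W) <= 1)
        assert np.all(np.abs(layer.d) <= 1)

    def test_weights_are_frozen(self):
        layer = make_hidden_layer(2, 3, seed=0)
        with pytest.raises(ValueError):
            layer.W[0, 0] = 99.0


class TestHiddenOutput:
    def test_zero_weights_give_half(self):
        layer = RandomHiddenLayer(W=np.zeros((3, 2)), d=np.zeros(3), seed=0)
        A = hidden_output(layer, np.array([[1.0, -4.0], [0.2, 7.0]]))
        assert np.array_equal(A, np.full((2, 3), 0.5))

    def test_single_node_values(self):
        layer = RandomHiddenLayer(W=np.array([[1.0, 0.0]]), d=np.zeros(1), seed=0)
        A = hidden_output(layer, np.array([[0.0, 0.0], [10.0, 0.0]]))
        assert A[0, 0] == pytest.approx(0.5)
        assert A[1, 0] == pytest.approx(1.0 / (1.0 + np.exp(-10)), abs=1e-9)
        assert A[1, 0] == pytest.approx(0.99995, abs=1e-4)

    def test_matches_scalar_loop_oracle(self, rng):
        layer = make_hidden_layer(3, 4, seed=9)
        X = rng.normal(size=(5, 3))
        expected = _sigmoid_loop(layer.W, layer.d, X)
        assert np.allclose(hidden_output(layer, X), expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        layer = make_hidden_layer(3, 4, seed=0)
        with pytest.raises(ValueError):
            hidden_output(layer, rng.normal(size=(5, 2)))

    def test_activations_strictly_in_unit_interval(self, rng):
        layer = make_hidden_layer(4, 10, seed=1)
        A = hidden_output(layer, rng.normal(size=(20, 4)))
        assert np.all(A > 0) and np.all(A < 1)

    def test_monotone_in_input_when_weight_positive(self, rng):
        layer = make_hidden_layer(2, 6, seed=4)
        x = rng.normal(size=(1, 2))
        bumped = x.copy()
        bumped[0, 0] += 0.5
        lo, hi = hidden_output(layer, x)[0], hidden_output(layer, bumped)[0]
        pos = layer.W[:, 0] > 0
        assert np.all(hi[pos] >= lo[pos])
        assert np.all(hi[~pos] <= lo[~pos])


def _random_instance(rng, N, n, V, seed):
    X = rng.normal(size=(N, n))
    labels = rng.integers(0, 2, size=N)
    labels[0], labels[1] = 0, 1  # both classes present
    Y = TargetMatrix.from_labels(labels, m=2)
    return X, Y, make_hidden_layer(n, V, seed=seed)


class TestTrainSnn:
    def test_constant_target_is_fit_exactly(self, rng):
        X = rng.normal(size=(6, 2))
        Y = TargetMatrix(np.tile([0.3, 0.7], (6, 1)))
        model = train_snn(X, Y, make_hidden_layer(2, 3, seed=1))
        scores, _ = predict(model, X)
        assert np.linalg.norm(scores - Y.values) == pytest.approx(0.0, abs=1e-8)

    def test_matches_least_squares_oracle(self, rng):
        X, Y, layer = _random_instance(rng, 6, 2, 3, seed=1)
        model = train_snn(X, Y, layer)
        A = hidden_output(layer, X)
        beta = _lstsq_oracle(np.hstack([A, np.ones((6, 1))]), Y.values)
        assert np.allclose(np.vstack([model.P, model.q]), beta, atol=1e-8)

    def test_interpolates_at_full_row_rank(self, rng):
        X, Y, layer = _random_instance(rng, 4, 2, 8, seed=2)
        A_aug = np.hstack([hidden_output(layer, X), np.ones((4, 1))])
        assert np.linalg.matrix_rank(A_aug) == 4  # precondition for interpolation
        model = train_snn(X, Y, layer)
        scores, _ = predict(model, X)
        assert np.max(np.abs(scores - Y.values)) < 1e-6

    def test_empty_and_nonfinite_inputs_rejected(self):
        layer = make_hidden_layer(2, 3, seed=0)
        with pytest.raises(ValueError):
            train_snn(np.empty((0, 2)), np.empty((0, 2)), layer)
        with pytest.raises(ValueError):
            train_snn(np.array([[np.nan, 1.0]]), np.array([[1.0, 0.0]]), layer)

    def test_row_count_mismatch_rejected(self, rng):
        layer = make_hidden_layer(2, 3, seed=0)
        with pytest.raises(ValueError):
            train_snn(rng.normal(size=(5, 2)), np.eye(4)[:, :2], layer)


class TestTrainElm:
    def test_zero_targets_give_zero_weights(self, rng):
        X = rng.normal(size=(6, 2))
        model = train_elm(X, TargetMatrix(np.zeros((6, 2))), make_hidden_layer(2, 3, seed=1))
        assert np.array_equal(model.P, np.zeros((3, 2)))

    def test_matches_least_squares_oracle(self, rng):
        X, Y, layer = _random_instance(rng, 6, 2, 3, seed=1)
        model = train_elm(X, Y, layer)
        beta = _lstsq_oracle(hidden_output(layer, X), Y.values)
        assert np.allclose(model.P, beta, atol=1e-8)

    def test_interpolates_at_full_row_rank(self, rng):
        X, Y, layer = _random_instance(rng, 4, 2, 8, seed=2)
        A = hidden_output(layer, X)
        assert np.linalg.matrix_rank(A) == 4
        model = train_elm(X, Y, layer)
        scores, _ = predict(model, X)
        assert np.max(np.abs(scores - Y.values)) < 1e-6


class TestTrainRvfl:
    def test_degenerate_hidden_layer_collapses_to_linear_model(self, rng):
        X = rng.normal(size=(6, 2))
        labels = np.array([0, 1, 0, 1, 1, 0])
        Y = TargetMatrix.from_labels(labels)
        layer = RandomHiddenLayer(W=np.zeros((3, 2)), d=np.zeros(3), seed=0)
        model = train_rvfl(X, Y, layer)
        scores, _ = predict(model, X)
        # oracle: least squares on [X | 0.5 ones column]
        A_lin = np.hstack([X, 0.5 * np.ones((6, 1))])
        fitted = A_lin @ _lstsq_oracle(A_lin, Y.values)
        assert np.allclose(scores, fitted, atol=1e-8)

    def test_matches_least_squares_oracle(self, rng):
        X, Y, layer = _random_instance(rng, 6, 2, 3, seed=1)
        model = train_rvfl(X, Y, layer)
        A = np.hstack([X, hidden_output(layer, X)])
        assert np.allclose(model.p, _lstsq_oracle(A, Y.values), atol=1e-8)

    def test_interpolates_when_columns_exceed_rows(self, rng):
        X, Y, layer = _random_instance(rng, 5, 2, 4, seed=3)
        A = np.hstack([X, hidden_output(layer, X)])
        assert np.linalg.matrix_rank(A) == 5
        model = train_rvfl(X, Y, layer)
        scores, _ = predict(model, X)
        assert np.max(np.abs(scores - Y.values)) < 1e-6

    def test_direct_link_rows_come_first(self, rng):
        X, Y, layer = _random_instance(rng, 6, 2, 3, seed=1)
        model = train_rvfl(X, Y, layer)
        assert model.p.shape == (2 + 3, 2)


class TestPredict:
    def test_argmax_and_tie_break(self):
        layer = make_hidden_layer(2, 3, seed=0)
        model = SnnModel(hidden=layer, P=np.zeros((3, 2)), q=np.array([0.9, 0.1]))
        scores, labels = predict(model, np.zeros((1, 2)))
        assert labels[0] == 0
        tie = SnnModel(hidden=layer, P=np.zeros((3, 2)), q=np.array([0.5, 0.5]))
        _, labels = predict(tie, np.zeros((1, 2)))
        assert labels[0] == 0  # ties break toward the lowest class index

    def test_interpolating_model_recovers_training_labels(self, rng):
        X, Y, layer = _random_instance(rng, 4, 2, 8, seed=2)
        model = train_elm(X, Y, layer)
        _, labels = predict(model, X)
        assert np.array_equal(labels, np.argmax(Y.values, axis=1))

    def test_dimension_mismatch_rejected(self, rng):
        model = train_elm(rng.normal(size=(4, 3)),
                          TargetMatrix.from_labels([0, 1, 0, 1]),
                          make_hidden_layer(3, 5, seed=0))
        with pytest.raises(ValueError):
            predict(model, rng.normal(size=(2, 2)))


class TestProperties:
    @pytest.mark.parametrize("trial", range(10))
    def test_residual_matches_oracle_on_random_instances(self, trial):
        # exact residual equality is only numerically meaningful away from
        # near-rank-deficiency; beyond cond 1e7 assert optimality one-sidedly
        rng = np.random.default_rng(1000 + trial)
        N = int(rng.integers(2, 21))
        n = int(rng.integers(1, 6))
        V = int(rng.integers(1, 11))
        X, Y, layer = _random_instance(rng, N, n, V, seed=trial)
        for trainer, design in (
            (train_snn, lambda A, N=N: np.hstack([A, np.ones((N, 1))])),
            (train_elm, lambda A: A),
            (train_rvfl, lambda A, X=X: np.hstack([X, A])),
        ):
            model = trainer(X, Y, layer)
            scores, _ = predict(model, X)
            A = design(hidden_output(layer, X))
            res = np.linalg.norm(scores - Y.values)
            oracle_res = np.linalg.norm(A @ _lstsq_oracle(A, Y.values) - Y.values)
            cond = np.linalg.cond(A)
            # never beats the true minimum (up to conditioning-scaled noise)
            slack = 1e-8 + 1e-14 * cond * np.linalg.norm(Y.values)
            assert res >= oracle_res - slack
            if cond <= 1e7:
                assert res == pytest.approx(oracle_res, abs=1e-8)

    def test_duplicate_sample_keeps_interpolating_fit(self, rng):
        # in the full-row-rank regime the fit is exact with or without duplicates
        X, Y, layer = _random_instance(rng, 4, 2, 10, seed=6)
        Xd = np.vstack([X, X[0]])
        Yd = TargetMatrix(np.vstack([Y.values, Y.values[0]]))
        assert np.linalg.matrix_rank(hidden_output(layer, Xd)) == 4
        for trainer in (train_snn, train_elm):
            scores, _ = predict(trainer(Xd, Yd, layer), X)
            assert np.max(np.abs(scores - Y.values)) < 1e-6

    def test_training_is_deterministic(self, rng):
        X, Y, _ = _random_instance(rng, 8, 3, 5, seed=0)
        m1 = train_snn(X, Y, make_hidden_layer(3, 5, seed=11))
        m2 = train_snn(X, Y, make_hidden_layer(3, 5, seed=11))
        assert np.array_equal(m1.P, m2.P) and np.array_equal(m1.q, m2.q)

    def test_ridge_variant_close_to_pinv_for_tiny_lambda(self, rng):
        X, Y, layer = _random_instance(rng, 12, 3, 5, seed=2)
        m0 = train_elm(X, Y, layer)
        m1 = train_elm(X, Y, layer, ridge=1e-10)
        assert np.allclose(m0.P, m1.P, atol=1e-5)


class TestSerialization:
    @pytest.mark.parametrize("trainer,cls", [
        (train_snn, SnnModel), (train_elm, ElmModel), (train_rvfl, RvflModel),
    ])
    def test_roundtrip(self, tmp_path, rng, trainer, cls):
        X, Y, layer = _random_instance(rng, 6, 2, 3, seed=1)
        model = trainer(X, Y, layer)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert isinstance(loaded, cls)
        s1, l1 = predict(model, X)
        s2, l2 = predict(loaded, X)
        assert np.array_equal(s1, s2) and np.array_equal(l1, l2)


class TestMatrixTypes:
    def test_feature_matrix_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            FeatureMatrix(np.zeros((0, 3)))
        with pytest.raises(ValueError):
            FeatureMatrix(np.zeros(4))
        with pytest.raises(ValueError):
            FeatureMatrix(np.array([[1.0, np.inf]]))

    def test_one_hot_encoding(self):
        Y = TargetMatrix.from_labels([1, 0, 1], m=2)
        assert np.array_equal(Y.values, [[0, 1], [1, 0], [0, 1]])
        assert np.all(Y.values.sum(axis=1) == 1)
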