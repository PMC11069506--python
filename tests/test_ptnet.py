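"""Network construction, forward/backward correctness, ADAM, k-fold CV."""

import numpy as np
import pytest

from ptoct import (
    NetworkConfig,
    NetworkParams,
    TrainConfig,
    forward,
    forward_batch,
    init_params,
    predict_image,
    reconstruct_image,
    train,
    train_kfold,
)
from ptoct.ptnet import _AdamState, _adam_update, loss_and_gradients


def toy_regression(n=400, d=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    w = rng.normal(size=d)
    y = np.maximum(X @ w, 0) + 0.05 * rng.normal(size=n)
    return X, y


class TestInit:
    def test_seed_determinism(self):
        cfg = NetworkConfig()
        a = init_params(cfg, 3)
        b = init_params(cfg, 3)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_default_architecture_shapes(self):
        p = init_params(NetworkConfig(), 0)
        assert [w.shape for w in p.weights] == [(10, 88), (5, 10), (1, 5)]
        assert all(np.all(b == 0) for b in p.biases)
        assert all(np.max(np.abs(w)) <= 0.05 for w in p.weights)

    def test_zero_init_range_gives_zero_network(self):
        p = init_params(NetworkConfig(init_range=0.0), 0)
        assert forward(p, np.ones(88)) == 0.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(layer_sizes=(88, 1))  # no hidden layer
        with pytest.raises(ValueError):
            NetworkConfig(layer_sizes=(88, 10, 2))  # output not scalar


class TestForward:
    def test_hand_computed_toy_network(self):
        """[2,2,1] net: relu([x1-x2, x2]) then 2h1 + 3h2 + 1."""
        p = NetworkParams(
            weights=[np.array([[1.0, -1.0], [0.0, 1.0]]), np.array([[2.0, 3.0]])],
            biases=[np.zeros(2), np.array([1.0])],
        )
        assert forward(p, np.array([1.0, 1.0])) == pytest.approx(4.0)

    def test_all_negative_preactivations_yield_output_bias(self):
        p = NetworkParams(
            weights=[np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[2.0, 3.0]])],
            biases=[np.zeros(2), np.array([-0.5])],
        )
        assert forward(p, np.array([-1.0, -2.0])) == pytest.approx(-0.5)

    def test_shape_mismatch_raises(self):
        p = init_params(NetworkConfig(), 0)
        with pytest.raises(ValueError):
            forward(p, np.ones(87))

    def test_agrees_with_sklearn_reference(self):
        """Independent cross-check: the same weights loaded into sklearn's
        MLPRegressor produce identical predictions to 1e-6."""
        sklearn = pytest.importorskip("sklearn.neural_network")
        rng = np.random.default_rng(7)
        p = init_params(NetworkConfig(layer_sizes=(12, 10, 5, 1), init_range=0.5), 5)
        X = rng.normal(size=(20, 12))
        ref = sklearn.MLPRegressor(
            hidden_layer_sizes=(10, 5), activation="relu", max_iter=1
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref.fit(X, rng.normal(size=20))
        ref.coefs_ = [w.T.copy() for w in p.weights]
        ref.intercepts_ = [b.copy() for b in p.biases]
        assert np.allclose(ref.predict(X), forward_batch(p, X), atol=1e-6)


class TestGradients:
    def test_backprop_matches_central_differences(self):
        """Analytic gradients agree with finite differences to < 1e-5."""
        rng = np.random.default_rng(0)
        p = init_params(NetworkConfig(layer_sizes=(6, 4, 3, 1), init_range=0.5), 3)
        X = rng.normal(size=(5, 6))
        y = rng.normal(size=5)
        _, gw, gb = loss_and_gradients(p, X, y)
        eps, worst = 1e-6, 0.0
        for layer in range(len(p.weights)):
            for arr, g in ((p.weights[layer], gw[layer]), (p.biases[layer], gb[layer])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    i = it.multi_index
                    orig = arr[i]
                    arr[i] = orig + eps
                    lp, _, _ = loss_and_gradients(p, X, y)
                    arr[i] = orig - eps
                    lm, _, _ = loss_and_gradients(p, X, y)
                    arr[i] = orig
                    fd = (lp - lm) / (2 * eps)
                    if abs(fd) > 1e-8:
                        worst = max(worst, abs(fd - g[i]) / max(abs(fd), abs(g[i])))
        assert worst < 1e-5

    def test_adam_zero_gradient_is_identity(self):
        p = init_params(NetworkConfig(layer_sizes=(4, 3, 1), init_range=0.3), 1)
        before = p.copy()
        state = _AdamState(p)
        zeros_w = [np.zeros_like(w) for w in p.weights]
        zeros_b = [np.zeros_like(b) for b in p.biases]
        _adam_update(p, zeros_w, zeros_b, state, TrainConfig())
        for w0, w1 in zip(before.weights, p.weights):
            assert np.array_equal(w0, w1)


class TestTraining:
    def test_loss_decreases_in_seeded_runs(self):
        """Final training loss below the initial loss in >= 95% of runs."""
        X, y = toy_regression()
        cfg = NetworkConfig(layer_sizes=(8, 10, 5, 1))
        wins = 0
        for seed in range(10):
            tc = TrainConfig(epochs=15, batch_size=64, pool_size=400, seed=seed)
            p0 = init_params(cfg, np.random.default_rng(seed).integers(2**31))
            initial = np.mean((forward_batch(p0, X) - y) ** 2)
            params, history = train(X, y, cfg, tc, seed=seed)
            wins += history[-1] < initial
        assert wins >= 10 * 0.95

    def test_kfold_bookkeeping_and_determinism(self):
        X, y = toy_regression(n=1000)
        cfg = NetworkConfig(layer_sizes=(8, 6, 3, 1))
        tc = TrainConfig(epochs=3, batch_size=128, pool_size=1000, k_folds=10, seed=9)
        folds, selected = train_kfold((X, y), cfg, tc)
        assert len(folds) == 10
        assert all(f.val_indices.size == 100 for f in folds)
        # every pool index appears in exactly one validation fold
        all_val = np.concatenate([f.val_indices for f in folds])
        assert np.unique(all_val).size == 1000
        folds2, selected2 = train_kfold((X, y), cfg, tc)
        assert selected2.fold_index == selected.fold_index
        for w1, w2 in zip(selected.params.weights, selected2.params.weights):
            assert np.array_equal(w1, w2)

    def test_kfold_pool_shrinks_with_warning(self):
        X, y = toy_regression(n=200)
        cfg = NetworkConfig(layer_sizes=(8, 4, 1))
        tc = TrainConfig(epochs=2, batch_size=64, pool_size=5000, k_folds=4, seed=0)
        with pytest.warns(UserWarning):
            folds, _ = train_kfold((X, y), cfg, tc)
        assert sum(f.val_indices.size for f in folds) == 200

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            train_kfold(
                (np.empty((0, 8)), np.empty(0)),
                NetworkConfig(layer_sizes=(8, 4, 1)),
                TrainConfig(),
            )


class TestPredictImage:
    def test_zero_network_gives_zero_image(self, noisy_cube):
        cube, _ = noisy_cube
        p = init_params(NetworkConfig(init_range=0.0), 0)
        img = predict_image(p, cube)
        assert img.kind == "NET"
        assert np.allclose(img.amplitude_rad[img.mask], 0.0)

    def test_mask_and_shape_match_st_reconstruction(self, noisy_cube):
        cube, _ = noisy_cube
        p = init_params(NetworkConfig(), 0)
        net_img = predict_image(p, cube)
        st_img = reconstruct_image(cube, n_use=88)
        assert net_img.shape == st_img.shape
        assert np.array_equal(net_img.mask, st_img.mask)

    def test_negative_outputs_clipped(self, noisy_cube):
        cube, _ = noisy_cube
        p = init_params(NetworkConfig(layer_sizes=(88, 4, 1), init_range=0.0), 0)
        p.biases[-1][0] = -1.0  # force negative raw outputs
        img = predict_image(p, cube)
        assert np.all(img.amplitude_rad[img.mask] == 0.0)

    def test_input_size_mismatch_raises(self, noisy_cube):
        cube, _ = noisy_cube
        p = init_params(NetworkConfig(layer_sizes=(44, 4, 1)), 0)
        with pytest.raises(ValueError):
            predict_image(p, cube, n_short=88)
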