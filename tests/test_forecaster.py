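"""TCN-GRU forecaster: convolution arithmetic, gate equations, gradients,
causality, and training behaviour."""

import numpy as np
import pytest

from barncast.forecaster import (
    Architecture,
    GRUWeights,
    TCNGRURegressor,
    TrainConfig,
    build_model,
    causal_dilated_conv,
    gru_step,
    load_model,
    save_model,
    train_model,
)
from barncast.synthetic_data import learnable_toy

SMALL_ARCH = Architecture(f1=4, f2=5, n1=3, n2=4, lookback=7, n_features=3)


class TestCausalDilatedConv:
    def test_identity_kernel(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        for d in (1, 2, 3):
            np.testing.assert_allclose(causal_dilated_conv(x, np.array([1.0]), d), x)

    def test_two_tap_dilation_one(self):
        out = causal_dilated_conv(np.array([1.0, 2, 3, 4]), np.array([1.0, 1.0]), 1)
        np.testing.assert_allclose(out, [1, 3, 5, 7])

    def test_two_tap_dilation_two(self):
        out = causal_dilated_conv(np.array([1.0, 2, 3, 4]), np.array([1.0, 1.0]), 2)
        np.testing.assert_allclose(out, [1, 2, 4, 6])

    def test_multichannel_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((9, 2))
        w = rng.standard_normal((3, 2, 4))
        d = 2
        out = causal_dilated_conv(x, w, d)
        # brute force: y[t] = sum_j x[t - j*d] @ w[j] (zero outside)
        expected = np.zeros((9, 4))
        for t in range(9):
            for j in range(3):
                if t - j * d >= 0:
                    expected[t] += x[t - j * d] @ w[j]
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestGRUStep:
    def test_zero_weights_halve_hidden_state(self):
        n = 4
        z = np.zeros((n, n))
        w = GRUWeights(w_z=z, u_z=z, w_r=z, u_r=z, w_h=z, u_h=z)
        h = np.array([1.0, -2.0, 0.5, 3.0])
        out = gru_step(np.zeros(n), h, w)
        np.testing.assert_allclose(out, 0.5 * h)

    def test_zero_everything_stays_zero(self):
        n = 3
        z = np.zeros((n, n))
        w = GRUWeights(w_z=z, u_z=z, w_r=z, u_r=z, w_h=z, u_h=z)
        out = gru_step(np.zeros(n), np.zeros(n), w)
        np.testing.assert_allclose(out, np.zeros(n))

    def test_scalar_case_hand_evaluation(self):
        # W_z=U_z=W_r=U_r=0, W=1, U=0, x=0: z=0.5, h~=tanh(0)=0 -> h = 0.5*h_prev
        one = np.ones((1, 1))
        zero = np.zeros((1, 1))
        w = GRUWeights(w_z=zero, u_z=zero, w_r=zero, u_r=zero, w_h=one, u_h=zero)
        out = gru_step(np.array([0.0]), np.array([0.8]), w)
        np.testing.assert_allclose(out, [0.4])

    def test_matches_elementwise_bruteforce_on_random_shapes(self):
        rng = np.random.default_rng(17)

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        for _ in range(100):
            c, n = rng.integers(1, 6, size=2)
            W = {k: rng.standard_normal((c, n)) for k in ("wz", "wr", "wh")}
            U = {k: rng.standard_normal((n, n)) for k in ("uz", "ur", "uh")}
            x = rng.standard_normal(c)
            h = rng.standard_normal(n)
            weights = GRUWeights(w_z=W["wz"], u_z=U["uz"], w_r=W["wr"],
                                 u_r=U["ur"], w_h=W["wh"], u_h=U["uh"])
            out = gru_step(x, h, weights)
            # independent scalar-loop evaluation of the gate equations
            expected = np.empty(n)
            for j in range(n):
                zj = sig(x @ W["wz"][:, j] + h @ U["uz"][:, j])
                rj = sig(x @ W["wr"][:, j] + h @ U["ur"][:, j])
                rh = np.array([sig(x @ W["wr"][:, m] + h @ U["ur"][:, m]) * h[m]
                               for m in range(n)])
                hj = np.tanh(x @ W["wh"][:, j] + rh @ U["uh"][:, j])
                expected[j] = (1 - zj) * h[j] + zj * hj
            np.testing.assert_allclose(out, expected, atol=1e-6)


class TestModel:
    def test_output_shape(self):
        model = build_model(SMALL_ARCH, seed=0)
        x = np.zeros((6, 7, 3))
        assert model.forward(x).shape == (6,)

    def test_seeded_init_reproducible(self):
        a = build_model(SMALL_ARCH, seed=9)
        b = build_model(SMALL_ARCH, seed=9)
        for key in a.params:
            np.testing.assert_array_equal(a.params[key], b.params[key])

    def test_feature_count_mismatch_rejected(self):
        model = build_model(SMALL_ARCH, seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 7, 5)))

    def test_tcn_causality_probe(self):
        """Perturbing the input after step t leaves TCN activations at t unchanged."""
        model = build_model(SMALL_ARCH, seed=1)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 7, 3))
        cache = {}
        model.forward(x, cache)
        d1, d2 = SMALL_ARCH.dilations
        base1 = np.maximum(cache["block1_z"], 0) + cache["block1_x"] @ model.params["proj1_w"]
        base2 = np.maximum(cache["block2_z"], 0) + cache["block2_x"] @ model.params["proj2_w"]
        for t_perturbed in range(1, 7):
            x2 = x.copy()
            x2[0, t_perturbed:] += 100.0
            cache2 = {}
            model.forward(x2, cache2)
            out1 = np.maximum(cache2["block1_z"], 0) + cache2["block1_x"] @ model.params["proj1_w"]
            out2 = np.maximum(cache2["block2_z"], 0) + cache2["block2_x"] @ model.params["proj2_w"]
            np.testing.assert_array_equal(out1[0, :t_perturbed], base1[0, :t_perturbed])
            np.testing.assert_array_equal(out2[0, :t_perturbed], base2[0, :t_perturbed])

    def test_gradients_match_finite_differences(self):
        model = build_model(SMALL_ARCH, seed=3)
        rng = np.random.default_rng(4)
        x = rng.standard_normal((3, 7, 3))
        y = rng.standard_normal(3)
        cache = {}
        pred = model.forward(x, cache)
        grads = model.backward(cache, 2.0 * (pred - y) / len(y))

        def loss():
            return float(np.mean((model.forward(x) - y) ** 2))

        eps = 1e-6
        for key in model.params:
            flat = model.params[key].ravel()
            gflat = grads[key].ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                # absolute floor guards near-zero gradients against
                # finite-difference round-off
                assert abs(fd - gflat[i]) < 1e-6 + 1e-4 * (abs(fd) + abs(gflat[i])), key


class TestTrainingAndPrediction:
    def test_constant_target_val_loss_shrinks(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((60, 7, 3))
        y = np.zeros(60)
        model = build_model(SMALL_ARCH, seed=0)
        h = model.fit(x[:48], y[:48], x[48:], y[48:], TrainConfig(epochs=5, seed=0))
        assert h["val_loss"][-1] <= h["val_loss"][0]
        assert len(h["train_loss"]) == 5

    def test_linear_task_converges(self):
        toy = learnable_toy(500, lookback=8, seed=3)
        arch = Architecture(f1=8, f2=8, n1=8, n2=8, lookback=8)
        model = build_model(arch, seed=0)
        h = model.fit(toy.inputs[:400], toy.targets[:400], toy.inputs[400:],
                      toy.targets[400:], TrainConfig(epochs=50, seed=0, learning_rate=0.005))
        assert h["val_loss"][-1] < 0.01
        # smoothed training curve decreases over the early epochs
        smoothed = np.convolve(h["train_loss"], np.ones(5) / 5, mode="valid")
        assert smoothed[5] < smoothed[0]

    def test_predictions_deterministic_and_batch_invariant(self):
        model = build_model(SMALL_ARCH, seed=0)
        rng = np.random.default_rng(8)
        x = rng.standard_normal((40, 7, 3))
        a = model.predict(x)
        b = model.predict(x)
        np.testing.assert_array_equal(a, b)
        singles = np.concatenate([model.predict(x[i : i + 1]) for i in range(len(x))])
        np.testing.assert_allclose(singles, a, atol=1e-6)

    def test_permuting_windows_permutes_predictions(self):
        model = build_model(SMALL_ARCH, seed=0)
        rng = np.random.default_rng(9)
        x = rng.standard_normal((20, 7, 3))
        perm = rng.permutation(20)
        np.testing.assert_allclose(model.predict(x[perm]), model.predict(x)[perm], atol=1e-9)

    def test_non_finite_loss_aborts_with_diagnostic(self):
        x = np.full((8, 7, 3), 1.0)
        y = np.full(8, np.nan)
        model = build_model(SMALL_ARCH, seed=0)
        with pytest.raises(FloatingPointError):
            model.fit(x, y, config=TrainConfig(epochs=1, seed=0))

    def test_save_load_round_trip(self, tmp_path):
        model = build_model(SMALL_ARCH, seed=5)
        toy = learnable_toy(40, lookback=7, n_features=3, seed=1)
        train_model(model, toy, config=TrainConfig(epochs=2, seed=0))
        wpath, apath = tmp_path / "w.npz", tmp_path / "arch.txt"
        save_model(model, wpath, apath)
        loaded = load_model(wpath, apath)
        x = np.random.default_rng(2).standard_normal((5, 7, 3))
        np.testing.assert_array_equal(loaded.predict(x), model.predict(x))
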