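"""Gated cells: step maps, BPTT gradients, training, recursive forecasting."""

import numpy as np
import pytest

from apforecast.gated_rnn import (GatedModel, GatedSpec, TrainConfig,
                                  _loss_and_grads, forecast_recursive,
                                  gru_step, init_params, lstm_step,
                                  n_trainable, train_seq2seq)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _zero_layer(spec):
    H, G = spec.n_hidden, spec.n_gates
    n_in = spec.n_inputs
    return {"W": np.zeros((G * H, n_in)), "U": np.zeros((G * H, H)),
            "b": np.zeros(G * H)}


class TestLstmStep:
    def test_all_zero_weights(self):
        spec = GatedSpec("lstm", n_hidden=4, n_inputs=2)
        lp = _zero_layer(spec)
        h, c = lstm_step(lp, np.ones(2), np.zeros(4), np.zeros(4))
        np.testing.assert_array_equal(c, np.zeros(4))
        np.testing.assert_array_equal(h, np.zeros(4))

    def test_cell_state_halved_by_neutral_gates(self):
        # zero weights make every gate 1/2: c' = c/2, h' = tanh(c/2)/2
        spec = GatedSpec("lstm", n_hidden=3, n_inputs=1)
        lp = _zero_layer(spec)
        c_prev = np.array([0.2, -0.6, 1.0])
        h, c = lstm_step(lp, np.zeros(1), np.zeros(3), c_prev)
        np.testing.assert_allclose(c, 0.5 * c_prev, atol=1e-14)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev), atol=1e-14)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(0)
        H, n_in = 5, 3
        spec = GatedSpec("lstm", n_hidden=H, n_inputs=n_in)
        lp = {"W": rng.standard_normal((4 * H, n_in)),
              "U": rng.standard_normal((4 * H, H)),
              "b": rng.standard_normal(4 * H)}
        x = rng.standard_normal(n_in)
        h_prev = rng.standard_normal(H)
        c_prev = rng.standard_normal(H)
        a = lp["W"] @ x + lp["U"] @ h_prev + lp["b"]
        i = _sigmoid(a[0:H])
        f = _sigmoid(a[H:2 * H])
        o = _sigmoid(a[2 * H:3 * H])
        g = np.tanh(a[3 * H:4 * H])
        c_exp = f * c_prev + i * g
        h_exp = np.tanh(c_exp) * o
        h, c = lstm_step(lp, x, h_prev, c_prev)
        np.testing.assert_allclose(h, h_exp, atol=1e-13)
        np.testing.assert_allclose(c, c_exp, atol=1e-13)

    def test_output_bounded_by_tanh(self):
        rng = np.random.default_rng(1)
        H = 8
        lp = {"W": 5 * rng.standard_normal((4 * H, 2)),
              "U": 5 * rng.standard_normal((4 * H, H)),
              "b": 5 * rng.standard_normal(4 * H)}
        h, _ = lstm_step(lp, rng.standard_normal(2),
                         rng.standard_normal(H), rng.standard_normal(H))
        assert np.all(np.abs(h) <= 1.0)


class TestGruStep:
    def test_all_zero_weights_halves_state(self):
        spec = GatedSpec("gru", n_hidden=4, n_inputs=2)
        lp = _zero_layer(spec)
        h_prev = np.array([0.4, -0.2, 0.8, 0.0])
        h = gru_step(lp, np.zeros(2), h_prev)
        np.testing.assert_allclose(h, 0.5 * h_prev, atol=1e-14)

    def test_closed_update_gate_preserves_state(self):
        spec = GatedSpec("gru", n_hidden=3, n_inputs=1)
        lp = _zero_layer(spec)
        lp["b"][0:3] = -50.0  # update gate pinned near zero
        h_prev = np.array([0.3, -0.7, 0.1])
        h = gru_step(lp, np.ones(1), h_prev)
        np.testing.assert_allclose(h, h_prev, atol=1e-12)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(2)
        H, n_in = 4, 2
        lp = {"W": rng.standard_normal((3 * H, n_in)),
              "U": rng.standard_normal((3 * H, H)),
              "b": rng.standard_normal(3 * H)}
        x = rng.standard_normal(n_in)
        h_prev = rng.standard_normal(H)
        z = _sigmoid(lp["W"][0:H] @ x + lp["U"][0:H] @ h_prev + lp["b"][0:H])
        r = _sigmoid(lp["W"][H:2 * H] @ x + lp["U"][H:2 * H] @ h_prev
                     + lp["b"][H:2 * H])
        g = np.tanh(lp["W"][2 * H:] @ x + lp["U"][2 * H:] @ (r * h_prev)
                    + lp["b"][2 * H:])
        expected = (1 - z) * h_prev + z * g
        np.testing.assert_allclose(gru_step(lp, x, h_prev), expected,
                                   atol=1e-13)


class TestGradients:
    @pytest.mark.parametrize("kind,layers", [("lstm", 1), ("gru", 1),
                                             ("lstm", 2), ("gru", 2)])
    def test_bptt_matches_finite_differences(self, kind, layers):
        rng = np.random.default_rng(3)
        spec = GatedSpec(kind, n_hidden=3, n_layers=layers, n_inputs=2)
        params = init_params(spec, seed=1)
        X = rng.standard_normal((2, 10, 2))
        Y = rng.standard_normal((2, 10))
        _, grads = _loss_and_grads(params, X, Y)
        eps = 1e-6

        def check(arr, garr):
            flat = arr.ravel()
            gflat = garr.ravel()
            idx = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for k in idx:
                old = flat[k]
                flat[k] = old + eps
                lp, _ = _loss_and_grads(params, X, Y)
                flat[k] = old - eps
                lm, _ = _loss_and_grads(params, X, Y)
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(gflat[k]), 1e-8)
                assert abs(num - gflat[k]) / denom < 1e-4

        for li in range(layers):
            for key in ("W", "U", "b"):
                check(params["layers"][li][key], grads["layers"][li][key])
        check(params["Wy"], grads["Wy"])
        check(params["by"], grads["by"])


class TestTraining:
    def test_constant_series_learned_to_optimizer_noise_floor(self):
        spec = GatedSpec("lstm", n_hidden=4, n_inputs=1)
        T = 60
        X = np.full((T, 1), 0.4)
        y = np.full(T, 0.4)
        cfg = TrainConfig(learning_rate=2e-2, max_epochs=300, window=0,
                          seed=0)
        model = train_seq2seq(spec, X, y, cfg)
        assert model.loss_history[-1] < 1e-4

    def test_gru_has_fewer_parameters_than_lstm(self):
        lstm = init_params(GatedSpec("lstm", n_hidden=32, n_inputs=2), 0)
        gru = init_params(GatedSpec("gru", n_hidden=32, n_inputs=2), 0)
        assert n_trainable(gru) < n_trainable(lstm)

    def test_loss_trends_downward(self):
        rng = np.random.default_rng(4)
        t = np.arange(400)
        v = 0.5 + 0.4 * np.sin(2 * np.pi * t / 25.0)
        X = v[:-1, None]
        y = v[1:]
        spec = GatedSpec("gru", n_hidden=8, n_inputs=1)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=20, window=64,
                          stride=16, seed=1)
        model = train_seq2seq(spec, X, y, cfg)
        assert model.loss_history[-1] < 0.25 * model.loss_history[0]

    def test_shape_validation(self):
        spec = GatedSpec("lstm", n_hidden=2, n_inputs=2)
        with pytest.raises(ValueError):
            train_seq2seq(spec, np.zeros((10, 1)), np.zeros(10),
                          TrainConfig())


class TestForecastRecursive:
    def _constant_model(self):
        spec = GatedSpec("lstm", n_hidden=4, n_inputs=1)
        X = np.full((60, 1), 0.4)
        cfg = TrainConfig(learning_rate=2e-2, max_epochs=300, window=0,
                          seed=0)
        return train_seq2seq(spec, X, np.full(60, 0.4), cfg)

    def test_zero_steps_empty(self):
        model = self._constant_model()
        assert len(forecast_recursive(model, np.full((10, 1), 0.4), None, 0,
                                      0.4)) == 0

    def test_learned_fixed_point_is_stable(self):
        model = self._constant_model()
        preds = forecast_recursive(model, np.full((30, 1), 0.4), None, 20,
                                   0.4)
        np.testing.assert_allclose(preds, 0.4, atol=1e-3)

    def test_exogenous_channel_required(self):
        spec = GatedSpec("gru", n_hidden=3, n_inputs=2)
        model = GatedModel(spec, init_params(spec, 0), TrainConfig())
        with pytest.raises(ValueError):
            forecast_recursive(model, np.zeros((5, 2)), None, 3, 0.0)
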