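"""Forward-pass correctness of the LSTM/GRU cells against an independent
scalar-loop reference, plus structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallrnn import ModelParams, init_model, load_model, predict, run_sequence, save_model
from fallrnn.rnncore import (
    BatchNormParams,
    batchnorm_apply,
    gru_step,
    lstm_step,
    predict_batch,
    softmax,
)
from fallrnn.synthdata import CLASSES

from reference_rnn import ref_batchnorm, ref_gru_sequence, ref_lstm_sequence, ref_model_forward


def _random_model(arch, rng, n_units=6, peepholes=False):
    m = init_model(arch, n_units=n_units, rng=rng, peepholes_enabled=peepholes)
    for _, arr in m.named_params():
        arr += rng.normal(0, 0.3, arr.shape)
    if peepholes:
        for layer in m.recurrent_layers:
            for n in ("wci", "wcf", "wco"):
                setattr(layer, n, rng.normal(0, 0.3, n_units))
    m.batchnorm.running_mean = rng.normal(0, 0.3, 3)
    m.batchnorm.running_var = rng.uniform(0.5, 2.0, 3)
    return m


class TestBatchNorm:
    def test_identity_parameters(self, rng):
        p = BatchNormParams(np.ones(3), np.zeros(3), np.zeros(3), np.ones(3), epsilon=1e-12)
        x = rng.normal(size=3)
        assert np.allclose(batchnorm_apply(p, x), x, atol=1e-9)

    def test_input_at_mean_returns_beta(self, rng):
        beta = rng.normal(size=3)
        mean = rng.normal(size=3)
        p = BatchNormParams(rng.uniform(0.5, 2, 3), beta, mean, rng.uniform(0.5, 2, 3))
        assert np.allclose(batchnorm_apply(p, mean), beta)

    def test_matches_scalar_reference(self, rng):
        p = BatchNormParams(
            rng.uniform(0.5, 2, 3), rng.normal(size=3), rng.normal(size=3),
            rng.uniform(0.5, 2, 3),
        )
        x = rng.normal(size=3)
        ref = ref_batchnorm(
            p.gamma.tolist(), p.beta.tolist(), p.running_mean.tolist(),
            p.running_var.tolist(), p.epsilon, x.tolist(),
        )
        assert np.allclose(batchnorm_apply(p, x), ref, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        p = BatchNormParams(np.ones(3), np.zeros(3), np.zeros(3), np.ones(3))
        with pytest.raises(ValueError, match="channels"):
            batchnorm_apply(p, np.zeros(4))


class TestLSTMStep:
    def test_zero_weights_and_states(self):
        m = init_model("1xLSTM", n_units=4, rng=0)
        layer = m.recurrent_layers[0]
        for name in layer.param_names():
            setattr(layer, name, np.zeros_like(getattr(layer, name)))
        h, c = lstm_step(layer, np.zeros(3), np.zeros(4), np.zeros(4))
        assert np.allclose(h, 0) and np.allclose(c, 0)

    def test_matches_reference_cell(self, rng):
        layer = _random_model("1xLSTM", rng).recurrent_layers[0]
        X = rng.normal(size=(7, 3))
        ref = ref_lstm_sequence(
            {k: getattr(layer, k).tolist() for k in
             ("Wxi", "Wxf", "Wxc", "Wxo", "Whi", "Whf", "Whc", "Who",
              "wci", "wcf", "wco", "bi", "bf", "bc", "bo")},
            X.tolist(), peepholes=False,
        )
        h = np.zeros(layer.n_units)
        c = np.zeros(layer.n_units)
        for t in range(len(X)):
            h, c = lstm_step(layer, X[t], h, c)
        assert np.linalg.norm(h - ref[-1]) / np.linalg.norm(ref[-1]) < 1e-10

    def test_zero_peepholes_equal_disabled(self, rng):
        layer = _random_model("1xLSTM", rng).recurrent_layers[0]
        x, h0, c0 = rng.normal(size=3), rng.normal(size=6), rng.normal(size=6)
        layer.peepholes_enabled = False
        h_off, c_off = lstm_step(layer, x, h0, c0)
        layer.peepholes_enabled = True
        layer.wci = layer.wcf = layer.wco = np.zeros(6)
        h_on, c_on = lstm_step(layer, x, h0, c0)
        assert np.array_equal(h_off, h_on) and np.array_equal(c_off, c_on)

    def test_peepholes_change_the_output(self, rng):
        layer = _random_model("1xLSTM", rng, peepholes=True).recurrent_layers[0]
        x, h0 = rng.normal(size=3), rng.normal(size=6)
        c0 = rng.normal(size=6)
        h_on, _ = lstm_step(layer, x, h0, c0)
        layer.peepholes_enabled = False
        h_off, _ = lstm_step(layer, x, h0, c0)
        assert not np.allclose(h_on, h_off)

    def test_shape_mismatch_rejected(self, rng):
        layer = _random_model("1xLSTM", rng).recurrent_layers[0]
        with pytest.raises(ValueError, match="shape mismatch"):
            lstm_step(layer, np.zeros(5), np.zeros(6), np.zeros(6))


class TestGRUStep:
    def test_zero_everything(self):
        m = init_model("1xGRU", n_units=4, rng=0)
        layer = m.recurrent_layers[0]
        for name in layer.param_names():
            setattr(layer, name, np.zeros_like(getattr(layer, name)))
        assert np.allclose(gru_step(layer, np.zeros(3), np.zeros(4)), 0)

    def test_closed_update_gate_preserves_state(self, rng):
        layer = _random_model("1xGRU", rng).recurrent_layers[0]
        layer.Wxz = np.zeros_like(layer.Wxz)
        layer.Whz = np.zeros_like(layer.Whz)
        layer.bz = np.full(6, -50.0)  # z ~ 0: update gate closed
        h_prev = rng.normal(size=6)
        h = gru_step(layer, rng.normal(size=3), h_prev)
        assert np.allclose(h, h_prev, atol=1e-15)

    def test_matches_reference_cell(self, rng):
        layer = _random_model("1xGRU", rng).recurrent_layers[0]
        X = rng.normal(size=(7, 3))
        ref = ref_gru_sequence(
            {k: getattr(layer, k).tolist() for k in
             ("Wxz", "Wxr", "Wxc", "Whz", "Whr", "Whc", "bz", "br", "bc")},
            X.tolist(),
        )
        h = np.zeros(layer.n_units)
        for t in range(len(X)):
            h = gru_step(layer, X[t], h)
        assert np.linalg.norm(h - ref[-1]) / np.linalg.norm(ref[-1]) < 1e-10

    def test_hidden_state_bounded_from_zero_init(self, rng):
        layer = _random_model("1xGRU", rng).recurrent_layers[0]
        h = np.zeros(6)
        for t in range(50):
            h = gru_step(layer, rng.normal(size=3), h)
            assert np.all(np.abs(h) <= 1.0)  # convex combination of tanh outputs


class TestRunSequence:
    @pytest.mark.parametrize("arch", ["1xLSTM", "2xLSTM", "1xGRU", "2xGRU"])
    def test_softmax_output_is_a_distribution(self, arch, rng):
        m = _random_model(arch, rng)
        scores = run_sequence(m, rng.normal(size=(16, 3)))
        assert np.all(scores > 0) and np.all(scores < 1)
        assert abs(scores.sum() - 1.0) < 1e-9

    def test_zero_dense_gives_uniform(self, rng):
        m = _random_model("1xGRU", rng)
        m.dense.W = np.zeros_like(m.dense.W)
        m.dense.b = np.zeros_like(m.dense.b)
        scores = run_sequence(m, rng.normal(size=(8, 3)))
        assert np.allclose(scores, 1 / 3)

    @pytest.mark.parametrize("arch", ["1xLSTM", "2xLSTM", "1xGRU", "2xGRU"])
    def test_end_to_end_matches_scalar_reference(self, arch, rng):
        m = _random_model(arch, rng)
        block = rng.normal(size=(12, 3))
        got = run_sequence(m, block)
        ref = np.array(ref_model_forward(m, block.tolist()))
        assert np.linalg.norm(got - ref) / np.linalg.norm(ref) < 1e-10

    def test_precision_does_not_flip_labels(self, rng):
        m = _random_model("1xGRU", rng)
        X64 = rng.normal(size=(20, 10, 3))
        labels64, _ = predict_batch(m, X64)
        labels32, _ = predict_batch(m, X64.astype(np.float32).astype(np.float64))
        assert np.array_equal(labels64, labels32)


class TestPredict:
    def test_argmax_and_tie_break(self, rng):
        m = _random_model("1xGRU", rng)
        m.dense.W = np.zeros_like(m.dense.W)
        m.dense.b = np.zeros_like(m.dense.b)
        label, scores = predict(m, rng.normal(size=(8, 3)))
        assert label == "BKG"  # exact three-way tie resolves to the first class
        m.dense.b = np.array([0.0, 0.0, 1.0])
        label, _ = predict(m, rng.normal(size=(8, 3)))
        assert label == "FALL"

    def test_agreement_with_argmax_oracle(self, rng):
        m = _random_model("2xGRU", rng, n_units=4)
        X = rng.normal(size=(200, 6, 3))
        labels, probs = predict_batch(m, X)
        expected = [CLASSES[int(max(range(3), key=lambda i: p[i]))] for p in probs]
        assert list(labels) == expected


class TestGateRanges:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_lstm_hidden_state_bounded(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_model("1xLSTM", rng, n_units=4)
        h = np.zeros(4)
        c = np.zeros(4)
        for _ in range(30):
            h, c = lstm_step(m.recurrent_layers[0], rng.normal(size=3), h, c)
            assert np.all(np.abs(h) < 1.0)  # |o * tanh(c)| < 1


class TestPersistence:
    @pytest.mark.parametrize("arch", ["1xLSTM", "2xGRU"])
    def test_save_load_round_trip(self, arch, rng, tmp_path):
        m = _random_model(arch, rng)
        path = tmp_path / "model.json"
        save_model(m, path)
        back = load_model(path)
        X = rng.normal(size=(4, 8, 3))
        from fallrnn.rnncore import forward_batch

        assert np.allclose(forward_batch(m, X), forward_batch(back, X), atol=1e-12)

    def test_bad_version_rejected(self, rng, tmp_path):
        import json

        m = _random_model("1xGRU", rng)
        path = tmp_path / "model.json"
        save_model(m, path)
        payload = json.loads(path.read_text())
        payload["format_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="version"):
            load_model(path)


class TestModelValidation:
    def test_mismatched_layer_chain_rejected(self, rng):
        m = _random_model("2xGRU", rng)
        m.recurrent_layers[1].Wxz = np.zeros((6, 5))  # wrong input size
        with pytest.raises(ValueError):
            m.validate()

    def test_wrong_arch_tag_rejected(self, rng):
        with pytest.raises(ValueError, match="arch"):
            init_model("3xGRU")
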