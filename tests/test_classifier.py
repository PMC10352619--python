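"""Bi-LSTM cell mechanics, forward pass and training behavior."""

import math

import numpy as np
import pytest

from hemotex.classifier import (
    BiLSTMModel,
    LSTMCellParams,
    SequenceSample,
    TrainConfig,
    forward,
    load_model,
    lstm_step,
    model_from_dict,
    model_to_dict,
    predict,
    save_model,
    train,
    vector_to_sequence,
)
from hemotex.errors import ParameterError, ValidationError


def random_cell(rng, H, F, scale=1.0):
    parts = {}
    for g in "ifco":
        parts[f"W_{g}h"] = rng.normal(size=(H, H)) * scale
        parts[f"W_{g}a"] = rng.normal(size=(H, F)) * scale
        parts[f"b_{g}"] = rng.normal(size=H) * scale
    return LSTMCellParams(**parts)


def zero_cell(H, F):
    return LSTMCellParams(**{
        f"W_{g}{s}": np.zeros((H, H if s == "h" else F)) for g in "ifco" for s in "ha"
    } | {f"b_{g}": np.zeros(H) for g in "ifco"})


def scalar_step(params, a, h0, c0):
    """Independent scalar-loop evaluation of the gate equations."""
    H, F = params.hidden_size, params.input_size
    sig = lambda x: 1.0 / (1.0 + math.exp(-x))
    h, c = np.zeros(H), np.zeros(H)
    for j in range(H):
        z = {}
        for g in "ifco":
            Wh = getattr(params, f"W_{g}h")
            Wa = getattr(params, f"W_{g}a")
            b = getattr(params, f"b_{g}")
            z[g] = (sum(Wh[j, m] * h0[m] for m in range(H))
                    + sum(Wa[j, m] * a[m] for m in range(F)) + b[j])
        c[j] = sig(z["f"]) * c0[j] + sig(z["i"]) * math.tanh(z["c"])
        h[j] = sig(z["o"]) * math.tanh(c[j])
    return h, c


class TestLSTMStep:
    def test_zero_parameters_give_half_gates_and_zero_state(self, rng):
        params = zero_cell(4, 3)
        h, c = lstm_step(params, rng.normal(size=3), rng.normal(size=4),
                         np.zeros(4))
        assert np.allclose(h, 0.0) and np.allclose(c, 0.0)

    def test_saturated_gates_preserve_cell_state(self, rng):
        params = zero_cell(4, 3)
        params.b_f[:] = 50.0  # forget gate -> 1
        params.b_i[:] = -50.0  # input gate -> 0
        c_prev = rng.normal(size=4)
        _, c = lstm_step(params, rng.normal(size=3), rng.normal(size=4), c_prev)
        np.testing.assert_allclose(c, c_prev, atol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(5):
            params = random_cell(rng, H=3, F=2)
            a, h0, c0 = rng.normal(size=2), rng.normal(size=3), rng.normal(size=3)
            h, c = lstm_step(params, a, h0, c0)
            h2, c2 = scalar_step(params, a, h0, c0)
            np.testing.assert_allclose(h, h2, atol=1e-10)
            np.testing.assert_allclose(c, c2, atol=1e-10)

    def test_hidden_state_bounded_by_tanh(self, rng):
        params = random_cell(rng, H=6, F=4, scale=3.0)
        h, _ = lstm_step(params, rng.normal(size=4), rng.normal(size=6),
                         rng.normal(size=6))
        assert np.all(np.abs(h) < 1.0)

    def test_shape_mismatch_rejected(self, rng):
        params = random_cell(rng, H=3, F=2)
        with pytest.raises(ValidationError):
            lstm_step(params, np.zeros(5), np.zeros(3), np.zeros(3))


class TestVectorToSequence:
    def test_exact_reshape(self):
        s = vector_to_sequence(np.arange(560.0), chunk_T=8)
        assert s.a.shape == (8, 70)

    def test_zero_padding(self):
        s = vector_to_sequence(np.array([1.0, 2, 3, 4, 5]), chunk_T=2)
        assert s.a.shape == (2, 3)
        assert s.a[1, 2] == 0.0
        assert s.a.ravel()[:5].tolist() == [1, 2, 3, 4, 5]


def small_model(rng, H=4, F=3, C=5):
    return BiLSTMModel(
        forward_cell=random_cell(rng, H, F, 0.3),
        backward_cell=random_cell(rng, H, F, 0.3),
        head_W=rng.normal(size=(C, 2 * H)) * 0.3,
        head_b=rng.normal(size=C) * 0.3,
        class_names=tuple(range(C)),
    )


class TestForward:
    def test_probabilities_valid_simplex(self, rng):
        model = small_model(rng)
        p = forward(model, SequenceSample(rng.normal(size=(6, 3)), label=0))
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p > 0) and np.all(p < 1)

    def test_palindrome_with_shared_cells_gives_equal_finals(self, rng):
        cell = random_cell(rng, 4, 3, 0.3)
        model = BiLSTMModel(
            forward_cell=cell, backward_cell=cell,
            head_W=rng.normal(size=(5, 8)), head_b=np.zeros(5),
            class_names=tuple(range(5)),
        )
        half = rng.normal(size=(3, 3))
        a = np.vstack([half, half[::-1]])  # palindromic in time
        from hemotex.classifier import _forward_batch

        _, feats, _, _ = _forward_batch(
            cell.stacked(), cell.stacked(), model.head_W, model.head_b,
            a[None])
        np.testing.assert_allclose(feats[0, :4], feats[0, 4:], atol=1e-12)

    def test_zero_weight_model_uniform_probabilities(self):
        model = BiLSTMModel(
            forward_cell=zero_cell(4, 3), backward_cell=zero_cell(4, 3),
            head_W=np.zeros((5, 8)), head_b=np.zeros(5),
            class_names=tuple(range(5)),
        )
        p = forward(model, SequenceSample(np.zeros((4, 3)), label=0))
        np.testing.assert_allclose(p, 0.2, atol=1e-12)

    def test_feature_width_mismatch_rejected(self, rng):
        model = small_model(rng)
        with pytest.raises(ValidationError):
            forward(model, SequenceSample(rng.normal(size=(4, 7)), label=0))


class TestPredict:
    def test_order_invariant_and_argmax_consistent(self, rng):
        model = small_model(rng)
        samples = [SequenceSample(rng.normal(size=(5, 3)), label=0)
                   for _ in range(6)]
        labels, probs = predict(model, samples)
        labels_rev, _ = predict(model, samples[::-1])
        assert labels == labels_rev[::-1]
        assert labels == [model.class_names[k] for k in probs.argmax(axis=1)]

    def test_zero_weight_model_ties_break_to_first_class(self, rng):
        model = BiLSTMModel(
            forward_cell=zero_cell(4, 3), backward_cell=zero_cell(4, 3),
            head_W=np.zeros((5, 8)), head_b=np.zeros(5),
            class_names=("a", "b", "c", "d", "e"),
        )
        labels, _ = predict(model, [SequenceSample(np.zeros((3, 3)), label="a")])
        assert labels == ["a"]


def separable_sequences(rng, n=20, T=4, F=10, n_classes=4):
    seqs = []
    for i in range(n):
        c = i % n_classes
        a = rng.normal(size=(T, F)) * 0.3
        a[:, c * 2:(c + 1) * 2] += 2.0
        seqs.append(SequenceSample(a, label=c))
    return seqs


class TestTrain:
    def test_overfits_separable_data(self, rng):
        seqs = separable_sequences(rng)
        model, losses = train(seqs, TrainConfig(epochs=40, hidden=16, seed=0))
        labels, _ = predict(model, seqs)
        assert np.mean([p == s.label for p, s in zip(labels, seqs)]) == 1.0
        assert np.isfinite(losses).all()
        assert losses[-1] < losses[0]

    def test_same_seed_identical_loss(self, rng):
        seqs = separable_sequences(rng, n=12)
        cfg = TrainConfig(epochs=5, hidden=8, seed=4)
        _, la = train(seqs, cfg)
        _, lb = train(seqs, cfg)
        assert abs(la[-1] - lb[-1]) < 1e-6

    def test_single_class_rejected(self, rng):
        seqs = [SequenceSample(rng.normal(size=(3, 4)), label=1)
                for _ in range(5)]
        with pytest.raises(ValidationError):
            train(seqs, TrainConfig(epochs=1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            TrainConfig(epochs=0)


def test_model_json_round_trip(tmp_path, rng):
    model = small_model(rng)
    p = tmp_path / "m.json"
    save_model(model, str(p))
    loaded = load_model(str(p))
    s = SequenceSample(rng.normal(size=(5, 3)), label=0)
    np.testing.assert_allclose(forward(model, s), forward(loaded, s), atol=1e-12)
    assert model_to_dict(model_from_dict(model_to_dict(model))) == model_to_dict(model)
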