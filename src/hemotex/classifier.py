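"""Bi-directional LSTM for 5-way hemorrhage-subtype classification.

One LSTM cell update, for input a_t, previous hidden state h_{t-1} and
previous cell state c_{t-1}:

    i_t = sigmoid(W_ih h_{t-1} + W_ia a_t + b_i)      (input gate)
    f_t = sigmoid(W_fh h_{t-1} + W_fa a_t + b_f)      (forget gate)
    c_t = f_t * c_{t-1} + i_t * tanh(W_ch h_{t-1} + W_ca a_t + b_c)
    o_t = sigmoid(W_oh h_{t-1} + W_oa a_t + b_o)      (output gate)
    h_t = o_t * tanh(c_t)

The bidirectional model runs one cell over t = 1..T and an independent
cell over t = T..1; the two final hidden states are concatenated (2H) and
fed to a dense softmax head over the five subtypes.

Training is mini-batch Adam on cross-entropy with global gradient-norm
clipping, implemented directly in NumPy (full backpropagation through
time); runs are deterministic given the config seed under single-threaded
execution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError, ValidationError

_GATES = ("i", "f", "c", "o")  # stacking order in the fused weight matrices


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMCellParams:
    """Per-gate weights: W_gh (H,H) recurrent, W_ga (H,F) input, b_g (H,)."""

    W_ih: np.ndarray
    W_ia: np.ndarray
    b_i: np.ndarray
    W_fh: np.ndarray
    W_fa: np.ndarray
    b_f: np.ndarray
    W_ch: np.ndarray
    W_ca: np.ndarray
    b_c: np.ndarray
    W_oh: np.ndarray
    W_oa: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        H, F = self.W_ia.shape
        for g in _GATES:
            wh = getattr(self, f"W_{g}h")
            wa = getattr(self, f"W_{g}a")
            b = getattr(self, f"b_{g}")
            if wh.shape != (H, H) or wa.shape != (H, F) or b.shape != (H,):
                raise ValidationError(f"inconsistent shapes for gate {g!r}")
            if not (np.isfinite(wh).all() and np.isfinite(wa).all()
                    and np.isfinite(b).all()):
                raise ValidationError(f"non-finite parameters in gate {g!r}")

    @property
    def hidden_size(self) -> int:
        return self.W_ih.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_ia.shape[1]

    # fused (4H, .) views used by the batched training path
    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        Wh = np.concatenate([getattr(self, f"W_{g}h") for g in _GATES])
        Wa = np.concatenate([getattr(self, f"W_{g}a") for g in _GATES])
        b = np.concatenate([getattr(self, f"b_{g}") for g in _GATES])
        return Wh, Wa, b

    @classmethod
    def from_stacked(cls, Wh: np.ndarray, Wa: np.ndarray, b: np.ndarray
                     ) -> "LSTMCellParams":
        H = Wh.shape[1]
        parts = {}
        for k, g in enumerate(_GATES):
            parts[f"W_{g}h"] = Wh[k * H:(k + 1) * H]
            parts[f"W_{g}a"] = Wa[k * H:(k + 1) * H]
            parts[f"b_{g}"] = b[k * H:(k + 1) * H]
        return cls(**parts)


@dataclass(frozen=True)
class SequenceSample:
    """One T x F feature sequence with its subtype label."""

    a: np.ndarray
    label: object
    source_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        if a.ndim != 2 or a.shape[0] < 1:
            raise ValidationError("sequence must be a T x F matrix, T >= 1")
        object.__setattr__(self, "a", a)


@dataclass
class BiLSTMModel:
    forward_cell: LSTMCellParams
    backward_cell: LSTMCellParams
    head_W: np.ndarray  # (n_classes, 2H)
    head_b: np.ndarray  # (n_classes,)
    class_names: tuple

    def __post_init__(self) -> None:
        if self.forward_cell.hidden_size != self.backward_cell.hidden_size:
            raise ValidationError("cells differ in hidden size")
        if self.forward_cell.input_size != self.backward_cell.input_size:
            raise ValidationError("cells differ in input size")
        if self.head_W.shape != (len(self.class_names),
                                 2 * self.forward_cell.hidden_size):
            raise ValidationError("head shape inconsistent with cells/classes")


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.001
    grad_clip: float = 1.0
    batch_size: int = 27
    hidden: int = 64
    seq_mode: str = "slices"  # or "chunked"
    chunk_T: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epochs", "learning_rate", "grad_clip", "batch_size",
                     "hidden", "chunk_T"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


def lstm_step(
    params: LSTMCellParams,
    a_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One cell update; returns (h_t, c_t)."""
    a_t = np.asarray(a_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    H, F = params.hidden_size, params.input_size
    if a_t.shape != (F,) or h_prev.shape != (H,) or c_prev.shape != (H,):
        raise ValidationError(
            f"shape mismatch: a_t {a_t.shape}, h_prev {h_prev.shape}, "
            f"c_prev {c_prev.shape}; expected ({F},), ({H},), ({H},)"
        )
    i = _sigmoid(params.W_ih @ h_prev + params.W_ia @ a_t + params.b_i)
    f = _sigmoid(params.W_fh @ h_prev + params.W_fa @ a_t + params.b_f)
    g = np.tanh(params.W_ch @ h_prev + params.W_ca @ a_t + params.b_c)
    o = _sigmoid(params.W_oh @ h_prev + params.W_oa @ a_t + params.b_o)
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def vector_to_sequence(
    values: np.ndarray, mode: str = "chunked", chunk_T: int = 8,
    label: object = None, source_id: str = "",
) -> SequenceSample:
    """Reshape a flat feature vector into a T x F sequence.

    ``chunked`` zero-pads the vector to a multiple of chunk_T and reshapes
    to (chunk_T, ceil(len/chunk_T)). ``slices`` sequences are built
    upstream by stacking per-slice vectors of a scan.
    """
    if mode != "chunked":
        raise ParameterError("vector_to_sequence only handles 'chunked'; "
                             "'slices' sequences are stacked upstream")
    v = np.asarray(values, dtype=np.float64).ravel()
    F = int(np.ceil(len(v) / chunk_T))
    padded = np.zeros(chunk_T * F)
    padded[: len(v)] = v
    return SequenceSample(padded.reshape(chunk_T, F), label=label,
                          source_id=source_id)


# --- batched internals -----------------------------------------------------

def _init_stacked(rng: np.random.Generator, H: int, F: int):
    s = 1.0 / np.sqrt(H)
    Wh = rng.uniform(-s, s, size=(4 * H, H))
    Wa = rng.uniform(-s, s, size=(4 * H, F))
    b = np.zeros(4 * H)
    b[H:2 * H] = 1.0  # forget-gate bias: remember by default
    return [Wh, Wa, b]


def _run_cell_batch(theta, X: np.ndarray, reverse: bool):
    """Run a stacked cell over X (B,T,F); returns final h and BPTT cache."""
    Wh, Wa, b = theta
    H = Wh.shape[1]
    B, T, _ = X.shape
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    for t in order:
        x = X[:, t, :]
        z = h @ Wh.T + x @ Wa.T + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        cache.append((x, h, c, i, f, g, o, tc))
        h = o * tc
        c = c_new
    return h, cache


def _backward_cell_batch(theta, cache, dh_final: np.ndarray):
    """BPTT through one direction given the gradient at its final h."""
    Wh, Wa, b = theta
    H = Wh.shape[1]
    dWh = np.zeros_like(Wh)
    dWa = np.zeros_like(Wa)
    db = np.zeros_like(b)
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for (x, h_prev, c_prev, i, f, g, o, tc) in reversed(cache):
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g**2),
            do * o * (1.0 - o),
        ], axis=1)
        dWh += dz.T @ h_prev
        dWa += dz.T @ x
        db += dz.sum(axis=0)
        dh = dz @ Wh
        dc = dc * f
    return [dWh, dWa, db]


def _forward_batch(params_f, params_b, head_W, head_b, X):
    hf, cache_f = _run_cell_batch(params_f, X, reverse=False)
    hb, cache_b = _run_cell_batch(params_b, X, reverse=True)
    feats = np.concatenate([hf, hb], axis=1)
    logits = feats @ head_W.T + head_b
    logits -= logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return probs, feats, cache_f, cache_b


def forward(model: BiLSTMModel, s: SequenceSample) -> np.ndarray:
    """Class probabilities for one sequence (sums to 1)."""
    if s.a.shape[1] != model.forward_cell.input_size:
        raise ValidationError(
            f"sequence has F={s.a.shape[1]}, model expects "
            f"{model.forward_cell.input_size}"
        )
    probs, *_ = _forward_batch(
        model.forward_cell.stacked(), model.backward_cell.stacked(),
        model.head_W, model.head_b, s.a[None, :, :],
    )
    return probs[0]


def predict(
    model: BiLSTMModel, samples: Sequence[SequenceSample]
) -> tuple[list, np.ndarray]:
    """Argmax labels and the probability matrix; ties break toward the
    lower class index."""
    if not samples:
        return [], np.zeros((0, len(model.class_names)))
    X = np.stack([s.a for s in samples])
    probs, *_ = _forward_batch(
        model.forward_cell.stacked(), model.backward_cell.stacked(),
        model.head_W, model.head_b, X,
    )
    idx = np.argmax(probs, axis=1)  # first max -> lowest index on ties
    return [model.class_names[k] for k in idx], probs


def train(
    dataset: Sequence[SequenceSample], cfg: TrainConfig
) -> tuple[BiLSTMModel, np.ndarray]:
    """Fit the Bi-LSTM; returns the model and the per-epoch loss trace."""
    if not dataset:
        raise ValidationError("empty dataset")
    labels = [s.label for s in dataset]
    class_names = tuple(sorted(set(labels), key=str))
    if len(class_names) < 2:
        raise ValidationError("training needs at least 2 classes")
    class_idx = {c: k for k, c in enumerate(class_names)}
    shapes = {s.a.shape for s in dataset}
    if len(shapes) != 1:
        raise ValidationError(f"sequences differ in shape: {shapes}")
    X = np.stack([s.a for s in dataset])
    y = np.array([class_idx[s.label] for s in dataset])
    n, T, F = X.shape
    H, C = cfg.hidden, len(class_names)

    rng = np.random.default_rng(cfg.seed)
    theta_f = _init_stacked(rng, H, F)
    theta_b = _init_stacked(rng, H, F)
    s = 1.0 / np.sqrt(2 * H)
    head_W = rng.uniform(-s, s, size=(C, 2 * H))
    head_b = np.zeros(C)
    params = theta_f + theta_b + [head_W, head_b]

    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    losses = np.empty(cfg.epochs)

    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = perm[start:start + cfg.batch_size]
            Xb, yb = X[batch], y[batch]
            B = len(batch)
            probs, feats, cache_f, cache_b = _forward_batch(
                params[0:3], params[3:6], params[6], params[7], Xb)
            epoch_loss += -np.log(probs[np.arange(B), yb] + 1e-12).sum()

            dlogits = probs.copy()
            dlogits[np.arange(B), yb] -= 1.0
            dlogits /= B
            d_head_W = dlogits.T @ feats
            d_head_b = dlogits.sum(axis=0)
            dfeats = dlogits @ params[6]
            grads_f = _backward_cell_batch(params[0:3], cache_f, dfeats[:, :H])
            grads_b = _backward_cell_batch(params[3:6], cache_b, dfeats[:, H:])
            grads = grads_f + grads_b + [d_head_W, d_head_b]

            gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if gnorm > cfg.grad_clip:
                grads = [g * (cfg.grad_clip / gnorm) for g in grads]

            step += 1
            for k, g in enumerate(grads):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        losses[epoch] = epoch_loss / n

    model = BiLSTMModel(
        forward_cell=LSTMCellParams.from_stacked(*params[0:3]),
        backward_cell=LSTMCellParams.from_stacked(*params[3:6]),
        head_W=params[6],
        head_b=params[7],
        class_names=class_names,
    )
    return model, losses


# --- serialization ---------------------------------------------------------

def model_to_dict(model: BiLSTMModel) -> dict:
    def cell(c: LSTMCellParams) -> dict:
        return {
            k: getattr(c, k).tolist()
            for g in _GATES
            for k in (f"W_{g}h", f"W_{g}a", f"b_{g}")
        }

    return {
        "schema": "hemotex-bilstm-v1",
        "hidden": model.forward_cell.hidden_size,
        "input_size": model.forward_cell.input_size,
        "class_names": [str(c) for c in model.class_names],
        "forward_cell": cell(model.forward_cell),
        "backward_cell": cell(model.backward_cell),
        "head_W": model.head_W.tolist(),
        "head_b": model.head_b.tolist(),
    }


def model_from_dict(d: dict) -> BiLSTMModel:
    def cell(cd: dict) -> LSTMCellParams:
        return LSTMCellParams(**{k: np.asarray(v, dtype=np.float64)
                                 for k, v in cd.items()})

    return BiLSTMModel(
        forward_cell=cell(d["forward_cell"]),
        backward_cell=cell(d["backward_cell"]),
        head_W=np.asarray(d["head_W"], dtype=np.float64),
        head_b=np.asarray(d["head_b"], dtype=np.float64),
        class_names=tuple(d["class_names"]),
    )


def save_model(model: BiLSTMModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path: str) -> BiLSTMModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
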