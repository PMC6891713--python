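"""Gated-RNN forward computation implemented directly from the cell equations.

Four architectures are supported, all of the shape
``batch normalization -> one or two recurrent layers (LSTM or GRU) ->
fully-connected layer -> softmax`` applied to a block of triaxial samples.
Classification is many-to-one: the dense layer reads the final hidden state.

The LSTM cell is the peephole variant,

    i_t = sigma(Wxi x_t + Whi h_{t-1} + wci o c_{t-1} + b_i)
    f_t = sigma(Wxf x_t + Whf h_{t-1} + wcf o c_{t-1} + b_f)
    c~t = tanh (Wxc x_t + Whc h_{t-1} + b_c)
    c_t = f_t o c_{t-1} + i_t o c~t
    o_t = sigma(Wxo x_t + Who h_{t-1} + wco o c_t + b_o)
    h_t = o_t o tanh(c_t)

with ``o`` elementwise multiplication; setting ``peepholes_enabled=False``
drops the wc* terms, giving the standard cell.  The GRU cell is

    z_t = sigma(Wxz x_t + Whz h_{t-1} + b_z)
    r_t = sigma(Wxr x_t + Whr h_{t-1} + b_r)
    h~t = tanh (Wxc x_t + Whc (r_t o h_{t-1}) + b_c)
    h_t = (1 - z_t) o h_{t-1} + z_t o h~t

with the reset gate applied to the hidden state *before* the recurrent
matrix multiplication, and an optional candidate bias (default zero).
Initial hidden and cell states are zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .synthdata import CLASSES

ARCHITECTURES = ("1xLSTM", "2xLSTM", "1xGRU", "2xGRU")

FORMAT_VERSION = 1


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x, dtype=x.dtype if np.issubdtype(x.dtype, np.floating) else float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class BatchNormParams:
    """Per-channel affine normalization (inference mode)."""

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("gamma", "beta", "running_mean", "running_var"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.running_var < 0):
            raise ValueError("running_var must be non-negative")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


@dataclass
class LSTMParams:
    Wxi: np.ndarray
    Wxf: np.ndarray
    Wxc: np.ndarray
    Wxo: np.ndarray
    Whi: np.ndarray
    Whf: np.ndarray
    Whc: np.ndarray
    Who: np.ndarray
    wci: np.ndarray
    wcf: np.ndarray
    wco: np.ndarray
    bi: np.ndarray
    bf: np.ndarray
    bc: np.ndarray
    bo: np.ndarray
    peepholes_enabled: bool = False

    @property
    def n_units(self) -> int:
        return self.Wxi.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.Wxi.shape[1]

    def validate(self) -> None:
        N, M = self.Wxi.shape
        for name in ("Wxi", "Wxf", "Wxc", "Wxo"):
            if getattr(self, name).shape != (N, M):
                raise ValueError(f"{name} must be {(N, M)}")
        for name in ("Whi", "Whf", "Whc", "Who"):
            if getattr(self, name).shape != (N, N):
                raise ValueError(f"{name} must be {(N, N)}")
        for name in ("wci", "wcf", "wco", "bi", "bf", "bc", "bo"):
            if getattr(self, name).shape != (N,):
                raise ValueError(f"{name} must be length {N}")
        for name in self.param_names():
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")

    def param_names(self) -> list[str]:
        names = ["Wxi", "Wxf", "Wxc", "Wxo", "Whi", "Whf", "Whc", "Who", "bi", "bf", "bc", "bo"]
        if self.peepholes_enabled:
            names += ["wci", "wcf", "wco"]
        return names


@dataclass
class GRUParams:
    Wxz: np.ndarray
    Wxr: np.ndarray
    Wxc: np.ndarray
    Whz: np.ndarray
    Whr: np.ndarray
    Whc: np.ndarray
    bz: np.ndarray
    br: np.ndarray
    bc: np.ndarray | None = None  # optional candidate bias, default zero

    def __post_init__(self) -> None:
        if self.bc is None:
            self.bc = np.zeros(self.Wxz.shape[0])

    @property
    def n_units(self) -> int:
        return self.Wxz.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.Wxz.shape[1]

    def validate(self) -> None:
        N, M = self.Wxz.shape
        for name in ("Wxz", "Wxr", "Wxc"):
            if getattr(self, name).shape != (N, M):
                raise ValueError(f"{name} must be {(N, M)}")
        for name in ("Whz", "Whr", "Whc"):
            if getattr(self, name).shape != (N, N):
                raise ValueError(f"{name} must be {(N, N)}")
        for name in ("bz", "br", "bc"):
            if getattr(self, name).shape != (N,):
                raise ValueError(f"{name} must be length {N}")
        for name in self.param_names():
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")

    def param_names(self) -> list[str]:
        return ["Wxz", "Wxr", "Wxc", "Whz", "Whr", "Whc", "bz", "br", "bc"]


@dataclass
class DenseParams:
    W: np.ndarray  # (C, N)
    b: np.ndarray  # (C,)

    def validate(self) -> None:
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[0],):
            raise ValueError("dense W must be (C, N) with b length C")
        if self.W.shape[0] != len(CLASSES):
            raise ValueError(f"dense layer must have {len(CLASSES)} outputs")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ValueError("dense parameters contain non-finite entries")

    def param_names(self) -> list[str]:
        return ["W", "b"]


@dataclass
class ModelParams:
    """Ordered layer parameters of one of the four architectures."""

    batchnorm: BatchNormParams
    recurrent_layers: list
    dense: DenseParams
    arch: str
    act_quant: Optional[Callable[[np.ndarray], np.ndarray]] = None  # deploy hook

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"arch must be one of {ARCHITECTURES}, got {self.arch!r}")
        depth = int(self.arch[0])
        cell = LSTMParams if "LSTM" in self.arch else GRUParams
        if len(self.recurrent_layers) != depth:
            raise ValueError(f"{self.arch} requires {depth} recurrent layer(s)")
        if not all(isinstance(l, cell) for l in self.recurrent_layers):
            raise ValueError(f"{self.arch} requires homogeneous {cell.__name__} layers")
        n_channels = len(self.batchnorm.gamma)
        expected_in = n_channels
        for layer in self.recurrent_layers:
            layer.validate()
            if layer.n_inputs != expected_in:
                raise ValueError(
                    f"layer expects {layer.n_inputs} inputs, but receives {expected_in}"
                )
            expected_in = layer.n_units
        self.dense.validate()
        if self.dense.W.shape[1] != expected_in:
            raise ValueError("dense layer width does not match last recurrent layer")

    @property
    def n_units(self) -> int:
        return self.recurrent_layers[-1].n_units

    def named_params(self) -> list[tuple[str, np.ndarray]]:
        """Trainable parameters as (name, array) pairs; arrays are live views."""
        out = [("bn.gamma", self.batchnorm.gamma), ("bn.beta", self.batchnorm.beta)]
        prefix = "lstm" if "LSTM" in self.arch else "gru"
        for i, layer in enumerate(self.recurrent_layers, start=1):
            out += [(f"{prefix}{i}.{n}", getattr(layer, n)) for n in layer.param_names()]
        out += [(f"dense.{n}", getattr(self.dense, n)) for n in self.dense.param_names()]
        return out


# ---------------------------------------------------------------------------
# Initialization


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))  # fix the sign ambiguity deterministically


def init_model(
    arch: str,
    n_units: int = 32,
    n_inputs: int = 3,
    rng: np.random.Generator | int | None = None,
    peepholes_enabled: bool = False,
) -> ModelParams:
    """Fresh model: Glorot-uniform input/dense weights, orthogonal recurrent
    weights, zero biases, identity batch norm."""
    if arch not in ARCHITECTURES:
        raise ValueError(f"arch must be one of {ARCHITECTURES}, got {arch!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    depth = int(arch[0])
    layers = []
    m = n_inputs
    for _ in range(depth):
        if "LSTM" in arch:
            layers.append(
                LSTMParams(
                    Wxi=_glorot(rng, (n_units, m)),
                    Wxf=_glorot(rng, (n_units, m)),
                    Wxc=_glorot(rng, (n_units, m)),
                    Wxo=_glorot(rng, (n_units, m)),
                    Whi=_orthogonal(rng, n_units),
                    Whf=_orthogonal(rng, n_units),
                    Whc=_orthogonal(rng, n_units),
                    Who=_orthogonal(rng, n_units),
                    wci=np.zeros(n_units),
                    wcf=np.zeros(n_units),
                    wco=np.zeros(n_units),
                    bi=np.zeros(n_units),
                    bf=np.ones(n_units),  # forget-gate bias 1: remember by default
                    bc=np.zeros(n_units),
                    bo=np.zeros(n_units),
                    peepholes_enabled=peepholes_enabled,
                )
            )
        else:
            layers.append(
                GRUParams(
                    Wxz=_glorot(rng, (n_units, m)),
                    Wxr=_glorot(rng, (n_units, m)),
                    Wxc=_glorot(rng, (n_units, m)),
                    Whz=_orthogonal(rng, n_units),
                    Whr=_orthogonal(rng, n_units),
                    Whc=_orthogonal(rng, n_units),
                    bz=np.zeros(n_units),
                    br=np.zeros(n_units),
                    bc=np.zeros(n_units),
                )
            )
        m = n_units
    bn = BatchNormParams(
        gamma=np.ones(n_inputs),
        beta=np.zeros(n_inputs),
        running_mean=np.zeros(n_inputs),
        running_var=np.ones(n_inputs),
    )
    dense = DenseParams(W=_glorot(rng, (len(CLASSES), n_units)), b=np.zeros(len(CLASSES)))
    return ModelParams(batchnorm=bn, recurrent_layers=layers, dense=dense, arch=arch)


# ---------------------------------------------------------------------------
# Forward computation


def batchnorm_apply(p: BatchNormParams, x: np.ndarray) -> np.ndarray:
    """Inference-mode normalization: gamma*(x - mean)/sqrt(var + eps) + beta.

    ``x`` may be a single channel vector or any array whose last axis is the
    channel axis.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(p.gamma):
        raise ValueError(f"expected {len(p.gamma)} channels, got {x.shape[-1]}")
    return p.gamma * (x - p.running_mean) / np.sqrt(p.running_var + p.epsilon) + p.beta


def lstm_step(
    p: LSTMParams, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step.  Inputs may be vectors or (batch, dim) arrays."""
    x_t, h_prev, c_prev = (np.asarray(a, dtype=float) for a in (x_t, h_prev, c_prev))
    if x_t.shape[-1] != p.n_inputs or h_prev.shape[-1] != p.n_units:
        raise ValueError(
            f"shape mismatch: x has {x_t.shape[-1]} features (need {p.n_inputs}), "
            f"h has {h_prev.shape[-1]} units (need {p.n_units})"
        )
    a_i = x_t @ p.Wxi.T + h_prev @ p.Whi.T + p.bi
    a_f = x_t @ p.Wxf.T + h_prev @ p.Whf.T + p.bf
    if p.peepholes_enabled:
        a_i = a_i + p.wci * c_prev
        a_f = a_f + p.wcf * c_prev
    i_t = sigmoid(a_i)
    f_t = sigmoid(a_f)
    c_tilde = np.tanh(x_t @ p.Wxc.T + h_prev @ p.Whc.T + p.bc)
    c_t = f_t * c_prev + i_t * c_tilde
    a_o = x_t @ p.Wxo.T + h_prev @ p.Who.T + p.bo
    if p.peepholes_enabled:
        a_o = a_o + p.wco * c_t
    o_t = sigmoid(a_o)
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


def gru_step(p: GRUParams, x_t: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    """One GRU step.  Inputs may be vectors or (batch, dim) arrays."""
    x_t, h_prev = np.asarray(x_t, dtype=float), np.asarray(h_prev, dtype=float)
    if x_t.shape[-1] != p.n_inputs or h_prev.shape[-1] != p.n_units:
        raise ValueError(
            f"shape mismatch: x has {x_t.shape[-1]} features (need {p.n_inputs}), "
            f"h has {h_prev.shape[-1]} units (need {p.n_units})"
        )
    z_t = sigmoid(x_t @ p.Wxz.T + h_prev @ p.Whz.T + p.bz)
    r_t = sigmoid(x_t @ p.Wxr.T + h_prev @ p.Whr.T + p.br)
    h_tilde = np.tanh(x_t @ p.Wxc.T + (r_t * h_prev) @ p.Whc.T + p.bc)
    return (1.0 - z_t) * h_prev + z_t * h_tilde


def _layer_forward(layer, X: np.ndarray, act_quant=None) -> np.ndarray:
    """Run one recurrent layer over a (batch, T, M) input; returns (batch, T, N)."""
    B, T, _ = X.shape
    N = layer.n_units
    H = np.zeros((B, T, N))
    h = np.zeros((B, N))
    if isinstance(layer, LSTMParams):
        c = np.zeros((B, N))
        for t in range(T):
            h, c = lstm_step(layer, X[:, t, :], h, c)
            if act_quant is not None:
                h, c = act_quant(h), act_quant(c)
            H[:, t, :] = h
    else:
        for t in range(T):
            h = gru_step(layer, X[:, t, :], h)
            if act_quant is not None:
                h = act_quant(h)
            H[:, t, :] = h
    return H


def forward_batch(model: ModelParams, X: np.ndarray) -> np.ndarray:
    """Class probabilities for a stacked block array (n_blocks, width, 3)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3:
        raise ValueError("expected (n_blocks, width, channels) input")
    q = model.act_quant
    Z = batchnorm_apply(model.batchnorm, X)
    if q is not None:
        Z = q(Z)
    for layer in model.recurrent_layers:
        Z = _layer_forward(layer, Z, act_quant=q)
    h_last = Z[:, -1, :]
    logits = h_last @ model.dense.W.T + model.dense.b
    if q is not None:
        logits = q(logits)
    return softmax(logits)


def run_sequence(model: ModelParams, block) -> np.ndarray:
    """Softmax class scores (length 3, summing to 1) for one block."""
    values = block.values if hasattr(block, "values") else np.asarray(block)
    if values.ndim != 2:
        raise ValueError("a single block must be a (width, 3) array")
    if len(values) < 1:
        raise ValueError("block must contain at least one sample")
    return forward_batch(model, values[None])[0]


def predict(model: ModelParams, block) -> tuple[str, np.ndarray]:
    """(label, scores); argmax with ties broken toward the lower class index
    in the order (BKG, ALERT, FALL)."""
    scores = run_sequence(model, block)
    return CLASSES[int(np.argmax(scores))], scores


def predict_batch(model: ModelParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = forward_batch(model, X)
    labels = np.array([CLASSES[i] for i in np.argmax(probs, axis=1)], dtype="<U5")
    return labels, probs


# ---------------------------------------------------------------------------
# Persistence (JSON weight container)


def save_model(model: ModelParams, path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "arch": model.arch,
        "bn.running_mean": model.batchnorm.running_mean.tolist(),
        "bn.running_var": model.batchnorm.running_var.tolist(),
        "bn.epsilon": model.batchnorm.epsilon,
        "peepholes_enabled": bool(
            getattr(model.recurrent_layers[0], "peepholes_enabled", False)
        ),
        "params": {name: arr.tolist() for name, arr in model.named_params()},
    }
    if "LSTM" in model.arch:  # peephole vectors are part of the container either way
        for i, layer in enumerate(model.recurrent_layers, start=1):
            for n in ("wci", "wcf", "wco"):
                payload["params"][f"lstm{i}.{n}"] = getattr(layer, n).tolist()
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> ModelParams:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported weight-container version: {payload.get('format_version')}")
    arch = payload["arch"]
    params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    depth = int(arch[0])
    layers = []
    if "LSTM" in arch:
        for i in range(1, depth + 1):
            kw = {
                n: params[f"lstm{i}.{n}"]
                for n in (
                    "Wxi", "Wxf", "Wxc", "Wxo", "Whi", "Whf", "Whc", "Who",
                    "wci", "wcf", "wco", "bi", "bf", "bc", "bo",
                )
            }
            layers.append(LSTMParams(**kw, peepholes_enabled=payload["peepholes_enabled"]))
    else:
        for i in range(1, depth + 1):
            kw = {
                n: params[f"gru{i}.{n}"]
                for n in ("Wxz", "Wxr", "Wxc", "Whz", "Whr", "Whc", "bz", "br", "bc")
            }
            layers.append(GRUParams(**kw))
    bn = BatchNormParams(
        gamma=params["bn.gamma"],
        beta=params["bn.beta"],
        running_mean=np.asarray(payload["bn.running_mean"], dtype=float),
        running_var=np.asarray(payload["bn.running_var"], dtype=float),
        epsilon=payload["bn.epsilon"],
    )
    dense = DenseParams(W=params["dense.W"], b=params["dense.b"])
    return ModelParams(batchnorm=bn, recurrent_layers=layers, dense=dense, arch=arch)
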