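"""Training of the gated-RNN block classifiers.

The objective is mean multi-class cross-entropy over the softmax output;
gradients are exact analytic backpropagation through time through the cell
equations (including the peephole terms when enabled).  Inverted dropout is
applied only to the inputs of the fully-connected layer.  Evaluation
protocol utilities — subject-balanced train/test splitting, subject-wise
10-fold cross-validation and the 3x3x3 hyperparameter grid (learning rate x
batch size x dropout) — live here too.

Batch-norm statistics are frozen from the training set before optimization
(inference-mode normalization with trainable gamma/beta), so the gradient is
exact and a trained model behaves identically at train and test time.

The sklearn-style front door is :class:`FallDetectorRNN`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import metrics as _metrics
from .rnncore import (
    ARCHITECTURES,
    GRUParams,
    LSTMParams,
    ModelParams,
    batchnorm_apply,
    forward_batch,
    init_model,
    predict_batch,
    sigmoid,
    softmax,
)
from .synthdata import CLASSES, Recording
from .windowing import Block, blocks_to_arrays

logger = logging.getLogger(__name__)

#: The exhaustive hyperparameter grid searched in this study.
DEFAULT_GRID = {
    "learning_rate": [0.001, 0.0005, 0.0001],
    "batch_size": [32, 48, 64],
    "dropout": [0.0, 0.2, 0.35],
}

_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    dropout: float = 0.0
    epochs: int = 30
    optimizer: str = "adam"
    seed: int = 0
    patience: int = 10  # early stop on validation macro-F1 when val data given
    n_units: int = 32
    peepholes: bool = False

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer!r}")


# ---------------------------------------------------------------------------
# Loss


def cross_entropy(scores: np.ndarray, true_label) -> float:
    """-log(score of the true class), clipped away from log(0).

    ``scores`` must be a probability vector (non-negative, summing to 1).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or np.any(scores < 0) or abs(scores.sum() - 1.0) > 1e-6:
        raise ValueError("scores must be a probability vector")
    idx = true_label if isinstance(true_label, (int, np.integer)) else _CLASS_INDEX[str(true_label)]
    return float(-np.log(max(scores[idx], 1e-12)))


def _one_hot(labels: Sequence) -> np.ndarray:
    idx = _metrics._as_indices(labels)
    out = np.zeros((len(idx), len(CLASSES)))
    out[np.arange(len(idx)), idx] = 1.0
    return out


# ---------------------------------------------------------------------------
# Forward with cache + analytic BPTT


def _lstm_forward_cached(p: LSTMParams, X: np.ndarray):
    B, T, _ = X.shape
    N = p.n_units
    H = np.zeros((B, T, N))
    cache = {k: np.zeros((B, T, N)) for k in ("I", "F", "Ct", "C", "O", "Cprev", "Hprev")}
    h = np.zeros((B, N))
    c = np.zeros((B, N))
    for t in range(T):
        x = X[:, t, :]
        a_i = x @ p.Wxi.T + h @ p.Whi.T + p.bi
        a_f = x @ p.Wxf.T + h @ p.Whf.T + p.bf
        if p.peepholes_enabled:
            a_i = a_i + p.wci * c
            a_f = a_f + p.wcf * c
        i_t, f_t = sigmoid(a_i), sigmoid(a_f)
        c_tilde = np.tanh(x @ p.Wxc.T + h @ p.Whc.T + p.bc)
        c_new = f_t * c + i_t * c_tilde
        a_o = x @ p.Wxo.T + h @ p.Who.T + p.bo
        if p.peepholes_enabled:
            a_o = a_o + p.wco * c_new
        o_t = sigmoid(a_o)
        cache["I"][:, t], cache["F"][:, t], cache["Ct"][:, t] = i_t, f_t, c_tilde
        cache["O"][:, t], cache["Cprev"][:, t], cache["Hprev"][:, t] = o_t, c, h
        c = c_new
        h = o_t * np.tanh(c_new)
        cache["C"][:, t] = c_new
        H[:, t] = h
    cache["X"] = X
    return H, cache


def _lstm_backward(p: LSTMParams, cache, dH: np.ndarray):
    X = cache["X"]
    B, T, _ = X.shape
    g = {n: np.zeros_like(getattr(p, n)) for n in p.param_names()}
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, p.n_units))
    dc_next = np.zeros((B, p.n_units))
    for t in reversed(range(T)):
        I, F, Ct = cache["I"][:, t], cache["F"][:, t], cache["Ct"][:, t]
        O, C, Cprev = cache["O"][:, t], cache["C"][:, t], cache["Cprev"][:, t]
        h_prev, x = cache["Hprev"][:, t], X[:, t]
        tanh_c = np.tanh(C)
        dh = dH[:, t] + dh_next
        da_o = dh * tanh_c * O * (1 - O)
        dc = dh * O * (1 - tanh_c**2) + dc_next
        if p.peepholes_enabled:
            dc = dc + da_o * p.wco
        da_c = dc * I * (1 - Ct**2)
        da_i = dc * Ct * I * (1 - I)
        da_f = dc * Cprev * F * (1 - F)
        dc_next = dc * F
        if p.peepholes_enabled:
            dc_next = dc_next + da_i * p.wci + da_f * p.wcf
            g["wci"] += (da_i * Cprev).sum(axis=0)
            g["wcf"] += (da_f * Cprev).sum(axis=0)
            g["wco"] += (da_o * C).sum(axis=0)
        for da, wx, wh, b in (
            (da_i, "Wxi", "Whi", "bi"),
            (da_f, "Wxf", "Whf", "bf"),
            (da_c, "Wxc", "Whc", "bc"),
            (da_o, "Wxo", "Who", "bo"),
        ):
            g[wx] += da.T @ x
            g[wh] += da.T @ h_prev
            g[b] += da.sum(axis=0)
        dX[:, t] = da_i @ p.Wxi + da_f @ p.Wxf + da_c @ p.Wxc + da_o @ p.Wxo
        dh_next = da_i @ p.Whi + da_f @ p.Whf + da_c @ p.Whc + da_o @ p.Who
    return g, dX


def _gru_forward_cached(p: GRUParams, X: np.ndarray):
    B, T, _ = X.shape
    N = p.n_units
    H = np.zeros((B, T, N))
    cache = {k: np.zeros((B, T, N)) for k in ("Z", "R", "Ht", "Hprev")}
    h = np.zeros((B, N))
    for t in range(T):
        x = X[:, t, :]
        z = sigmoid(x @ p.Wxz.T + h @ p.Whz.T + p.bz)
        r = sigmoid(x @ p.Wxr.T + h @ p.Whr.T + p.br)
        h_tilde = np.tanh(x @ p.Wxc.T + (r * h) @ p.Whc.T + p.bc)
        cache["Z"][:, t], cache["R"][:, t] = z, r
        cache["Ht"][:, t], cache["Hprev"][:, t] = h_tilde, h
        h = (1 - z) * h + z * h_tilde
        H[:, t] = h
    cache["X"] = X
    return H, cache


def _gru_backward(p: GRUParams, cache, dH: np.ndarray):
    X = cache["X"]
    B, T, _ = X.shape
    g = {n: np.zeros_like(getattr(p, n)) for n in p.param_names()}
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, p.n_units))
    for t in reversed(range(T)):
        Z, R = cache["Z"][:, t], cache["R"][:, t]
        Ht, Hprev = cache["Ht"][:, t], cache["Hprev"][:, t]
        x = X[:, t]
        dh = dH[:, t] + dh_next
        da_h = dh * Z * (1 - Ht**2)
        da_z = dh * (Ht - Hprev) * Z * (1 - Z)
        d_rh = da_h @ p.Whc  # gradient w.r.t. r o h_prev
        da_r = d_rh * Hprev * R * (1 - R)
        g["Wxz"] += da_z.T @ x
        g["Whz"] += da_z.T @ Hprev
        g["bz"] += da_z.sum(axis=0)
        g["Wxr"] += da_r.T @ x
        g["Whr"] += da_r.T @ Hprev
        g["br"] += da_r.sum(axis=0)
        g["Wxc"] += da_h.T @ x
        g["Whc"] += da_h.T @ (R * Hprev)
        g["bc"] += da_h.sum(axis=0)
        dX[:, t] = da_z @ p.Wxz + da_r @ p.Wxr + da_h @ p.Wxc
        dh_next = dh * (1 - Z) + d_rh * R + da_z @ p.Whz + da_r @ p.Whr
    return g, dX


def _forward_cached(model: ModelParams, X: np.ndarray, dropout_mask: np.ndarray | None):
    bn = model.batchnorm
    xhat = (X - bn.running_mean) / np.sqrt(bn.running_var + bn.epsilon)
    Z = bn.gamma * xhat + bn.beta
    layer_caches = []
    for layer in model.recurrent_layers:
        if isinstance(layer, LSTMParams):
            Z, cache = _lstm_forward_cached(layer, Z)
        else:
            Z, cache = _gru_forward_cached(layer, Z)
        layer_caches.append(cache)
    h_last = Z[:, -1, :]
    h_drop = h_last * dropout_mask if dropout_mask is not None else h_last
    logits = h_drop @ model.dense.W.T + model.dense.b
    probs = softmax(logits)
    return probs, {"xhat": xhat, "layers": layer_caches, "h_drop": h_drop, "T": X.shape[1]}


def _backward(model: ModelParams, cache, probs, Y, dropout_mask):
    B = len(Y)
    grads: dict[str, np.ndarray] = {}
    dlogits = (probs - Y) / B
    grads["dense.W"] = dlogits.T @ cache["h_drop"]
    grads["dense.b"] = dlogits.sum(axis=0)
    dh = dlogits @ model.dense.W
    if dropout_mask is not None:
        dh = dh * dropout_mask
    prefix = "lstm" if "LSTM" in model.arch else "gru"
    N_last = model.recurrent_layers[-1].n_units
    dZ = np.zeros((B, cache["T"], N_last))
    dZ[:, -1, :] = dh
    for i in reversed(range(len(model.recurrent_layers))):
        layer = model.recurrent_layers[i]
        if isinstance(layer, LSTMParams):
            g, dZ = _lstm_backward(layer, cache["layers"][i], dZ)
        else:
            g, dZ = _gru_backward(layer, cache["layers"][i], dZ)
        for name, val in g.items():
            grads[f"{prefix}{i + 1}.{name}"] = val
    grads["bn.gamma"] = (dZ * cache["xhat"]).sum(axis=(0, 1))
    grads["bn.beta"] = dZ.sum(axis=(0, 1))
    return grads


def gradients(
    model: ModelParams,
    blocks,
    labels: Sequence,
    dropout_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Exact analytic gradients of mean cross-entropy w.r.t. every trainable
    parameter (including peephole weights when enabled)."""
    X = _blocks_as_array(blocks)
    if len(X) == 0:
        raise ValueError("batch must be non-empty")
    Y = _one_hot(labels)
    if len(Y) != len(X):
        raise ValueError("blocks and labels length mismatch")
    probs, cache = _forward_cached(model, X, dropout_mask)
    return _backward(model, cache, probs, Y, dropout_mask)


def batch_loss(model: ModelParams, blocks, labels, dropout_mask=None) -> float:
    """Mean cross-entropy of a batch (the quantity `gradients` differentiates)."""
    X = _blocks_as_array(blocks)
    probs, _ = _forward_cached(model, X, dropout_mask)
    idx = _metrics._as_indices(labels)
    return float(-np.mean(np.log(np.clip(probs[np.arange(len(idx)), idx], 1e-12, None))))


def _blocks_as_array(blocks) -> np.ndarray:
    if isinstance(blocks, np.ndarray):
        return blocks if blocks.ndim == 3 else blocks[None]
    if len(blocks) and isinstance(blocks[0], Block):
        return np.stack([b.values for b in blocks])
    return np.asarray(blocks, dtype=float)


# ---------------------------------------------------------------------------
# Optimizers


class _Adam:
    def __init__(self, names, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {n: np.zeros(s) for n, s in zip(names, shapes)}
        self.v = {n: np.zeros(s) for n, s in zip(names, shapes)}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for n, g in grads.items():
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            mhat = self.m[n] / (1 - self.b1**self.t)
            vhat = self.v[n] / (1 - self.b2**self.t)
            params[n] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, lr):
        self.lr = lr

    def step(self, params: dict, grads: dict) -> None:
        for n, g in grads.items():
            params[n] -= self.lr * g


# ---------------------------------------------------------------------------
# Training loop


def train(
    arch: str,
    blocks,
    labels: Sequence,
    cfg: TrainConfig | None = None,
    validation: tuple | None = None,
) -> tuple[ModelParams, list[dict]]:
    """Mini-batch training of one architecture; deterministic given the seed.

    Returns the trained model and a history of per-epoch mean loss and
    training macro-F1 (plus validation macro-F1 when ``validation`` =
    (X_val, y_val) is given; early stopping then uses ``cfg.patience``).
    """
    cfg = cfg or TrainConfig()
    X = _blocks_as_array(blocks)
    y = np.asarray(labels)
    if len(X) == 0:
        raise ValueError("training set is empty")
    if len(X) != len(y):
        raise ValueError("blocks and labels length mismatch")
    rng = np.random.default_rng(cfg.seed)
    model = init_model(arch, n_units=cfg.n_units, n_inputs=X.shape[2], rng=rng,
                       peepholes_enabled=cfg.peepholes)
    # freeze normalization statistics from the training set
    model.batchnorm.running_mean = X.mean(axis=(0, 1))
    model.batchnorm.running_var = X.var(axis=(0, 1))
    params = dict(model.named_params())
    if cfg.optimizer == "adam":
        opt = _Adam(params.keys(), [p.shape for p in params.values()], cfg.learning_rate)
    else:
        opt = _SGD(cfg.learning_rate)
    Yidx = _metrics._as_indices(y)
    history: list[dict] = []
    best_val, best_state, stall = -np.inf, None, 0
    n = len(X)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            Xb, yb = X[sel], Yidx[sel]
            mask = None
            if cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                mask = (rng.random((len(sel), model.n_units)) < keep) / keep
            probs, cache = _forward_cached(model, Xb, mask)
            Yb = np.zeros((len(sel), len(CLASSES)))
            Yb[np.arange(len(sel)), yb] = 1.0
            losses.append(
                float(-np.mean(np.log(np.clip(probs[np.arange(len(sel)), yb], 1e-12, None))))
            )
            grads = _backward(model, cache, probs, Yb, mask)
            opt.step(params, grads)
        pred, _ = predict_batch(model, X)
        _, _, train_f1 = _metrics.macro_metrics(_metrics.confusion(y, pred))
        record = {"epoch": epoch, "loss": float(np.mean(losses)), "train_macro_f1": train_f1}
        if validation is not None:
            Xv, yv = validation
            pv, _ = predict_batch(model, _blocks_as_array(Xv))
            _, _, val_f1 = _metrics.macro_metrics(_metrics.confusion(np.asarray(yv), pv))
            record["val_macro_f1"] = val_f1
            if val_f1 > best_val:
                best_val, stall = val_f1, 0
                best_state = {k: v.copy() for k, v in params.items()}
            else:
                stall += 1
        history.append(record)
        logger.debug("epoch %d: loss=%.4f train_f1=%.4f", epoch, record["loss"], train_f1)
        if validation is not None and stall > cfg.patience:
            logger.info("early stop at epoch %d (best val macro-F1 %.4f)", epoch, best_val)
            break
    if best_state is not None:
        for k, v in best_state.items():
            params[k][...] = v
    return model, history


# ---------------------------------------------------------------------------
# Protocol: splits, cross-validation, grid search


def _age_groups(recordings: Mapping[str, list[Recording]]) -> dict[str, str]:
    return {s: recs[0].age_group for s, recs in recordings.items()}


def subject_split(
    recordings: Mapping[str, list[Recording]],
    train_fraction: float = 0.8,
    seed: int = 0,
    balance_age_groups: bool = True,
) -> tuple[list[str], list[str]]:
    """Random subject-wise split preserving the adult/elderly proportion.

    No subject (hence no recording or block) appears on both sides.  With
    23 adults + 15 elderly at 0.8 this gives 30 train / 8 test subjects.
    """
    subjects = sorted(recordings)
    if len(subjects) < 2:
        raise ValueError("need at least two subjects to split")
    rng = np.random.default_rng(seed)
    groups = _age_groups(recordings)
    train: list[str] = []
    test: list[str] = []
    if balance_age_groups:
        present = sorted(set(groups.values()))
        if len(present) < 2 and len(set(groups.values())) < 2:
            # only one age group present: fall back to a plain split
            pass
        for grp in present:
            members = [s for s in subjects if groups[s] == grp]
            rng.shuffle(members)
            k = int(round(train_fraction * len(members)))
            k = min(max(k, 0), len(members))
            train += members[:k]
            test += members[k:]
    else:
        members = list(subjects)
        rng.shuffle(members)
        k = int(round(train_fraction * len(members)))
        train, test = members[:k], members[k:]
    if not train or not test:
        raise ValueError(
            f"split impossible: {len(subjects)} subjects at fraction {train_fraction} "
            f"leaves an empty side (train={len(train)}, test={len(test)})"
        )
    return sorted(train), sorted(test)


def kfold_cv(
    arch: str,
    blocks_by_subject: Mapping[str, Sequence[Block]],
    k: int = 10,
    cfg: TrainConfig | None = None,
) -> dict:
    """Subject-wise k-fold cross-validation.

    Subjects are shuffled once and dealt round-robin into k folds; each fold
    serves as validation exactly once.  Returns per-fold EvalReports plus
    the mean and standard deviation of macro-F1.
    """
    cfg = cfg or TrainConfig()
    subjects = sorted(blocks_by_subject)
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot fill {k} folds")
    rng = np.random.default_rng(cfg.seed)
    order = list(subjects)
    rng.shuffle(order)
    folds = [order[i::k] for i in range(k)]
    reports = []
    for i, val_subjects in enumerate(folds):
        val_set = set(val_subjects)
        train_blocks = [b for s in subjects if s not in val_set for b in blocks_by_subject[s]]
        val_blocks = [b for s in val_subjects for b in blocks_by_subject[s]]
        Xtr, ytr, _ = blocks_to_arrays(train_blocks)
        Xva, yva, _ = blocks_to_arrays(val_blocks)
        model, _ = train(arch, Xtr, ytr, cfg)
        pred, probs = predict_batch(model, Xva)
        reports.append(_metrics.evaluate(yva, pred, probs))
        logger.info("fold %d/%d: macro-F1 %.4f", i + 1, k, reports[-1].macro_f1)
    f1s = np.array([r.macro_f1 for r in reports])
    return {
        "reports": reports,
        "folds": folds,
        "macro_f1_mean": float(f1s.mean()),
        "macro_f1_std": float(f1s.std(ddof=1)) if k > 1 else 0.0,
    }


@dataclass
class GridSearchResult:
    results: list  # [(config dict, mean macro-F1, std)]
    best_config: dict
    best_score: float

    def __post_init__(self) -> None:
        if self.results and self.best_score < max(r[1] for r in self.results) - 1e-12:
            raise ValueError("best configuration must attain the maximum mean macro-F1")


def grid_search(
    arch: str,
    blocks_by_subject: Mapping[str, Sequence[Block]],
    grid: Mapping[str, Sequence] | None = None,
    k: int = 10,
    cfg: TrainConfig | None = None,
) -> GridSearchResult:
    """Exhaustive search over the hyperparameter grid via subject-wise k-fold
    cross-validation; returns the argmax configuration."""
    grid = dict(grid or DEFAULT_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    base = cfg or TrainConfig()
    keys = sorted(grid)
    results = []
    for combo in itertools.product(*(grid[key] for key in keys)):
        point = dict(zip(keys, combo))
        trial = TrainConfig(**{**asdict(base), **point})
        cv = kfold_cv(arch, blocks_by_subject, k=k, cfg=trial)
        results.append((point, cv["macro_f1_mean"], cv["macro_f1_std"]))
        logger.info("grid point %s: macro-F1 %.4f +- %.4f", point, results[-1][1], results[-1][2])
    best = max(results, key=lambda r: r[1])
    return GridSearchResult(results=results, best_config=best[0], best_score=best[1])


# ---------------------------------------------------------------------------
# sklearn estimator


class FallDetectorRNN(ClassifierMixin, BaseEstimator):
    """Gated-RNN block classifier with the sklearn estimator interface.

    Parameters mirror :class:`TrainConfig`; ``X`` is a stacked block array
    of shape (n_blocks, width, 3) in g units and ``y`` holds labels in
    {"BKG", "ALERT", "FALL"}.

    Fitted attributes: ``model_`` (the trained :class:`ModelParams`),
    ``history_`` (per-epoch loss/macro-F1 records), ``classes_``.
    """

    def __init__(
        self,
        arch: str = "1xGRU",
        n_units: int = 32,
        learning_rate: float = 0.001,
        batch_size: int = 32,
        dropout: float = 0.0,
        epochs: int = 30,
        optimizer: str = "adam",
        peepholes: bool = False,
        patience: int = 10,
        random_state: int = 0,
    ):
        self.arch = arch
        self.n_units = n_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.dropout = dropout
        self.epochs = epochs
        self.optimizer = optimizer
        self.peepholes = peepholes
        self.patience = patience
        self.random_state = random_state

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 3:
            raise ValueError(f"X must be (n_blocks, width, 3), got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            dropout=self.dropout,
            epochs=self.epochs,
            optimizer=self.optimizer,
            seed=self.random_state,
            patience=self.patience,
            n_units=self.n_units,
            peepholes=self.peepholes,
        )

    def fit(self, X, y, validation: tuple | None = None):
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"arch must be one of {ARCHITECTURES}, got {self.arch!r}")
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        _metrics._as_indices(y)  # label validation
        self.model_, self.history_ = train(self.arch, X, y, self._config(), validation=validation)
        self.classes_ = np.array(CLASSES, dtype="<U5")
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return forward_batch(self.model_, self._validate_X(X))

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        labels, _ = predict_batch(self.model_, self._validate_X(X))
        return labels

    def score(self, X, y, sample_weight=None) -> float:
        """Macro F1-score (the study's headline figure), not accuracy."""
        pred = self.predict(X)
        _, _, f1 = _metrics.macro_metrics(_metrics.confusion(np.asarray(y), pred))
        return f1

    def evaluate(self, X, y) -> _metrics.EvalReport:
        pred = self.predict(X)
        return _metrics.evaluate(np.asarray(y), pred, self.predict_proba(X))

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
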