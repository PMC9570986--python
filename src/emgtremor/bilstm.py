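"""Bidirectional LSTM window classifier, implemented in numpy.

The classifier consumes one 250 ms window of filtered sEMG — an ``(l, 8)``
matrix of l samples by 8 channels — and emits a class distribution over
tasks or tremor types.  Two cell formulations are provided:

``paper_literal``
    The minimal memory cell in which the previous hidden state enters the
    three gate pre-activations unweighted and the cell candidate sees only
    the current input::

        i_t = sigma(Wi x_t + h_{t-1})
        f_t = sigma(Wf x_t + h_{t-1})
        o_t = sigma(Wo x_t + h_{t-1})
        c_t = f_t * c_{t-1} + i_t * tanh(Wc x_t)
        h_t = tanh(c_t) * o_t

``standard``
    The conventional cell with recurrent weight matrices ``Ui..Uc`` and
    bias vectors on every gate.  This is the training default.

A forward cell consumes the window in time order and a backward cell in
reverse; their final hidden states are concatenated into a softmax head,
trained with categorical cross-entropy under plain SGD or Adam
(beta1=0.9, beta2=0.999, eps=1e-8).  Gradients are exact
backpropagation-through-time, validated against finite differences in the
test-suite.  All randomness is seeded; identical inputs and seeds give
bit-identical models.

The ``activation`` hyperparameter (tanh or ReLU) selects the cell-candidate
nonlinearity; gates remain logistic and the cell output transform remains
tanh.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "LSTMCellParams", "CellState", "BiLSTMModel", "TrainingHistory",
    "init_model", "lstm_step", "bilstm_forward", "predict_proba", "train",
    "warm_start", "loss_and_grads", "BiLSTMClassifier",
    "save_model", "load_model",
]

_GATES = ("i", "f", "o", "c")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(x)
    if kind == "ReLU":
        return np.maximum(x, 0.0)
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad(pre: np.ndarray, post: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - post * post
    return (pre > 0).astype(pre.dtype)


@dataclass
class LSTMCellParams:
    """Parameters of one directional LSTM cell.

    Gate weights are stored stacked as ``W`` of shape ``(4h, d)`` in gate
    order (input, forget, output, candidate); the named single-gate views
    ``Wi, Wf, Wo, Wc`` are slices of it.  ``standard`` mode additionally
    carries stacked recurrent weights ``U`` (4h, h) and biases ``b`` (4h,).
    """

    mode: str
    hidden: int
    input_dim: int
    activation: str
    W: np.ndarray
    U: Optional[np.ndarray] = None
    b: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mode not in ("paper_literal", "standard"):
            raise ValueError(f"unknown cell mode {self.mode!r}")
        if self.W.shape != (4 * self.hidden, self.input_dim):
            raise ValueError(f"W must be (4h, d) = {(4 * self.hidden, self.input_dim)}")
        if self.mode == "standard":
            if self.U is None or self.b is None:
                raise ValueError("standard mode requires U and b")

    def _gate(self, which: str) -> np.ndarray:
        k = _GATES.index(which)
        return self.W[k * self.hidden : (k + 1) * self.hidden]

    @property
    def Wi(self) -> np.ndarray:
        return self._gate("i")

    @property
    def Wf(self) -> np.ndarray:
        return self._gate("f")

    @property
    def Wo(self) -> np.ndarray:
        return self._gate("o")

    @property
    def Wc(self) -> np.ndarray:
        return self._gate("c")


@dataclass
class CellState:
    """Hidden and cell vectors (h_t, c_t) of one direction."""

    h: np.ndarray
    c: np.ndarray

    @staticmethod
    def zeros(hidden: int) -> "CellState":
        return CellState(h=np.zeros(hidden), c=np.zeros(hidden))


@dataclass
class BiLSTMModel:
    """Forward and backward cells plus a dense softmax head.

    The head maps the concatenated final hidden states (forward first,
    then backward; dimension 2h) to class scores.
    """

    forward_cell: LSTMCellParams
    backward_cell: LSTMCellParams
    head_W: np.ndarray  # (K, 2h)
    head_b: np.ndarray  # (K,)
    classes: Tuple[str, ...]
    hyper: Dict[str, object]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def hidden(self) -> int:
        return self.forward_cell.hidden

    def copy(self) -> "BiLSTMModel":
        return copy.deepcopy(self)

    def parameters(self) -> Dict[str, np.ndarray]:
        """Named view of every trainable tensor."""
        out = {"head_W": self.head_W, "head_b": self.head_b}
        for tag, cell in (("fwd", self.forward_cell), ("bwd", self.backward_cell)):
            out[f"{tag}_W"] = cell.W
            if cell.mode == "standard":
                out[f"{tag}_U"] = cell.U
                out[f"{tag}_b"] = cell.b
        return out


@dataclass
class TrainingHistory:
    """Per-epoch loss and training accuracy traces."""

    loss: List[float]
    accuracy: List[float]
    seed: int


def _init_cell(
    mode: str, hidden: int, input_dim: int, activation: str, rng: np.random.Generator
) -> LSTMCellParams:
    # scaled-uniform init: +-1/sqrt(fan_in) per matrix
    sw = 1.0 / np.sqrt(input_dim)
    W = rng.uniform(-sw, sw, size=(4 * hidden, input_dim))
    U = b = None
    if mode == "standard":
        su = 1.0 / np.sqrt(hidden)
        U = rng.uniform(-su, su, size=(4 * hidden, hidden))
        b = np.zeros(4 * hidden)
    return LSTMCellParams(mode, hidden, input_dim, activation, W, U, b)


def init_model(
    hyper: Dict[str, object],
    classes: Sequence[str],
    n_channels: int = 8,
    seed: int = 0,
    mode: str = "standard",
) -> BiLSTMModel:
    """Build a randomly initialized BiLSTM with the given hyperparameters.

    Weights are drawn from a scaled-uniform distribution (+-1/sqrt(fan-in))
    keyed on ``seed``; identical arguments give bit-identical models.
    """
    if len(classes) == 0:
        raise ValueError("class list must be non-empty")
    hidden = int(hyper.get("n_neurons", 20))
    activation = str(hyper.get("activation", "tanh"))
    if activation not in ("tanh", "ReLU"):
        raise ValueError(f"unknown activation {activation!r}")
    rng = np.random.default_rng(seed)
    fwd = _init_cell(mode, hidden, n_channels, activation, rng)
    bwd = _init_cell(mode, hidden, n_channels, activation, rng)
    sh = 1.0 / np.sqrt(2 * hidden)
    head_W = rng.uniform(-sh, sh, size=(len(classes), 2 * hidden))
    head_b = np.zeros(len(classes))
    return BiLSTMModel(
        forward_cell=fwd,
        backward_cell=bwd,
        head_W=head_W,
        head_b=head_b,
        classes=tuple(classes),
        hyper=dict(hyper),
    )


def _cell_pre(params: LSTMCellParams, x: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    """Stacked gate pre-activations for a batch: (B, 4h)."""
    pre = x @ params.W.T
    h = params.hidden
    if params.mode == "standard":
        pre = pre + h_prev @ params.U.T + params.b
    else:
        # hidden state enters gates i, f, o unweighted; candidate sees only x
        pre[:, : 3 * h] += np.tile(h_prev, (1, 3))
    return pre


def lstm_step(params: LSTMCellParams, xt: np.ndarray, state: CellState) -> CellState:
    """Advance one LSTM cell by a single time step (single sample)."""
    xt = np.asarray(xt, dtype=float)
    if xt.shape != (params.input_dim,):
        raise ValueError(f"xt must have shape ({params.input_dim},), got {xt.shape}")
    if state.h.shape != (params.hidden,) or state.c.shape != (params.hidden,):
        raise ValueError("state dimension does not match cell hidden size")
    pre = _cell_pre(params, xt[None, :], state.h[None, :])[0]
    h = params.hidden
    i = _sigmoid(pre[0 * h : 1 * h])
    f = _sigmoid(pre[1 * h : 2 * h])
    o = _sigmoid(pre[2 * h : 3 * h])
    g = _act(pre[3 * h : 4 * h], params.activation)
    c = f * state.c + i * g
    return CellState(h=np.tanh(c) * o, c=c)


def _run_direction(
    params: LSTMCellParams, X: np.ndarray, reverse: bool, keep_cache: bool
):
    """Unroll one direction over a batch X of shape (B, T, d)."""
    B, T, _ = X.shape
    h = np.zeros((B, params.hidden))
    c = np.zeros((B, params.hidden))
    cache = []
    order = range(T - 1, -1, -1) if reverse else range(T)
    nh = params.hidden
    for t in order:
        x = X[:, t, :]
        pre = _cell_pre(params, x, h)
        i = _sigmoid(pre[:, 0 * nh : 1 * nh])
        f = _sigmoid(pre[:, 1 * nh : 2 * nh])
        o = _sigmoid(pre[:, 2 * nh : 3 * nh])
        g_pre = pre[:, 3 * nh : 4 * nh]
        g = _act(g_pre, params.activation)
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        if keep_cache:
            cache.append((x, h, c, i, f, o, g_pre, g, c_new, tanh_c))
        h = tanh_c * o
        c = c_new
    return h, cache


def _direction_backward(
    params: LSTMCellParams, cache, dh_final: np.ndarray
) -> Tuple[Dict[str, np.ndarray], None]:
    """BPTT through one direction; only the final hidden state receives
    an external gradient (per-window classification uses final states)."""
    nh = params.hidden
    dW = np.zeros_like(params.W)
    dU = np.zeros_like(params.U) if params.U is not None else None
    db = np.zeros_like(params.b) if params.b is not None else None
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for x, h_prev, c_prev, i, f, o, g_pre, g, c_new, tanh_c in reversed(cache):
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_prev = dc * f
        dpre = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * _act_grad(g_pre, g, params.activation),
            ],
            axis=1,
        )
        dW += dpre.T @ x
        if params.mode == "standard":
            dU += dpre.T @ h_prev
            db += dpre.sum(axis=0)
            dh = dpre @ params.U
        else:
            # identity coupling of h_prev into the i, f, o pre-activations
            dh = dpre[:, 0 * nh : 1 * nh] + dpre[:, 1 * nh : 2 * nh] + dpre[:, 2 * nh : 3 * nh]
        dc = dc_prev
    grads = {"W": dW}
    if params.mode == "standard":
        grads["U"] = dU
        grads["b"] = db
    return grads, None


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_proba(model: BiLSTMModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of windows X of shape (B, l, d)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None, :, :]
    if X.shape[2] != model.forward_cell.input_dim:
        raise ValueError(
            f"expected {model.forward_cell.input_dim} channels, got {X.shape[2]}"
        )
    h_fwd, _ = _run_direction(model.forward_cell, X, reverse=False, keep_cache=False)
    h_bwd, _ = _run_direction(model.backward_cell, X, reverse=True, keep_cache=False)
    z = np.concatenate([h_fwd, h_bwd], axis=1)
    return _softmax(z @ model.head_W.T + model.head_b)


def bilstm_forward(model: BiLSTMModel, window: np.ndarray) -> np.ndarray:
    """Class probability vector for a single (l, d) window."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError(f"window must be 2-D (l, channels), got shape {window.shape}")
    return predict_proba(model, window[None, :, :])[0]


def loss_and_grads(
    model: BiLSTMModel, X: np.ndarray, y_idx: np.ndarray
) -> Tuple[float, Dict[str, np.ndarray], np.ndarray]:
    """Mean cross-entropy over a batch and exact gradients of every tensor.

    Returns ``(loss, grads, probs)`` with grads keyed like
    :meth:`BiLSTMModel.parameters`.
    """
    X = np.asarray(X, dtype=float)
    B = X.shape[0]
    h_fwd, cache_f = _run_direction(model.forward_cell, X, reverse=False, keep_cache=True)
    h_bwd, cache_b = _run_direction(model.backward_cell, X, reverse=True, keep_cache=True)
    z = np.concatenate([h_fwd, h_bwd], axis=1)
    probs = _softmax(z @ model.head_W.T + model.head_b)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(B), y_idx] + eps)))

    dlogits = probs.copy()
    dlogits[np.arange(B), y_idx] -= 1.0
    dlogits /= B
    grads: Dict[str, np.ndarray] = {
        "head_W": dlogits.T @ z,
        "head_b": dlogits.sum(axis=0),
    }
    dz = dlogits @ model.head_W
    nh = model.hidden
    gf, _ = _direction_backward(model.forward_cell, cache_f, dz[:, :nh])
    gb, _ = _direction_backward(model.backward_cell, cache_b, dz[:, nh:])
    for tag, g in (("fwd", gf), ("bwd", gb)):
        for k, v in g.items():
            grads[f"{tag}_{k}"] = v
    return loss, grads, probs


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class _SGD:
    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr = lr

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        for k, p in params.items():
            p -= self.lr * grads[k]


def _as_xy(train_set) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(train_set, tuple):
        return np.asarray(train_set[0], dtype=float), np.asarray(train_set[1])
    return np.asarray(train_set.windows, dtype=float), np.asarray(train_set.labels)


def train(
    model: BiLSTMModel,
    train_set,
    seed: int = 0,
) -> Tuple[BiLSTMModel, TrainingHistory]:
    """Train a copy of ``model`` by minibatch gradient descent.

    ``train_set`` is a :class:`~emgtremor.preprocess.WindowedDataset` or an
    ``(X, y)`` tuple.  Minimises categorical cross-entropy for
    ``hyper['n_epochs']`` epochs at ``hyper['learning_rate']`` with the
    chosen optimizer; batch order is shuffled from ``seed``.  Deterministic
    given (model, data, seed).
    """
    X, y = _as_xy(train_set)
    class_to_idx = {c: k for k, c in enumerate(model.classes)}
    unseen = sorted({str(l) for l in y if str(l) not in class_to_idx})
    if unseen:
        raise ValueError(f"labels {unseen} not among model classes {model.classes}")
    y_idx = np.array([class_to_idx[str(l)] for l in y])

    hyper = model.hyper
    n_epochs = int(hyper.get("n_epochs", 50))
    batch_size = int(hyper.get("batch_size", 32))
    lr = float(hyper.get("learning_rate", 1e-3))
    opt_name = str(hyper.get("optimizer", "Adam"))
    n = X.shape[0]
    if batch_size > n:
        raise ValueError(f"batch_size {batch_size} exceeds dataset size {n}")

    model = model.copy()
    params = model.parameters()
    if opt_name == "Adam":
        opt = _Adam(params, lr)
    elif opt_name == "SGD":
        opt = _SGD(params, lr)
    else:
        raise ValueError(f"unknown optimizer {opt_name!r}")

    rng = np.random.default_rng(seed)
    losses, accs = [], []
    for _ in range(n_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss, grads, probs = loss_and_grads(model, X[idx], y_idx[idx])
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
            correct += int((probs.argmax(axis=1) == y_idx[idx]).sum())
        losses.append(epoch_loss / n)
        accs.append(correct / n)
    return model, TrainingHistory(loss=losses, accuracy=accs, seed=seed)


def warm_start(
    target: BiLSTMModel,
    source: BiLSTMModel,
    policy: str = "strict",
) -> Tuple[BiLSTMModel, float]:
    """Initialize ``target`` from a trained ``source`` model.

    ``strict`` requires identical architectures and copies every tensor;
    ``compatible_only`` copies each tensor whose shape matches and leaves
    the rest at their fresh initialization.  Returns the new model and the
    fraction of tensors copied.
    """
    if policy not in ("strict", "compatible_only"):
        raise ValueError(f"unknown warm-start policy {policy!r}")
    out = target.copy()
    tgt = out.parameters()
    src = source.parameters()
    names = sorted(set(tgt) | set(src))
    copied = 0
    for name in names:
        if name in tgt and name in src and tgt[name].shape == src[name].shape:
            tgt[name][...] = src[name]
            copied += 1
        elif policy == "strict":
            raise ValueError(
                f"strict warm start: tensor {name!r} missing or shape-mismatched "
                f"between source and target architectures"
            )
    return out, copied / len(names)


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: BiLSTMModel, path: Path) -> None:
    """Save a checkpoint: binary array container plus JSON metadata."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.parameters())
    meta = {
        "classes": list(model.classes),
        "hyper": model.hyper,
        "mode": model.forward_cell.mode,
        "hidden": model.hidden,
        "input_dim": model.forward_cell.input_dim,
        "activation": model.forward_cell.activation,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path: Path) -> BiLSTMModel:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    model = init_model(
        meta["hyper"], meta["classes"], n_channels=meta["input_dim"],
        seed=0, mode=meta["mode"],
    )
    with np.load(path.with_suffix(".npz")) as arc:
        for name, tensor in model.parameters().items():
            tensor[...] = arc[name]
    return model


# ---------------------------------------------------------------------------
# scikit-learn estimator


class BiLSTMClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style wrapper around the numpy BiLSTM.

    Parameters mirror the discrete hyperparameter space used for
    architecture search: hidden width, learning rate, epochs, batch size,
    optimizer (``"Adam"`` or ``"SGD"``) and candidate activation
    (``"tanh"`` or ``"ReLU"``).

    ``X`` is a 3-D array ``(n_windows, window_len, n_channels)``; ``y`` is
    a label vector.  Fitted attributes: ``classes_``, ``model_``,
    ``history_``.
    """

    def __init__(
        self,
        n_neurons: int = 20,
        learning_rate: float = 1e-3,
        n_epochs: int = 50,
        batch_size: int = 32,
        optimizer: str = "Adam",
        activation: str = "tanh",
        cell_mode: str = "standard",
        random_state: int = 0,
    ):
        self.n_neurons = n_neurons
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.activation = activation
        self.cell_mode = cell_mode
        self.random_state = random_state

    def _hyper(self) -> Dict[str, object]:
        return {
            "n_neurons": self.n_neurons,
            "learning_rate": self.learning_rate,
            "n_epochs": self.n_epochs,
            "batch_size": self.batch_size,
            "optimizer": self.optimizer,
            "activation": self.activation,
        }

    def fit(self, X, y, init: Optional[BiLSTMModel] = None) -> "BiLSTMClassifier":
        """Fit on windows X (n, l, channels); ``init`` warm-starts weights."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError(f"X must be 3-D (n, window_len, channels), got {X.shape}")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        self.classes_ = np.unique(y.astype(str))
        model = init_model(
            self._hyper(),
            classes=list(self.classes_),
            n_channels=X.shape[2],
            seed=self.random_state,
            mode=self.cell_mode,
        )
        if init is not None:
            model, self.warm_fraction_ = warm_start(model, init, policy="compatible_only")
        self.model_, self.history_ = train(model, (X, y), seed=self.random_state)
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return predict_proba(self.model_, np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted; call fit first")
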