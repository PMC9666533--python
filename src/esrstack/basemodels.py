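"""Base forecasters: MLP, LSTM and GRU mapping a truncated window to the ESR.

Each model takes the normalized column heights sampled every 0.5 min on
[0, L] minutes (2L+1 values, L=15 by default) and regresses the 60-min value.
The MLP sees the window as a flat vector through two hidden layers (15 and 10
neurons); the LSTM and GRU consume it as a univariate sequence through one
recurrent layer of 15 units whose final hidden state feeds a single linear
output neuron.

The recurrent cells follow the standard gate equations —

LSTM:  i_t = sigma(W_i1 x_t + W_i2 h_{t-1} + b_i)      (input gate)
       o_t = sigma(W_o1 x_t + W_o2 h_{t-1} + b_o)      (output gate)
       f_t = sigma(W_f1 x_t + W_f2 h_{t-1} + b_f)      (forget gate)
       c_t = f_t*c_{t-1} + i_t*tanh(W_c1 x_t + W_c2 h_{t-1} + b_c)
       h_t = o_t*tanh(c_t)

GRU:   g_t = sigma(W_z1 x_t + W_z2 h_{t-1} + b_z)      (update gate)
       r_t = sigma(W_r1 x_t + W_r2 h_{t-1} + b_r)      (reset gate)
       hcand_t = tanh(W_h1 x_t + W_h2 (r_t*h_{t-1}) + b_h)
       h_t = (1-g_t)*h_{t-1} + g_t*hcand_t

— with * the elementwise product.  Gate weight matrices are stored fused
(gates stacked column-wise) for speed; per-gate views are exposed under the
standard names above.  Training is full backprop(-through-time) with Adam, an
exponentially decayed learning rate, MSE loss and early stopping on the
validation loss, all driven by a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from esrstack.synth import SedimentationCurve, TIME_STEP_MIN

#: window lengths (minutes) used in the sequence-length selection sweep
STANDARD_LENGTHS = (5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)

MODEL_KINDS = ("MLP", "LSTM", "GRU")


class TrainingError(RuntimeError):
    pass


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x, a: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x, a: 1.0 - a * a),
    "identity": (lambda x: x, lambda x, a: np.ones_like(x)),
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Network family and layer sizes.

    Defaults: MLP hidden [15, 10]; LSTM/GRU hidden [15]; one linear output.
    ``activation`` applies to MLP hidden layers only (rectifier by default).
    """

    kind: str
    hidden_sizes: tuple[int, ...] | None = None
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")
        if self.hidden_sizes is None:
            default = (15, 10) if self.kind == "MLP" else (15,)
            object.__setattr__(self, "hidden_sizes", default)
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.kind in ("LSTM", "GRU") and len(self.hidden_sizes) != 1:
            raise ValueError(f"{self.kind} uses a single recurrent layer")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: Adam + exponential LR decay + early stopping."""

    max_epochs: int = 300
    patience: int = 15
    initial_lr: float = 1e-2
    decay_rate: float = 0.96
    decay_steps: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("patience must be positive and below max_epochs")
        if self.initial_lr <= 0 or self.decay_rate <= 0 or self.decay_steps <= 0:
            raise ValueError("learning-rate schedule parameters must be positive")

    def lr_at(self, step: int) -> float:
        return self.initial_lr * self.decay_rate ** (step / self.decay_steps)


# ---------------------------------------------------------------------------
# windows

@dataclass
class WindowSet:
    """Supervised samples: input window h(0..L) -> target h(60)."""

    X: np.ndarray           # (n, 2L+1)
    y: np.ndarray           # (n,)
    sample_ids: list[str]
    length_min: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != self.y.size or self.X.shape[0] != len(self.sample_ids):
            raise ValueError("X, y and sample_ids must agree in length")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(
            self.X[idx], self.y[idx], [self.sample_ids[i] for i in idx], self.length_min
        )


def make_windows(
    curves: list[SedimentationCurve], length_min: float, allow_any_length: bool = False
) -> WindowSet:
    """Truncate each curve to [0, L] minutes; target is the final (60-min) value.

    L must be one of the standard sweep lengths {5, 7.5, ..., 20} unless
    ``allow_any_length`` is set (L=60 then degenerates to target==last input).
    """
    if not allow_any_length and length_min not in STANDARD_LENGTHS:
        raise ValueError(
            f"length_min={length_min} not in standard set {STANDARD_LENGTHS}; "
            "pass allow_any_length=True to override"
        )
    n_in = int(round(length_min / TIME_STEP_MIN)) + 1
    X_rows, y_vals, ids = [], [], []
    for c in curves:
        if c.times.size < n_in:
            raise ValueError(f"curve {c.sample_id} shorter than window {length_min} min")
        X_rows.append(c.h_ratio[:n_in])
        y_vals.append(c.h_ratio[-1])
        ids.append(c.sample_id)
    X = np.array(X_rows) if X_rows else np.empty((0, n_in))
    return WindowSet(X, np.array(y_vals), ids, length_min)


# ---------------------------------------------------------------------------
# weights

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class MLPNet:
    def __init__(self, spec: ArchitectureSpec, n_inputs: int, rng: np.random.Generator):
        self.spec = spec
        self.n_inputs = n_inputs
        sizes = [n_inputs, *spec.hidden_sizes, 1]
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            self.weights.append(_glorot(rng, fan_in, fan_out, (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.act, self.act_grad = ACTIVATIONS[spec.activation]

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = self.act(a @ W + b)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()

    def loss_grads(self, X: np.ndarray, y: np.ndarray):
        n = X.shape[0]
        acts = [X]
        pre = []
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            z = a @ W + b
            a = self.act(z)
            pre.append(z)
            acts.append(a)
        out = (a @ self.weights[-1] + self.biases[-1]).ravel()
        resid = out - y
        loss = float(np.mean(resid**2))
        delta = (2.0 * resid / n)[:, None]
        gW = [np.empty_like(W) for W in self.weights]
        gb = [np.empty_like(b) for b in self.biases]
        gW[-1] = acts[-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        d = delta @ self.weights[-1].T
        for i in range(len(self.weights) - 2, -1, -1):
            d = d * self.act_grad(pre[i], acts[i + 1])
            gW[i] = acts[i].T @ d
            gb[i] = d.sum(axis=0)
            if i > 0:
                d = d @ self.weights[i].T
        return loss, [*gW, *gb]


@dataclass
class LSTMWeights:
    """Fused LSTM weights; gate order along columns is [i | o | f | c]."""

    Wx: np.ndarray   # (n_in, 4H)
    Wh: np.ndarray   # (H, 4H)
    b: np.ndarray    # (4H,)

    @property
    def hidden(self) -> int:
        return self.Wh.shape[0]

    def _blk(self, j):
        H = self.hidden
        return slice(j * H, (j + 1) * H)

    # per-gate views under the standard equation names
    @property
    def W_i1(self): return self.Wx[:, self._blk(0)]
    @property
    def W_o1(self): return self.Wx[:, self._blk(1)]
    @property
    def W_f1(self): return self.Wx[:, self._blk(2)]
    @property
    def W_c1(self): return self.Wx[:, self._blk(3)]
    @property
    def W_i2(self): return self.Wh[:, self._blk(0)]
    @property
    def W_o2(self): return self.Wh[:, self._blk(1)]
    @property
    def W_f2(self): return self.Wh[:, self._blk(2)]
    @property
    def W_c2(self): return self.Wh[:, self._blk(3)]
    @property
    def b_i(self): return self.b[self._blk(0)]
    @property
    def b_o(self): return self.b[self._blk(1)]
    @property
    def b_f(self): return self.b[self._blk(2)]
    @property
    def b_c(self): return self.b[self._blk(3)]


@dataclass
class GRUWeights:
    """Fused GRU weights; gate order is [g (update) | r (reset)] plus candidate."""

    Wx_gr: np.ndarray  # (n_in, 2H)
    Wh_gr: np.ndarray  # (H, 2H)
    b_gr: np.ndarray   # (2H,)
    Wx_c: np.ndarray   # (n_in, H)
    Wh_c: np.ndarray   # (H, H)
    b_c: np.ndarray    # (H,)

    @property
    def hidden(self) -> int:
        return self.Wh_c.shape[0]

    def _blk(self, j):
        H = self.hidden
        return slice(j * H, (j + 1) * H)

    @property
    def W_z1(self): return self.Wx_gr[:, self._blk(0)]
    @property
    def W_r1(self): return self.Wx_gr[:, self._blk(1)]
    @property
    def W_z2(self): return self.Wh_gr[:, self._blk(0)]
    @property
    def W_r2(self): return self.Wh_gr[:, self._blk(1)]
    @property
    def b_z(self): return self.b_gr[self._blk(0)]
    @property
    def b_r(self): return self.b_gr[self._blk(1)]
    @property
    def W_h1(self): return self.Wx_c
    @property
    def W_h2(self): return self.Wh_c
    @property
    def b_h(self): return self.b_c


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray
    i: np.ndarray | None = None
    o: np.ndarray | None = None
    f: np.ndarray | None = None
    c_cand: np.ndarray | None = None


@dataclass
class GRUState:
    h: np.ndarray
    g: np.ndarray | None = None
    r: np.ndarray | None = None
    h_cand: np.ndarray | None = None


def lstm_step(state: LSTMState, weights: LSTMWeights, x_t: np.ndarray) -> LSTMState:
    """One LSTM update; gates evaluated in the order i, o, f, then c and h."""
    H = weights.hidden
    a = x_t @ weights.Wx + state.h @ weights.Wh + weights.b
    i = _sigmoid(a[..., 0 * H : 1 * H])
    o = _sigmoid(a[..., 1 * H : 2 * H])
    f = _sigmoid(a[..., 2 * H : 3 * H])
    c_cand = np.tanh(a[..., 3 * H : 4 * H])
    c = f * state.c + i * c_cand
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c, i=i, o=o, f=f, c_cand=c_cand)


def gru_step(state: GRUState, weights: GRUWeights, x_t: np.ndarray) -> GRUState:
    """One GRU update; reset gate multiplies h_{t-1} inside the candidate."""
    H = weights.hidden
    a = x_t @ weights.Wx_gr + state.h @ weights.Wh_gr + weights.b_gr
    g = _sigmoid(a[..., :H])
    r = _sigmoid(a[..., H:])
    h_cand = np.tanh(x_t @ weights.Wx_c + (r * state.h) @ weights.Wh_c + weights.b_c)
    h = (1.0 - g) * state.h + g * h_cand
    return GRUState(h=h, g=g, r=r, h_cand=h_cand)


def mlp_forward(net: "MLPNet", X: np.ndarray) -> np.ndarray:
    """Forward pass of the MLP on a batch of flattened windows."""
    return net.forward(np.atleast_2d(X))


class LSTMNet:
    def __init__(self, spec: ArchitectureSpec, n_inputs: int, rng: np.random.Generator):
        self.spec = spec
        self.n_inputs = n_inputs  # sequence length; input is univariate
        H = spec.hidden_sizes[0]
        self.cell = LSTMWeights(
            Wx=_glorot(rng, 1, H, (1, 4 * H)),
            Wh=_glorot(rng, H, H, (H, 4 * H)),
            b=np.zeros(4 * H),
        )
        self.Wy = _glorot(rng, H, 1, (H, 1))
        self.by = np.zeros(1)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.cell.Wx, self.cell.Wh, self.cell.b, self.Wy, self.by]

    def _run(self, X: np.ndarray, keep_cache: bool):
        n, T = X.shape
        H = self.cell.hidden
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        cache = []
        for t in range(T):
            x_t = X[:, t : t + 1]
            state = lstm_step(LSTMState(h=h, c=c), self.cell, x_t)
            if keep_cache:
                cache.append((x_t, h, c, state))
            h, c = state.h, state.c
        pred = (h @ self.Wy + self.by).ravel()
        return pred, h, cache

    def forward(self, X: np.ndarray) -> np.ndarray:
        return self._run(np.atleast_2d(X), keep_cache=False)[0]

    def loss_grads(self, X: np.ndarray, y: np.ndarray):
        n, T = X.shape
        H = self.cell.hidden
        pred, h_T, cache = self._run(X, keep_cache=True)
        resid = pred - y
        loss = float(np.mean(resid**2))
        dpred = (2.0 * resid / n)[:, None]
        gWy = h_T.T @ dpred
        gby = dpred.sum(axis=0)
        gWx = np.zeros_like(self.cell.Wx)
        gWh = np.zeros_like(self.cell.Wh)
        gb = np.zeros_like(self.cell.b)
        dh = dpred @ self.Wy.T
        dc = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, st = cache[t]
            tanh_c = np.tanh(st.c)
            c_cand = st.c_cand
            dc = dc + dh * st.o * (1.0 - tanh_c**2)
            da_o = (dh * tanh_c) * st.o * (1.0 - st.o)
            da_f = (dc * c_prev) * st.f * (1.0 - st.f)
            da_i = (dc * c_cand) * st.i * (1.0 - st.i)
            da_c = (dc * st.i) * (1.0 - c_cand**2)
            da = np.concatenate([da_i, da_o, da_f, da_c], axis=1)
            gWx += x_t.T @ da
            gWh += h_prev.T @ da
            gb += da.sum(axis=0)
            dh = da @ self.cell.Wh.T
            dc = dc * st.f
        return loss, [gWx, gWh, gb, gWy, gby]


class GRUNet:
    def __init__(self, spec: ArchitectureSpec, n_inputs: int, rng: np.random.Generator):
        self.spec = spec
        self.n_inputs = n_inputs
        H = spec.hidden_sizes[0]
        self.cell = GRUWeights(
            Wx_gr=_glorot(rng, 1, H, (1, 2 * H)),
            Wh_gr=_glorot(rng, H, H, (H, 2 * H)),
            b_gr=np.zeros(2 * H),
            Wx_c=_glorot(rng, 1, H, (1, H)),
            Wh_c=_glorot(rng, H, H, (H, H)),
            b_c=np.zeros(H),
        )
        self.Wy = _glorot(rng, H, 1, (H, 1))
        self.by = np.zeros(1)

    @property
    def params(self) -> list[np.ndarray]:
        c = self.cell
        return [c.Wx_gr, c.Wh_gr, c.b_gr, c.Wx_c, c.Wh_c, c.b_c, self.Wy, self.by]

    def _run(self, X: np.ndarray, keep_cache: bool):
        n, T = X.shape
        H = self.cell.hidden
        h = np.zeros((n, H))
        cache = []
        for t in range(T):
            x_t = X[:, t : t + 1]
            state = gru_step(GRUState(h=h), self.cell, x_t)
            if keep_cache:
                cache.append((x_t, h, state))
            h = state.h
        pred = (h @ self.Wy + self.by).ravel()
        return pred, h, cache

    def forward(self, X: np.ndarray) -> np.ndarray:
        return self._run(np.atleast_2d(X), keep_cache=False)[0]

    def loss_grads(self, X: np.ndarray, y: np.ndarray):
        n, T = X.shape
        pred, h_T, cache = self._run(X, keep_cache=True)
        resid = pred - y
        loss = float(np.mean(resid**2))
        dpred = (2.0 * resid / n)[:, None]
        gWy = h_T.T @ dpred
        gby = dpred.sum(axis=0)
        c = self.cell
        gWx_gr = np.zeros_like(c.Wx_gr)
        gWh_gr = np.zeros_like(c.Wh_gr)
        gb_gr = np.zeros_like(c.b_gr)
        gWx_c = np.zeros_like(c.Wx_c)
        gWh_c = np.zeros_like(c.Wh_c)
        gb_c = np.zeros_like(c.b_c)
        dh = dpred @ self.Wy.T
        for t in range(T - 1, -1, -1):
            x_t, h_prev, st = cache[t]
            da_g = (dh * (st.h_cand - h_prev)) * st.g * (1.0 - st.g)
            da_c = (dh * st.g) * (1.0 - st.h_cand**2)
            drh = da_c @ c.Wh_c.T
            da_r = (drh * h_prev) * st.r * (1.0 - st.r)
            da_gr = np.concatenate([da_g, da_r], axis=1)
            gWx_gr += x_t.T @ da_gr
            gWh_gr += h_prev.T @ da_gr
            gb_gr += da_gr.sum(axis=0)
            gWx_c += x_t.T @ da_c
            gWh_c += (st.r * h_prev).T @ da_c
            gb_c += da_c.sum(axis=0)
            dh = dh * (1.0 - st.g) + da_gr @ c.Wh_gr.T + drh * st.r
        return loss, [gWx_gr, gWh_gr, gb_gr, gWx_c, gWh_c, gb_c, gWy, gby]


_NET_CLASSES = {"MLP": MLPNet, "LSTM": LSTMNet, "GRU": GRUNet}


def build_net(spec: ArchitectureSpec, n_inputs: int, seed: int):
    rng = np.random.default_rng(seed)
    return _NET_CLASSES[spec.kind](spec, n_inputs, rng)


# ---------------------------------------------------------------------------
# training

class _Adam:
    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


@dataclass
class TrainedModel:
    net: object
    spec: ArchitectureSpec
    config: TrainConfig
    length_min: float
    log: pd.DataFrame
    best_epoch: int

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def train_model(
    spec: ArchitectureSpec,
    config: TrainConfig,
    train: WindowSet,
    val: WindowSet,
) -> TrainedModel:
    """Fit one base model under the standard protocol.

    Adam on minibatch MSE, exponentially decayed learning rate, at most
    ``max_epochs`` epochs, early stop after ``patience`` epochs without
    validation improvement, best-validation weights restored.  Deterministic
    given ``config.seed``.
    """
    if train.n == 0 or val.n == 0:
        raise TrainingError("empty training or validation set")
    if train.X.shape[1] != val.X.shape[1]:
        raise TrainingError("train/val window lengths differ")
    rng = np.random.default_rng(config.seed)
    net = _NET_CLASSES[spec.kind](spec, train.X.shape[1], rng)
    opt = _Adam(net.params)
    best_val = np.inf
    best_params = None
    best_epoch = 0
    stall = 0
    rows = []
    step = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(train.n)
        epoch_losses = []
        for start in range(0, train.n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = net.loss_grads(train.X[idx], train.y[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(kind={spec.kind}, seed={config.seed}, lr={config.lr_at(step):.3g})"
                )
            opt.step(net.params, grads, config.lr_at(step))
            step += 1
            epoch_losses.append(loss)
        val_pred = net.forward(val.X)
        val_loss = float(np.mean((val_pred - val.y) ** 2))
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "lr": config.lr_at(step),
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = [p.copy() for p in net.params]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    if best_params is not None:
        for p, bp in zip(net.params, best_params):
            p[...] = bp
    log = pd.DataFrame(rows)
    return TrainedModel(
        net=net, spec=spec, config=config,
        length_min=train.length_min, log=log, best_epoch=best_epoch,
    )


def predict(model: TrainedModel, X) -> np.ndarray:
    """Forecast ESR values for windows ``X`` ((n, 2L+1) array or WindowSet)."""
    if isinstance(X, WindowSet):
        X = X.X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.net.n_inputs:
        raise ValueError(
            f"window length {X.shape[1]} does not match training length {model.net.n_inputs}"
        )
    return model.net.forward(X)


# ---------------------------------------------------------------------------
# framework-agnostic weight dump

def weights_to_dict(model: TrainedModel) -> dict:
    net = model.net
    out: dict = {"kind": model.spec.kind, "length_min": model.length_min}
    if isinstance(net, MLPNet):
        for i, (W, b) in enumerate(zip(net.weights, net.biases)):
            out[f"W{i}"] = W.tolist()
            out[f"b{i}"] = b.tolist()
    elif isinstance(net, LSTMNet):
        cw = net.cell
        for name in ("W_i1", "W_i2", "b_i", "W_o1", "W_o2", "b_o",
                     "W_f1", "W_f2", "b_f", "W_c1", "W_c2", "b_c"):
            out[name] = np.asarray(getattr(cw, name)).tolist()
        out["W_y"] = net.Wy.tolist()
        out["b_y"] = net.by.tolist()
    elif isinstance(net, GRUNet):
        cw = net.cell
        for name in ("W_z1", "W_z2", "b_z", "W_r1", "W_r2", "b_r",
                     "W_h1", "W_h2", "b_h"):
            out[name] = np.asarray(getattr(cw, name)).tolist()
        out["W_y"] = net.Wy.tolist()
        out["b_y"] = net.by.tolist()
    return out


def save_weights_json(model: TrainedModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(weights_to_dict(model), fh)
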