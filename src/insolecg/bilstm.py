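"""Minimal numpy implementation of bidirectional LSTM sequence regression.

This module provides the recurrent machinery used by the center-of-gravity
trajectory models: a masked LSTM layer with exact backpropagation through
time, a bidirectional wrapper, a per-frame affine prediction head with
sigmoid activation, the Adam optimizer, and a training loop with
plateau-based learning-rate reduction and early stopping.

Conventions
-----------
* Sequences are ``(T, B, C)`` arrays: time-major, batch second.
* Masks are ``(T, B)`` float arrays in {0, 1}; a masked step is an identity
  update (hidden and cell state carry through unchanged), so right-padded
  and left-padded sequences are both handled exactly.
* Gate order in the fused weight matrices is ``(i, f, o, g)`` so one
  sigmoid call covers the first three gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


__all__ = [
    "LSTMCellParams",
    "BiLSTMLayer",
    "SigmoidDense",
    "Adam",
    "TrainingHistory",
    "fit_model",
]


@njit(cache=True)
def _forward_core(Zx, U, mask, Hs, Cs, gates):
    """Time loop of one directional LSTM; fills Hs, Cs, gates in place."""
    T, B, H4 = Zx.shape
    H = H4 // 4
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        z = Zx[t] + np.dot(h, U)
        sig = 1.0 / (1.0 + np.exp(-z[:, : 3 * H]))
        g = np.tanh(z[:, 3 * H :])
        i = sig[:, :H]
        f = sig[:, H : 2 * H]
        o = sig[:, 2 * H : 3 * H]
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        for b in range(B):
            if mask[t, b] != 0.0:
                h[b, :] = h_new[b, :]
                c[b, :] = c_new[b, :]
        Hs[t] = h
        Cs[t] = c
        gates[t, :, : 3 * H] = sig
        gates[t, :, 3 * H :] = g


@njit(cache=True)
def _backward_core(dH, UT, mask, Cs, gates, dZ):
    """Reverse time loop of BPTT; fills the fused gate gradients dZ."""
    T, B, H = dH.shape
    dh_carry = np.zeros((B, H))
    dc_carry = np.zeros((B, H))
    zeros = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i = gates[t, :, :H]
        f = gates[t, :, H : 2 * H]
        o = gates[t, :, 2 * H : 3 * H]
        g = gates[t, :, 3 * H :]
        tc = np.tanh(Cs[t])
        if t > 0:
            c_prev = Cs[t - 1]
        else:
            c_prev = zeros
        dh_total = dH[t] + dh_carry
        dc_total = dc_carry
        dz = dZ[t]
        dh_pass = np.zeros((B, H))
        dc_pass = np.zeros((B, H))
        for b in range(B):
            if mask[t, b] == 0.0:
                # masked step is an identity update: gradients pass through
                dh_pass[b, :] = dh_total[b, :]
                dc_pass[b, :] = dc_total[b, :]
                dh_total[b, :] = 0.0
                dc_total[b, :] = 0.0
        dc_tot = dc_total + dh_total * o * (1.0 - tc * tc)
        dz[:, :H] = dc_tot * g * i * (1.0 - i)
        dz[:, H : 2 * H] = dc_tot * c_prev * f * (1.0 - f)
        dz[:, 2 * H : 3 * H] = dh_total * tc * o * (1.0 - o)
        dz[:, 3 * H :] = dc_tot * i * (1.0 - g * g)
        dh_carry = np.dot(np.ascontiguousarray(dz), UT) + dh_pass
        dc_carry = dc_tot * f + dc_pass


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMCellParams:
    """Fused weights of one directional LSTM: ``z = x W + h U + b``."""

    W: np.ndarray  # (input_dim, 4H)
    U: np.ndarray  # (H, 4H)
    b: np.ndarray  # (4H,)

    @classmethod
    def init(cls, rng: np.random.Generator, input_dim: int, hidden: int) -> "LSTMCellParams":
        # Glorot-uniform input weights, orthogonal recurrent weights,
        # forget-gate bias 1 (standard LSTM initialization practice).
        limit = np.sqrt(6.0 / (input_dim + 4 * hidden))
        W = rng.uniform(-limit, limit, size=(input_dim, 4 * hidden))
        U = np.concatenate(
            [_orthogonal(rng, hidden) for _ in range(4)], axis=1
        )
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        return cls(W=W, U=U, b=b)

    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class _DirectionalLSTM:
    """One direction of an LSTM over a (possibly masked) sequence."""

    def __init__(self, params: LSTMCellParams):
        self.p = params
        self._cache = None

    def forward(self, X: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
        T, B, _ = X.shape
        H = self.p.U.shape[0]
        Zx = np.ascontiguousarray(X @ self.p.W + self.p.b)
        if mask is None:
            mask_arr = np.ones((T, B))
        else:
            mask_arr = np.ascontiguousarray(mask)
        Hs = np.empty((T, B, H))
        Cs = np.empty((T, B, H))
        gates = np.empty((T, B, 4 * H))
        _forward_core(Zx, self.p.U, mask_arr, Hs, Cs, gates)
        self._cache = (X, mask_arr, Hs, Cs, gates)
        return Hs

    def backward(self, dH: np.ndarray):
        X, mask_arr, Hs, Cs, gates = self._cache
        T, B, _ = X.shape
        H = self.p.U.shape[0]
        dZ = np.empty((T, B, 4 * H))
        _backward_core(
            np.ascontiguousarray(dH),
            np.ascontiguousarray(self.p.U.T),
            mask_arr,
            Cs,
            gates,
            dZ,
        )
        X2 = X.reshape(T * B, -1)
        dZ2 = dZ.reshape(T * B, 4 * H)
        Hprev = np.concatenate([np.zeros((1, B, H)), Hs[:-1]], axis=0)
        dW = X2.T @ dZ2
        dU = Hprev.reshape(T * B, H).T @ dZ2
        db = dZ2.sum(axis=0)
        dX = (dZ2 @ self.p.W.T).reshape(X.shape)
        self._cache = None
        return dX, [dW, dU, db]


class BiLSTMLayer:
    """Bidirectional LSTM: concatenated forward/backward hidden states."""

    def __init__(self, rng: np.random.Generator, input_dim: int, units: int):
        self.units = units
        self.fwd = _DirectionalLSTM(LSTMCellParams.init(rng, input_dim, units))
        self.bwd = _DirectionalLSTM(LSTMCellParams.init(rng, input_dim, units))

    @property
    def output_dim(self) -> int:
        return 2 * self.units

    def params(self) -> list[np.ndarray]:
        return self.fwd.p.params() + self.bwd.p.params()

    def forward(self, X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        Hf = self.fwd.forward(X, mask)
        rmask = mask[::-1] if mask is not None else None
        Hb = self.bwd.forward(X[::-1], rmask)[::-1]
        return np.concatenate([Hf, Hb], axis=2)

    def backward(self, dOut: np.ndarray):
        H = self.units
        dXf, gf = self.fwd.backward(dOut[:, :, :H])
        dXb_rev, gb = self.bwd.backward(dOut[::-1, :, H:])
        return dXf + dXb_rev[::-1], gf + gb


class SigmoidDense:
    """Per-frame affine map with sigmoid activation (the prediction head)."""

    def __init__(self, rng: np.random.Generator, input_dim: int, n_out: int):
        limit = np.sqrt(6.0 / (input_dim + n_out))
        self.W = rng.uniform(-limit, limit, size=(input_dim, n_out))
        self.b = np.zeros(n_out)
        self._cache = None

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        Y = _sigmoid(X @ self.W + self.b)
        self._cache = (X, Y)
        return Y

    def backward(self, dY: np.ndarray):
        X, Y = self._cache
        dZ = dY * Y * (1.0 - Y)
        T, B, _ = X.shape
        X2 = X.reshape(T * B, -1)
        dZ2 = dZ.reshape(T * B, -1)
        dW = X2.T @ dZ2
        db = dZ2.sum(axis=0)
        dX = (dZ2 @ self.W.T).reshape(X.shape)
        self._cache = None
        return dX, [dW, db]


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


@dataclass
class TrainingHistory:
    """Per-epoch record of a training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0
    best_val_loss: float = np.inf


def fit_model(
    model,
    train_data,
    val_data,
    seed: int,
    *,
    batch_size: int = 10,
    learning_rate: float = 1e-3,
    max_epochs: int = 1000,
    plateau_patience: int = 20,
    plateau_factor: float = 0.5,
    min_lr: float = 1e-5,
    early_stop_patience: int = 50,
) -> TrainingHistory:
    """Train ``model`` by mini-batch Adam on mean-squared-error loss.

    ``model`` must expose ``n_samples(data)``, ``loss_and_grads(data,
    indices) -> (loss, grads)``, ``evaluate(data) -> loss``, ``get_params()``
    and ``set_params()``.  Learning rate is halved when the validation loss
    plateaus and training stops early when it fails to improve for
    ``early_stop_patience`` epochs; the best-epoch weights are restored.
    """
    rng = np.random.default_rng(seed)
    n = model.n_samples(train_data)
    opt = Adam(model.param_arrays(), lr=learning_rate)
    hist = TrainingHistory()
    best_weights = [p.copy() for p in model.param_arrays()]
    plateau_wait = 0
    stop_wait = 0
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss, grads = model.loss_and_grads(train_data, idx)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; diverged"
                )
            opt.step(grads)
            epoch_loss += loss * len(idx)
        hist.train_loss.append(epoch_loss / n)
        vloss = model.evaluate(val_data)
        hist.val_loss.append(vloss)
        hist.lr.append(opt.lr)
        if vloss < hist.best_val_loss - 1e-12:
            hist.best_val_loss = vloss
            hist.best_epoch = epoch
            best_weights = [p.copy() for p in model.param_arrays()]
            plateau_wait = 0
            stop_wait = 0
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait >= plateau_patience:
                opt.lr = max(opt.lr * plateau_factor, min_lr)
                plateau_wait = 0
            if stop_wait >= early_stop_patience:
                hist.stop_epoch = epoch + 1
                break
    else:
        hist.stop_epoch = max_epochs
    if hist.stop_epoch == 0:
        hist.stop_epoch = max_epochs
    for p, best in zip(model.param_arrays(), best_weights):
        p[...] = best
    return hist
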