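"""Minimal numpy neural-network core for the recurrent attention classifier.

Implements exactly the layers the classifier stack needs — unidirectional
LSTM passes composed into a bi-LSTM, masked batch normalization, a
time-distributed dense layer, additive attention, and a sigmoid head — with
hand-written backpropagation and an ADAM optimizer.  Everything runs in
float64 on (batch, time, feature) arrays with a boolean validity mask;
padded time steps are always trailing and are excluded from normalization
statistics, attention weights and the loss, so padded and unpadded forward
passes of the same sequence agree to numerical precision.

Gradient correctness is enforced by finite-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Param",
    "Adam",
    "LSTMDirection",
    "BiLSTM",
    "MaskedBatchNorm",
    "TimeDistributedDense",
    "AdditiveAttention",
    "SigmoidHead",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    z = np.asarray(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy and d(loss)/d(logits)."""
    z = np.asarray(logits, dtype=float)
    y = np.asarray(y, dtype=float)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / len(y)
    return loss, dz


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    m: np.ndarray = field(init=False)
    v: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        lr = self.lr * math.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        for p in self.params:
            p.m = self.beta1 * p.m + (1 - self.beta1) * p.grad
            p.v = self.beta2 * p.v + (1 - self.beta2) * p.grad**2
            p.value -= lr * p.m / (np.sqrt(p.v) + self.eps)


def _glorot(rng, shape):
    fan_in, fan_out = shape[0], shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class LSTMDirection:
    """A single forward-direction LSTM pass over (B, T, F) input.

    Gate layout along the last axis of the fused weight matrices is
    (input, forget, cell, output).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        H = n_hidden
        self.H = H
        self.Wx = Param(_glorot(rng, (n_in, 4 * H)))
        self.Wh = Param(_glorot(rng, (H, 4 * H)))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        self.b = Param(b)
        self._cache = None

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        out = np.zeros((B, T, H))
        steps = []
        for t in range(T):
            a = X[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t] = h
        self._cache = (X, steps)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        X, steps = self._cache
        B, T, _ = X.shape
        H = self.H
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = steps[t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.Wx.grad += X[:, t].T @ da
            self.Wh.grad += h_prev.T @ da
            self.b.grad += da.sum(axis=0)
            dX[:, t] = da @ self.Wx.value.T
            dh_next = da @ self.Wh.value.T
            dc_next = dc * f
        return dX


def _reversal_index(mask: np.ndarray) -> np.ndarray:
    """Per-row index that reverses the valid prefix and fixes the padding."""
    B, T = mask.shape
    lengths = mask.sum(axis=1).astype(int)
    idx = np.tile(np.arange(T), (B, 1))
    for b in range(B):
        n = lengths[b]
        idx[b, :n] = np.arange(n - 1, -1, -1)
    return idx


class BiLSTM:
    """Bidirectional LSTM: forward pass plus a pass over the reversed valid
    prefix of each sequence, concatenated along the feature axis."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.fwd = LSTMDirection(n_in, n_hidden, rng)
        self.bwd = LSTMDirection(n_in, n_hidden, rng)
        self._rev = None

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        rev = _reversal_index(mask)
        self._rev = rev
        rows = np.arange(X.shape[0])[:, None]
        out_f = self.fwd.forward(X)
        out_b = self.bwd.forward(X[rows, rev])[rows, rev]
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.fwd.H
        rev = self._rev
        rows = np.arange(dout.shape[0])[:, None]
        dX = self.fwd.backward(dout[:, :, :H])
        dXb = self.bwd.backward(dout[:, :, H:][rows, rev])
        dX += dXb[rows, rev]
        return dX


class MaskedBatchNorm:
    """Batch normalization over all valid (batch, time) positions.

    Uses batch statistics in training mode (updating running statistics
    with the configured momentum) and running statistics at inference.
    """

    def __init__(self, n_features: int, momentum: float = 0.99, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, X: np.ndarray, mask: np.ndarray, train: bool) -> np.ndarray:
        m = mask[:, :, None].astype(float)
        if train:
            N = m.sum()
            mean = (X * m).sum(axis=(0, 1)) / N
            var = (((X - mean) ** 2) * m).sum(axis=(0, 1)) / N
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            N, mean, var = None, self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (X - mean) * inv * m
        out = (self.gamma.value * xhat + self.beta.value) * m
        self._cache = (xhat, inv, m, N, train)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, m, N, train = self._cache
        dout = dout * m
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1))
        self.beta.grad += dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma.value
        if not train:
            return dxhat * inv * m
        sum_dxhat = dxhat.sum(axis=(0, 1))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1))
        dX = (inv / N) * (N * dxhat - sum_dxhat - xhat * sum_dxhat_xhat) * m
        return dX


class TimeDistributedDense:
    """Shared dense layer applied independently at every time step (tanh)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        out = np.tanh(X @ self.W.value + self.b.value)
        self._cache = (X, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        X, out = self._cache
        dpre = dout * (1 - out**2)
        self.W.grad += np.einsum("bti,btj->ij", X, dpre)
        self.b.grad += dpre.sum(axis=(0, 1))
        return dpre @ self.W.value.T


class AdditiveAttention:
    """Additive (tanh-projection) attention pooling over time.

    score_t = v . tanh(Wa x_t + ba); weights are a masked softmax over the
    valid steps; output is the weighted sum of the inputs.
    """

    def __init__(self, n_in: int, attention_dim: int, rng: np.random.Generator):
        self.Wa = Param(_glorot(rng, (n_in, attention_dim)))
        self.ba = Param(np.zeros(attention_dim))
        self.v = Param(_glorot(rng, (attention_dim, 1))[:, 0])
        self._cache = None

    def params(self):
        return [self.Wa, self.ba, self.v]

    def forward(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        u = np.tanh(X @ self.Wa.value + self.ba.value)
        s = u @ self.v.value
        s = np.where(mask, s, -np.inf)
        s_max = s.max(axis=1, keepdims=True)
        e = np.exp(s - s_max) * mask
        alpha = e / e.sum(axis=1, keepdims=True)
        ctx = np.einsum("bt,btf->bf", alpha, X)
        self._cache = (X, u, alpha, mask)
        return ctx

    @property
    def last_weights(self) -> np.ndarray:
        return self._cache[2]

    def backward(self, dctx: np.ndarray) -> np.ndarray:
        X, u, alpha, mask = self._cache
        dX = alpha[:, :, None] * dctx[:, None, :]
        dalpha = np.einsum("bf,btf->bt", dctx, X)
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        ds = ds * mask
        du = ds[:, :, None] * self.v.value
        dpre = du * (1 - u**2)
        self.v.grad += np.einsum("bt,bta->a", ds, u)
        self.Wa.grad += np.einsum("bti,bta->ia", X, dpre)
        self.ba.grad += dpre.sum(axis=(0, 1))
        dX += dpre @ self.Wa.value.T
        return dX


class SigmoidHead:
    """Dense scalar output with sigmoid activation (returns logits)."""

    def __init__(self, n_in: int, rng: np.random.Generator):
        self.w = Param(_glorot(rng, (n_in, 1))[:, 0])
        self.b = Param(np.zeros(1))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._cache = X
        return X @ self.w.value + self.b.value[0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        X = self._cache
        self.w.grad += X.T @ dlogit
        self.b.grad += dlogit.sum(keepdims=True)
        return dlogit[:, None] * self.w.value
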