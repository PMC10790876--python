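"""Minimal numpy neural-network layers with explicit backpropagation.

This module is intentionally small: dense, stacked-LSTM and 1-D convolution /
max-pool layers with an Adam optimizer — exactly the building blocks the
generator (recurrent) and discriminator (convolutional) need.  All state is
numpy, so runs are bitwise reproducible for a fixed seed on a fixed platform.

Conventions
-----------
* Batch-major arrays: dense ``(B, F)``, recurrent ``(B, T, F)``,
  convolutional ``(B, C, L)``.
* ``forward`` caches whatever ``backward`` needs; ``backward`` receives the
  gradient w.r.t. the layer output, accumulates parameter gradients into
  ``layer.grads`` and returns the gradient w.r.t. the layer input.
* Initialization mirrors the common uniform fan-in scheme
  ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``.
"""
from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    params: list
    grads: list

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Affine map ``y = x @ W + b`` on the trailing feature axis."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.W = rng.uniform(-bound, bound, size=(in_features, out_features))
        self.b = rng.uniform(-bound, bound, size=out_features)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = _sigmoid(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class LSTM(Layer):
    """Single LSTM layer returning the full hidden sequence ``(B, T, H)``.

    Gate order in the packed weight matrices is (input, forget, cell, output).
    Initial hidden and cell states are zero.
    """

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.hidden = hidden
        bound = 1.0 / np.sqrt(hidden)
        self.W = rng.uniform(-bound, bound, size=(in_features, 4 * hidden))
        self.U = rng.uniform(-bound, bound, size=(hidden, 4 * hidden))
        self.b = rng.uniform(-bound, bound, size=4 * hidden)
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.U), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, F = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        out = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t, :] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t, :] = h
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, _ = dy.shape
        H = self.hidden
        dW, dU, db = self.grads
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dy[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += self._x[:, t, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dx


class Conv1d(Layer):
    """1-D convolution with 'same' zero padding and unit stride."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        bound = 1.0 / np.sqrt(in_ch * kernel)
        self.W = rng.uniform(-bound, bound, size=(out_ch, in_ch, kernel))
        self.b = rng.uniform(-bound, bound, size=out_ch)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # (B, C, k, L) view by stacking the k shifted slices
        self._shifts = np.stack([xp[:, :, j : j + L] for j in range(k)], axis=2)
        self._in_shape = x.shape
        y = np.einsum("bckl,ock->bol", self._shifts, self.W, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        k = self.kernel
        p = k // 2
        self.grads[0] += np.einsum("bol,bckl->ock", dy, self._shifts, optimize=True)
        self.grads[1] += dy.sum(axis=(0, 2))
        dxp = np.zeros((B, C, L + 2 * p))
        dshift = np.einsum("bol,ock->bckl", dy, self.W, optimize=True)
        for j in range(k):
            dxp[:, :, j : j + L] += dshift[:, :, j, :]
        return dxp[:, :, p : p + L]


class MaxPool1d(Layer):
    """Non-overlapping max pooling; input length must be divisible by size."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        s = self.size
        if L % s:
            raise ValueError(f"length {L} not divisible by pool size {s}")
        xr = x.reshape(B, C, L // s, s)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        s = self.size
        dxr = np.zeros((B, C, L // s, s))
        idx = np.indices(self._argmax.shape)
        dxr[idx[0], idx[1], idx[2], self._argmax] = dy
        return dxr.reshape(B, C, L)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    @property
    def all_params(self) -> list:
        return [p for l in self.layers for p in l.params]

    @property
    def all_grads(self) -> list:
        return [g for l in self.layers for g in l.grads]

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adam with the standard bias correction; one slot pair per parameter."""

    def __init__(self, params: list, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar ``f`` w.r.t. array ``x`` (test helper)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        ix = it.multi_index
        orig = x[ix]
        x[ix] = orig + eps
        fp = f()
        x[ix] = orig - eps
        fm = f()
        x[ix] = orig
        g[ix] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
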