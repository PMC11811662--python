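"""Small numpy neural-network engine: layers, backprop, Adam.

Supports exactly what the autoencoders need — dense layers, strided 1-D
convolutions and their transposed counterparts, ReLU, an LSTM with full
backpropagation through time, mean-squared-error loss and the Adam
optimizer.  All parameters are float64; initialization is Glorot uniform
from a seeded generator, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Reshape(Layer):
    def __init__(self, shape_out: tuple):
        self.shape_out = shape_out  # per-sample shape

    def forward(self, x):
        self._shape_in = x.shape
        return x.reshape((x.shape[0],) + self.shape_out)

    def backward(self, dy):
        return dy.reshape(self._shape_in)


class Conv1d(Layer):
    """1-D convolution, stride 2, kernel 3, zero padding 1 (halves length)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.s, self.p = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_glorot(rng, (c_out, c_in * kernel),
                               c_in * kernel, c_out))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def _cols(self, xp: np.ndarray, out_len: int) -> np.ndarray:
        b, c, _ = xp.shape
        idx = (np.arange(out_len)[:, None] * self.s + np.arange(self.k)).T
        cols = xp[:, :, idx]                       # (B, C, k, out_len)
        return cols.reshape(b, c * self.k, out_len)

    def forward(self, x):
        b, c, L = x.shape
        self._L = L
        out_len = (L + 2 * self.p - self.k) // self.s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p)))
        self._cols_cache = self._cols(xp, out_len)
        y = np.einsum("oc,bcl->bol", self.w.value, self._cols_cache)
        return y + self.b.value[None, :, None]

    def backward(self, dy):
        b = dy.shape[0]
        out_len = dy.shape[2]
        self.w.grad += np.einsum("bol,bcl->oc", dy, self._cols_cache)
        self.b.grad += dy.sum(axis=(0, 2))
        dcols = np.einsum("oc,bol->bcl", self.w.value, dy)
        dcols = dcols.reshape(b, self.c_in, self.k, out_len)
        dxp = np.zeros((b, self.c_in, self._L + 2 * self.p))
        for j in range(self.k):
            pos = np.arange(out_len) * self.s + j
            np.add.at(dxp, (slice(None), slice(None), pos), dcols[:, :, j, :])
        return dxp[:, :, self.p:self.p + self._L]


class ConvTranspose1d(Layer):
    """Transposed 1-D convolution, stride 2, kernel 3, padding 1,
    output padding 1 (doubles length)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 2, pad: int = 1,
                 out_pad: int = 1):
        self.k, self.s, self.p, self.op = kernel, stride, pad, out_pad
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_glorot(rng, (c_in, c_out, kernel),
                               c_in * kernel, c_out))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        b, c, L = x.shape
        self._x = x
        self._L = L
        full = (L - 1) * self.s + self.k + self.op
        out_len = (L - 1) * self.s - 2 * self.p + self.k + self.op
        ypad = np.zeros((b, self.c_out, full))
        pos = np.arange(L) * self.s
        for j in range(self.k):
            contrib = np.einsum("bci,co->boi", x, self.w.value[:, :, j])
            np.add.at(ypad, (slice(None), slice(None), pos + j), contrib)
        y = ypad[:, :, self.p:self.p + out_len]
        return y + self.b.value[None, :, None]

    def backward(self, dy):
        b = dy.shape[0]
        L = self._L
        full = (L - 1) * self.s + self.k + self.op
        out_len = dy.shape[2]
        dypad = np.zeros((b, self.c_out, full))
        dypad[:, :, self.p:self.p + out_len] = dy
        self.b.grad += dy.sum(axis=(0, 2))
        dx = np.zeros_like(self._x)
        pos = np.arange(L) * self.s
        for j in range(self.k):
            sl = dypad[:, :, pos + j]              # (B, C_out, L)
            self.w.grad[:, :, j] += np.einsum("bci,boi->co", self._x, sl)
            dx += np.einsum("boi,co->bci", sl, self.w.value[:, :, j])
        return dx


class LSTM(Layer):
    """Single-layer LSTM over (B, T, D) inputs, returning (B, T, H)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.h = hidden
        self.wx = Param(_glorot(rng, (n_in, 4 * hidden), n_in, 4 * hidden))
        self.wh = Param(_glorot(rng, (hidden, 4 * hidden), hidden, 4 * hidden))
        self.b = Param(np.zeros(4 * hidden))
        # forget-gate bias 1: standard trick for gradient flow
        self.b.value[hidden:2 * hidden] = 1.0

    def params(self):
        return [self.wx, self.wh, self.b]

    @staticmethod
    def _sig(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))

    def forward(self, x):
        b, T, _ = x.shape
        H = self.h
        h = np.zeros((b, H))
        c = np.zeros((b, H))
        self._x = x
        self._cache = []
        hs = np.empty((b, T, H))
        for t in range(T):
            z = x[:, t, :] @ self.wx.value + h @ self.wh.value + self.b.value
            i = self._sig(z[:, :H])
            f = self._sig(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = self._sig(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        return hs

    def backward(self, dhs):
        b, T, H = dhs.shape
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((b, H))
        dc_next = np.zeros((b, H))
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.wx.grad += self._x[:, t, :].T @ dz
            self.wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.wx.value.T
            dh_next = dz @ self.wh.value.T
            dc_next = dc * f
        return dx


class TakeLast(Layer):
    """Select the last timestep of a (B, T, H) sequence."""

    def forward(self, x):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dy):
        dx = np.zeros(self._shape)
        dx[:, -1, :] = dy
        return dx


class RepeatSteps(Layer):
    """Tile a (B, D) vector into a (B, T, D) sequence."""

    def __init__(self, T: int):
        self.T = T

    def forward(self, x):
        return np.repeat(x[:, None, :], self.T, axis=1)

    def backward(self, dy):
        return dy.sum(axis=1)


class TimeDistributed(Layer):
    """Apply a Dense layer independently at every timestep."""

    def __init__(self, inner: Dense):
        self.inner = inner

    def params(self):
        return self.inner.params()

    def forward(self, x):
        b, T, d = x.shape
        self._bt = (b, T)
        y = self.inner.forward(x.reshape(b * T, d))
        return y.reshape(b, T, -1)

    def backward(self, dy):
        b, T = self._bt
        dx = self.inner.backward(dy.reshape(b * T, -1))
        return dx.reshape(b, T, -1)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad ** 2
            mhat = p.m / (1 - self.b1 ** self.t)
            vhat = p.v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean-squared error and its gradient with respect to pred."""
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size
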