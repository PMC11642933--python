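"""Minimal NumPy neural-network core for the additive time-series models.

Implements exactly the pieces the fully convolutional subnetworks need —
1-D convolution with "same" zero padding, batch normalization, ReLU, dense
layers, and the Adam optimizer with L2 weight decay — with hand-written
backpropagation.  Convolutions are evaluated as a single GEMM over an
im2col view, which is fast enough for the window lengths used here (30-150
samples, <= 20 channels).

Conventions: activations are ``(N, C, L)`` arrays; parameters carry a
``decay`` flag (weight decay applies to convolution/dense weights only, not
to biases or batch-norm affine parameters).  Gradient correctness is pinned
by a numerical-differentiation test in the test-suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay


def _sliding(x: np.ndarray, k: int) -> np.ndarray:
    """Same-padded sliding windows: (N, C, L) -> (N, C, L, k), k odd."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    return np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)


class Conv1d:
    """1-D convolution (cross-correlation), stride 1, "same" zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        bound = 1.0 / np.sqrt(c_in * k)
        self.w = Param(rng.uniform(-bound, bound, (c_out, c_in, k)).astype(dtype), True)
        self.b = Param(rng.uniform(-bound, bound, c_out).astype(dtype), False)
        self.k = k

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, length = x.shape
        cols = _sliding(x, self.k)  # (N, C, L, k)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            n * length, c * self.k
        )
        if training:
            self._cols2, self._shape = cols2, (n, c, length)
        o = self.w.value.shape[0]
        y = cols2 @ self.w.value.reshape(o, -1).T
        return y.reshape(n, length, o).transpose(0, 2, 1) + self.b.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, o, length = dy.shape
        _, c, _ = self._shape
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * length, o)
        self.w.grad += (dyr.T @ self._cols2).reshape(self.w.value.shape)
        self.b.grad += dy.sum(axis=(0, 2))
        # dx = same-padded correlation of dy with channel-transposed,
        # kernel-flipped weights (exact for odd k, stride 1)
        wflip = self.w.value[:, :, ::-1]  # (O, C, k)
        m = np.ascontiguousarray(wflip.transpose(0, 2, 1)).reshape(o * self.k, c)
        cols_dy = _sliding(dy, self.k)  # (N, O, L, k)
        cols_dy2 = np.ascontiguousarray(cols_dy.transpose(0, 2, 1, 3)).reshape(
            n * length, o * self.k
        )
        dx = (cols_dy2 @ m).reshape(n, length, c).transpose(0, 2, 1)
        return np.ascontiguousarray(dx)


class BatchNorm1d:
    """Per-channel batch normalization over the (batch, time) axes."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype), False)
        self.beta = Param(np.zeros(c, dtype), False)
        self.running_mean = np.zeros(c, dtype)
        self.running_var = np.ones(c, dtype)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(self.running_var.dtype)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * invstd[None, :, None]
            self._xhat, self._invstd = xhat, invstd
        else:
            invstd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None]) * invstd[None, :, None]
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        m = dy.shape[0] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (invstd[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        bound = 1.0 / np.sqrt(n_in)
        self.w = Param(rng.uniform(-bound, bound, (n_in, n_out)).astype(dtype), True)
        self.b = Param(rng.uniform(-bound, bound, n_out).astype(dtype), False)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with (coupled) L2 weight decay on parameters flagged ``decay``."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if p.decay and self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.value.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def fcn_stack(c_in: int, hidden: int, kernel: int, n_layers: int,
              rng: np.random.Generator, dtype=np.float32) -> Sequential:
    """``n_layers`` x (conv -> batch norm -> ReLU) with constant width."""
    layers: list = []
    c = c_in
    for _ in range(n_layers):
        layers += [Conv1d(c, hidden, kernel, rng, dtype),
                   BatchNorm1d(hidden, dtype=dtype), ReLU()]
        c = hidden
    return Sequential(layers)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    """Numerically stable mean binary cross-entropy from logits."""
    z = np.asarray(z, dtype=np.float64)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
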