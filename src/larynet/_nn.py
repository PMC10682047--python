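"""Minimal numpy neural-network engine for the sequential feature extractor.

Activations flow in channel-last layout (N, L, C) so each convolution is k
shifted (N*L, C_in) x (C_in, C_out) matrix products without an explicit patch
matrix; max pooling keeps argmax bookkeeping for the backward pass.  All
arithmetic is float32 and deterministic: the same seed gives bit-identical
parameters and gradients.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    kind = "abstract"

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    @property
    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded stride-1 convolution over the time axis, all channels in.

    The layer standardizes its output per channel over the batch and time
    axes (batch normalization folded into the convolution, with a learnable
    gain and shift and running statistics for inference); deep stacks stay
    trainable without separate normalization layers.
    """

    kind = "conv"
    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel length must be odd for same padding")
        scale = np.sqrt(2.0 / (c_in * k))
        self.w = (scale * rng.standard_normal((c_out, c_in, k))).astype(F32)
        self.gain = np.ones(c_out, dtype=F32)
        self.beta = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.dgain = np.zeros_like(self.gain)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c_out, dtype=F32)
        self.running_var = np.ones(c_out, dtype=F32)
        self.train_mode = True
        self._xp: np.ndarray | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w, self.gain, self.beta]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.dgain, self.dbeta]

    @property
    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def _conv(self, xp: np.ndarray, length: int) -> np.ndarray:
        k = self.w.shape[2]
        y = xp[:, 0:length, :] @ self.w[:, :, 0].T
        for t in range(1, k):
            y += xp[:, t: t + length, :] @ self.w[:, :, t].T
        return y

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, _ = x.shape
        pad = self.w.shape[2] // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        self._xp = xp
        z = self._conv(xp, length)
        if self.train_mode:
            mean = z.mean(axis=(0, 1))
            var = z.var(axis=(0, 1))
            m = self.BN_MOMENTUM
            self.running_mean += (m * (mean - self.running_mean)).astype(F32)
            self.running_var += (m * (var - self.running_var)).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
        zhat = (z - mean) * inv_std
        self._zhat = zhat.astype(F32)
        self._inv_std = inv_std.astype(F32)
        return self.gain * self._zhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length, _ = dy.shape
        k = self.w.shape[2]
        pad = k // 2
        zhat, inv_std = self._zhat, self._inv_std
        self.dgain[...] = (dy * zhat).sum(axis=(0, 1))
        self.dbeta[...] = dy.sum(axis=(0, 1))
        dzhat = dy * self.gain
        if self.train_mode:
            m_tot = F32(n * length)
            dz = (inv_std / m_tot) * (
                m_tot * dzhat
                - dzhat.sum(axis=(0, 1))
                - zhat * (dzhat * zhat).sum(axis=(0, 1))
            )
        else:
            dz = dzhat * inv_std
        dz = dz.astype(F32)
        xp = self._xp
        for t in range(k):
            self.dw[:, :, t] = np.tensordot(
                dz, xp[:, t: t + length, :], axes=([0, 1], [0, 1])
            )
        dxp = np.zeros_like(xp)
        for t in range(k):
            dxp[:, t: t + length, :] += dz @ self.w[:, :, t]
        return np.ascontiguousarray(dxp[:, pad: pad + length, :])


class ReLU(Layer):
    kind = "activation"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, F32(0))


class MaxPool1D(Layer):
    """Width-2 stride-2 max pooling over time; an odd trailing sample is dropped."""

    kind = "pool"

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        l2 = length // 2
        self._in_len = length
        xv = x[:, : 2 * l2, :].reshape(n, l2, 2, c)
        self._arg = np.argmax(xv, axis=2)
        return np.max(xv, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, l2, c = dy.shape
        dx = np.zeros((n, self._in_len, c), dtype=dy.dtype)
        idx = 2 * np.arange(l2)[None, :, None] + self._arg
        np.put_along_axis(dx, idx, dy, axis=1)
        return dx


class GlobalAvgPool(Layer):
    kind = "global_pool"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._len, axis=1) / F32(self._len)


class L2Norm(Layer):
    """Project feature vectors onto the unit sphere (metric-learning convention).

    Keeps triplet distances bounded in [0, 2] and the classifier logits
    scale-stable regardless of how the extractor's activations grow.
    """

    kind = "l2norm"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._norm = np.sqrt(np.maximum((x * x).sum(axis=1, keepdims=True), 1e-24))
        self._y = x / self._norm
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        return (dy - y * (dy * y).sum(axis=1, keepdims=True)) / self._norm


class Dense(Layer):
    kind = "dense"

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = (scale * rng.standard_normal((d_out, d_in))).astype(F32)
        self.b = np.zeros(d_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w


class Residual(Layer):
    """Identity skip around a channel-preserving sub-stack (y = x + f(x)).

    Keeps deep conv stacks trainable; contributes no layers of its own — the
    census counts the wrapped conv/activation layers.
    """

    kind = "residual"

    def __init__(self, inner: list[Layer]):
        self.inner = inner

    @property
    def params(self) -> list[np.ndarray]:
        return [p for lay in self.inner for p in lay.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for lay in self.inner for g in lay.grads]

    @property
    def buffers(self) -> list[np.ndarray]:
        return [b for lay in self.inner for b in lay.buffers]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x
        for lay in self.inner:
            y = lay.forward(y)
        return x + y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy
        for lay in reversed(self.inner):
            dx = lay.backward(dx)
        return dy + dx


def iter_atomic_layers(layers):
    """Yield non-container layers, descending into residual wrappers."""
    for lay in layers:
        if isinstance(lay, Residual):
            yield from iter_atomic_layers(lay.inner)
        else:
            yield lay


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    @property
    def params(self) -> list[np.ndarray]:
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for lay in self.layers for g in lay.grads]

    @property
    def buffers(self) -> list[np.ndarray]:
        return [b for lay in self.layers for b in lay.buffers]

    def set_training(self, flag: bool) -> None:
        for lay in iter_atomic_layers(self.layers):
            if hasattr(lay, "train_mode"):
                lay.train_mode = flag
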