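"""Minimal NumPy neural-network framework for small CNN regressors.

Implements exactly what the count-regression model needs: same-padded 3x3
convolutions (im2col + BLAS matmul), ReLU, 2x2 max pooling, global average
pooling, dropout, a linear head, mean-squared-error loss, the Adam optimizer
and a reduce-on-plateau learning-rate scheduler.  Everything is float32,
single-process and fully deterministic given a seed.

Layers follow a tiny forward/backward protocol: ``forward(x, train)`` caches
what backward needs; ``backward(grad_out)`` returns ``grad_in`` and stores
parameter gradients in ``layer.grads`` aligned with ``layer.params``.
Gradient correctness is established by finite-difference tests rather than
by construction.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patch matrix for stride-1 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, h, w, k, k), strides=(s0, s1, s2, s3, s2, s3)
    )
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * k * k)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of patch gradients)."""
    n, c, h, w = x_shape
    d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]
    buffers: list[np.ndarray]  # non-trained state (e.g. batch-norm statistics)

    def __init__(self):
        self.params, self.grads, self.buffers = [], [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded stride-1 square convolution with He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in)).astype(np.float32)
        b = np.zeros(out_ch, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train):
        self._x_shape = x.shape
        n, c, h, w = x.shape
        self._cols = _im2col(x, self.k, self.k // 2)
        out = self._cols @ self.params[0].T + self.params[1]
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n, h * w, self.out_ch)
        self.grads[0][...] = np.tensordot(g, self._cols, axes=([0, 1], [0, 1]))
        self.grads[1][...] = g.sum(axis=(0, 1))
        dcols = g @ self.params[0]
        return _col2im(dcols, self._x_shape, self.k, self.k // 2)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling (input H, W must be even)."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        self._x_shape = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = r.argmax(axis=-1)
        return np.take_along_axis(r, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._x_shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dr, self._argmax[..., None], grad[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with learnable scale
    and shift.  Training batches use batch statistics and update running
    estimates (momentum 0.1); inference uses the running estimates."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        gamma = np.ones(channels, dtype=np.float32)
        beta = np.zeros(channels, dtype=np.float32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.buffers = [np.zeros(channels, dtype=np.float32),   # running mean
                        np.ones(channels, dtype=np.float32)]    # running var
        self.eps, self.momentum = eps, momentum

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.buffers[0][...] = (1 - self.momentum) * self.buffers[0] + self.momentum * mu
            self.buffers[1][...] = (1 - self.momentum) * self.buffers[1] + self.momentum * var
        else:
            mu, var = self.buffers
        self._train = train
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu.reshape(1, -1, 1, 1)) * self._invstd.reshape(1, -1, 1, 1)
        return (self.params[0].reshape(1, -1, 1, 1) * self._xhat
                + self.params[1].reshape(1, -1, 1, 1))

    def backward(self, grad):
        self.grads[0][...] = np.sum(grad * self._xhat, axis=(0, 2, 3))
        self.grads[1][...] = grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.params[0].reshape(1, -1, 1, 1)
        invstd = self._invstd.reshape(1, -1, 1, 1)
        if not self._train:
            return dxhat * invstd
        n, _, h, w = grad.shape
        m = n * h * w
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd / m) * (m * dxhat - s1 - self._xhat * s2)


class AvgPool2d(Layer):
    """Non-overlapping 2x2 average pooling (cheap downsampling stem)."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        self._x_shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._x_shape
        g = np.broadcast_to(
            grad[:, :, :, None, :, None], (n, c, h // 2, 2, w // 2, 2)
        )
        return (g / 4.0).reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train):
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._x_shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout p must be in [0, 1)")
        self.p, self._rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim)).astype(np.float32)
        b = np.zeros(out_dim, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.params[0].T + self.params[1]

    def backward(self, grad):
        self.grads[0][...] = grad.T @ self._x
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.params[0]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def buffers(self) -> list[np.ndarray]:
        return [b for layer in self.layers for b in getattr(layer, "buffers", [])]

    def state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.parameters() + self.buffers()]

    def load_state(self, state: list[np.ndarray]) -> None:
        arrays = self.parameters() + self.buffers()
        if len(arrays) != len(state):
            raise ValueError("state/parameter count mismatch")
        for a, s in zip(arrays, state):
            a[...] = s


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored loss (strict improvement, no
    minimum delta)."""

    def __init__(self, optimizer: Adam, factor: float = 0.2, patience: int = 10):
        if not (0.0 < factor < 1.0):
            raise ValueError("factor must be in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.num_bad = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, loss: float) -> bool:
        """Record an epoch loss; returns True if the rate was reduced."""
        if loss < self.best:
            self.best = loss
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad >= self.patience:
            self.optimizer.lr *= self.factor
            self.num_bad = 0
            return True
        return False
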