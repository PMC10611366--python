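"""Minimal CPU neural-network layers with explicit forward/backward passes.

Everything is float64 numpy. Each layer caches what its backward pass needs
during ``forward(..., train=True)``; ``backward`` consumes that cache and
returns the gradient with respect to the layer input while accumulating
parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-learnable state (e.g. batch-norm running stats)."""
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Conv2d(Module):
    """2D convolution (cross-correlation) via im2col + BLAS matmul."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        # He initialization, suited to the ReLU nonlinearities that follow
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel)))
        self.b = Param(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding
        self.kernel = kernel
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s][:, :, :ho, :wo]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)
        out_ch = self.w.value.shape[0]
        y = cols @ self.w.value.reshape(out_ch, -1).T
        if self.b is not None:
            y = y + self.b.value
        self._cache = (cols, x.shape) if train else None
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, grad):
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, s, p = self.kernel, self.stride, self.padding
        out_ch = self.w.value.shape[0]
        dy = grad.transpose(0, 2, 3, 1)  # (n, ho, wo, out)
        ho, wo = dy.shape[1], dy.shape[2]
        dy_flat = dy.reshape(-1, out_ch)
        self.w.grad += (dy_flat.T @ cols.reshape(-1, c * k * k)).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.w.value.reshape(out_ch, -1)).reshape(n, ho, wo, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n, c, ho, wo, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += dcols[:, :, :, :, ki, kj]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv_std, _shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.value[None, :, None, None]
        # standard batch-norm backward, fused
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return term * inv_std[None, :, None, None]


class ReLU(Module):
    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s][:, :, :ho, :wo]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        if train:
            self._cache = (idx, x.shape, (ho, wo))
        return flat.max(axis=-1)

    def backward(self, grad):
        idx, xshape, (ho, wo) = self._cache
        n, c, h, w = xshape
        k, s, p = self.kernel, self.stride, self.padding
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        ni, ci, hi, wi = np.indices((n, c, ho, wo))
        rows = hi * s + idx // k
        cols = wi * s + idx % k
        np.add.at(dxp, (ni, ci, rows, cols), grad)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class GlobalAvgPool(Module):
    """Spatial mean, (n, c, h, w) -> (n, c)."""

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class GlobalMaxPool(Module):
    """Spatial max, (n, c, h, w) -> (n, c); suits small localized features."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        idx = flat.argmax(axis=2)
        if train:
            self._cache = (idx, x.shape)
        return flat.max(axis=2)

    def backward(self, grad):
        idx, (n, c, h, w) = self._cache
        dflat = np.zeros((n, c, h * w))
        ni, ci = np.indices((n, c))
        dflat[ni, ci, idx] = grad
        return dflat.reshape(n, c, h, w)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_f)
        self.w = Param(rng.uniform(-bound, bound, (out_f, in_f)))
        self.b = Param(rng.uniform(-bound, bound, out_f))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Softmax(Module):
    """Row-wise softmax over the last axis of a 2D input."""

    def forward(self, x, train=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        if train:
            self._p = p
        return p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=1, keepdims=True))


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def params(self):
        return [p for m in self.modules for p in m.params()]

    def buffers(self):
        return [b for m in self.modules for b in m.buffers()]

    def forward(self, x, train=False):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, grad):
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad
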