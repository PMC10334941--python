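"""A compact numpy CNN engine with hand-written backward passes.

Layers store their parameters as :class:`Param` objects (value + gradient
buffer) and implement ``forward(x, train)`` / ``backward(grad_out)``; the
backward pass accumulates parameter gradients and returns the gradient with
respect to the layer input.  Convolution uses an im2col/matmul formulation
so the heavy lifting is BLAS.  Everything is deterministic: parameter
initialization takes an explicit ``numpy.random.Generator`` and no layer
draws randomness at run time, so a forward/backward pass is a pure function
of (parameters, input).

The engine exists to make the training objective fully transparent and
finite-difference-checkable; it is sized for small backbones on small
images, not for GPU-scale work.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Linear",
    "GlobalAvgPool",
    "Sequential",
    "Residual",
    "SGD",
]


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. BN running stats), copied with the model."""
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    if pad:
        xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
        xp[:, :, pad : pad + h, pad : pad + w] = x
    else:
        xp = x
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki, kj] = xp[
                :, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride
            ]
    return cols.reshape(n, c * k * k, oh * ow), (n, c, h, w, oh, ow)


def _col2im(gcols: np.ndarray, shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w, oh, ow = shape
    g = gcols.reshape(n, c, k, k, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride] += g[
                :, :, ki, kj
            ]
    return xp[:, :, pad : pad + h, pad : pad + w] if pad else xp


class Conv2d(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = Param(
            rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)).astype(dtype), "W"
        )
        self.b = Param(np.zeros(c_out, dtype=dtype), "b")
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        cols, shape = _im2col(x, self.kernel, self.stride, self.pad)
        n, _, _, _, oh, ow = shape
        c_out = self.W.value.shape[0]
        wmat = self.W.value.reshape(c_out, -1)
        # (n, ckk, ohow) x (c_out, ckk)^T, batched as one big matmul
        y = np.einsum("ncl,oc->nol", cols, wmat, optimize=True)
        y += self.b.value[None, :, None]
        self._cache = (cols, shape) if train else None
        return y.reshape(n, c_out, oh, ow)

    def backward(self, gy):
        cols, shape = self._cache
        n, c, h, w, oh, ow = shape
        c_out = gy.shape[1]
        g = gy.reshape(n, c_out, oh * ow)
        wmat = self.W.value.reshape(c_out, -1)
        self.W.grad += np.einsum("nol,ncl->oc", g, cols, optimize=True).reshape(
            self.W.value.shape
        )
        self.b.grad += g.sum(axis=(0, 2))
        gcols = np.einsum("nol,oc->ncl", g, wmat, optimize=True)
        return _col2im(gcols, shape, self.kernel, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype), "gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv) if train else None
        return y

    def backward(self, gy):
        xhat, inv = self._cache
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.value[None, :, None, None]
        # batch-statistics backward: gx = inv/m * (m*gxhat - sum(gxhat) - xhat*sum(gxhat*xhat))
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * gxhat - s1 - xhat * s2)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        mask = x > 0
        self._mask = mask if train else None
        return x * mask

    def backward(self, gy):
        return gy * self._mask


class Linear(Layer):
    def __init__(
        self, f_in: int, f_out: int, rng: np.random.Generator | None = None, dtype=np.float32
    ):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / f_in)
        self.W = Param(rng.normal(0.0, scale, size=(f_out, f_in)).astype(dtype), "W")
        self.b = Param(np.zeros(f_out, dtype=dtype), "b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.W.value.T + self.b.value

    def backward(self, gy):
        self.W.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value


class GlobalAvgPool(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train):
        self._shape = x.shape if train else None
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None], (n, c, h, w)) / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class Residual(Layer):
    """y = body(x) + shortcut(x); the ResNet basic-block skeleton."""

    def __init__(self, body: Layer, shortcut: Layer | None = None):
        self.body = body
        self.shortcut = shortcut  # None = identity

    def params(self):
        p = self.body.params()
        if self.shortcut is not None:
            p = p + self.shortcut.params()
        return p

    def buffers(self):
        b = self.body.buffers()
        if self.shortcut is not None:
            b = b + self.shortcut.buffers()
        return b

    def forward(self, x, train):
        y = self.body.forward(x, train)
        sc = x if self.shortcut is None else self.shortcut.forward(x, train)
        return y + sc

    def backward(self, gy):
        gx = self.body.backward(gy)
        if self.shortcut is None:
            return gx + gy
        return gx + self.shortcut.backward(gy)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v += p.grad
            p.value -= (self.lr * v).astype(p.value.dtype, copy=False)
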