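"""Minimal convolutional network primitives on numpy.

Single-sample (C, H, W) tensors, explicit forward/backward per layer, and
an Adam optimizer: just enough machinery to train the desk-scale pix2pix
generator/discriminator pair on a CPU.  Every layer caches what its
backward pass needs; gradients accumulate in ``Param.grad`` until
``zero_grad``.  All backward passes are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with zero padding, via im2col."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        w = rng.normal(0.0, 0.02, size=(cout, cin, k, k)).astype(dtype)
        self.w = Param(w)
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        cin, ho, wo = win.shape[0], win.shape[1], win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 3, 4, 1, 2)).reshape(
            cin * k * k, ho * wo
        )
        wmat = self.w.value.reshape(self.cout, -1)
        out = (wmat @ cols + self.b.value[:, None]).reshape(self.cout, ho, wo)
        self._cache = (cols, xp.shape, (ho, wo))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xp_shape, (ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        gmat = grad.reshape(self.cout, -1)
        self.w.grad += (gmat @ cols.T).reshape(self.w.value.shape)
        self.b.grad += gmat.sum(axis=1)
        dcols = (self.w.value.reshape(self.cout, -1).T @ gmat).reshape(
            self.cin, k, k, ho, wo
        )
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[:, ki, kj]
        if p:
            return dxp[:, p:-p, p:-p]
        return dxp


class UpsampleNearest2(Layer):
    """Nearest-neighbor x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c, h2, w2 = grad.shape
        return grad.reshape(c, h2 // 2, 2, w2 // 2, 2).sum(axis=(2, 4))


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Dropout that stays active at inference (the generator noise source)."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.p <= 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (
            1.0 - self.p
        )
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class InstanceNorm2d(Layer):
    """Per-channel normalization over the spatial axes, with affine scale."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = xhat.shape[1] * xhat.shape[2]
        self.gamma.grad += (grad * xhat).sum(axis=(1, 2))
        self.beta.grad += grad.sum(axis=(1, 2))
        dxhat = grad * self.gamma.value[:, None, None]
        term = (
            n * dxhat
            - dxhat.sum(axis=(1, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
        )
        return inv / n * term


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam over a list of Params (beta defaults follow the study setup)."""

    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
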