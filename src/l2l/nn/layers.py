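"""Minimal NumPy neural-network layers with explicit backpropagation.

Every layer exposes ``forward(x, train)`` and ``backward(grad_out)``;
trainable arrays live in ``layer.params`` with matching gradients in
``layer.grads``.  All computation is float32; batches are NCHW.  The
layer set is deliberately small — strided convolution, nearest-neighbour
upsampling, dense heads and pointwise nonlinearities are all the leaf
networks here require.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base class: stateless by default, no parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv2d(Layer):
    """k×k convolution via im2col, zero padding, integer stride."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.params = {
            "W": _he_init(rng, (c_out, c_in * k * k), c_in * k * k),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def _cols(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
        p, k, s = self.pad, self.k, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return np.ascontiguousarray(cols), (n, ho, wo)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols, (n, ho, wo) = self._cols(x)
        self._cache = (cols, x.shape, (n, ho, wo))
        out = cols @ self.params["W"].T + self.params["b"]
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, (n, ho, wo) = self._cache
        g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        self.grads["W"] += g.T @ cols
        self.grads["b"] += g.sum(axis=0)
        gcols = (g @ self.params["W"]).reshape(n, ho, wo, self.c_in, self.k, self.k)
        p, s = self.pad, self.stride
        hp, wp = x_shape[2] + 2 * p, x_shape[3] + 2 * p
        gx = np.zeros((n, self.c_in, hp, wp), dtype=F32)
        for ki in range(self.k):
            for kj in range(self.k):
                gx[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if p:
            gx = gx[:, :, p:-p, p:-p]
        return gx


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        self.params = {
            "W": _he_init(rng, (n_out, n_in), n_in),
            "b": np.zeros(n_out, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] += grad.T @ self._x
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = F32(slope)

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class NearestUpsample(Layer):
    """2× nearest-neighbour upsampling; gradient is a 2×2 block sum."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    """Inverted dropout; the mask comes from the generator handed to forward
    via ``set_rng`` so stochastic inference (Pix2pix noise source) is seedable."""

    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p
        self._rng = np.random.default_rng(0)

    def set_rng(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def forward(self, x, train=True):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self._rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=True):
        for lyr in self.layers:
            x = lyr.forward(x, train=train)
        return x

    def backward(self, grad):
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)
        return grad

    def zero_grad(self):
        for lyr in self.layers:
            lyr.zero_grad()

    def iter_params(self):
        for i, lyr in enumerate(self.layers):
            for name, p in lyr.params.items():
                yield f"{i}.{name}", p, lyr.grads[name]
            if isinstance(lyr, (Sequential, Residual)):
                for sub, p, g in lyr.iter_params():
                    yield f"{i}.{sub}", p, g


class Residual(Layer):
    """h(x) = r(x) + x where r is an inner stack preserving shape."""

    def __init__(self, inner: Sequential):
        super().__init__()
        self.inner = inner

    def forward(self, x, train=True):
        return self.inner.forward(x, train=train) + x

    def backward(self, grad):
        return self.inner.backward(grad) + grad

    def zero_grad(self):
        self.inner.zero_grad()

    def iter_params(self):
        for name, p, g in self.inner.iter_params():
            yield f"res.{name}", p, g


def collect_params(module) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Flatten (name, param, grad) triples of a Sequential/Residual tree."""
    if isinstance(module, (Sequential, Residual)):
        return list(module.iter_params())
    return [(n, p, module.grads[n]) for n, p in module.params.items()]
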