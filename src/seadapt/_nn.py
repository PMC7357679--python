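"""Minimal feed-forward network machinery (numpy forward/backward + Adam).

The networks in this package are tiny (two valid convolutions and one or two
dense layers), so layers are implemented directly on numpy arrays with
explicit reverse-mode gradients. Gradients accumulate into ``Param.grad``
(call :meth:`Network.zero_grad` between steps), which lets several loss terms
contribute to one optimizer step. Convolutions use im2col; everything is
deterministic given the seeded initializer and input order.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, ValidationError


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    name: str = ""

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Valid (no padding), stride-1 convolution on NHWC batches."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        fan_in = kernel * kernel * in_channels
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.W = Param(_uniform_fan_in(rng, (fan_in, out_channels), fan_in), "conv_W")
        self.b = Param(np.zeros(out_channels), "conv_b")
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.kernel
        if c != self.in_channels:
            raise ValidationError(f"expected {self.in_channels} channels, got {c}")
        if h < k or w < k:
            raise ConfigurationError(f"input {h}×{w} too small for a {k}×{k} valid convolution")
        # (N, oh, ow, C, k, k) -> (N*oh*ow, k*k*C) matching W's (k, k, C) raveling
        win = sliding_window_view(x, (k, k), axis=(1, 2))
        win = np.moveaxis(win, 3, 5)  # (N, oh, ow, k, k, C)
        oh, ow = win.shape[1], win.shape[2]
        cols = win.reshape(n * oh * ow, k * k * c)
        self._cols = cols
        self._x_shape = x.shape
        out = cols @ self.W.value + self.b.value
        return out.reshape(n, oh, ow, self.out_channels)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, oh, ow, _ = grad_out.shape
        k, c = self.kernel, self.in_channels
        g2 = grad_out.reshape(n * oh * ow, self.out_channels)
        self.W.grad += self._cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        gcols = (g2 @ self.W.value.T).reshape(n, oh, ow, k, k, c)
        dx = np.zeros(self._x_shape)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + oh, j : j + ow, :] += gcols[:, :, :, i, j, :]
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Param(_uniform_fan_in(rng, (in_dim, out_dim), in_dim), "dense_W")
        self.b = Param(np.zeros(out_dim), "dense_b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.W.value.T


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, 0.0)


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Network:
    """A plain layer chain with gradient accumulation."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.params()
        if len(arrays) != len(own):
            raise ValidationError(f"expected {len(own)} parameter arrays, got {len(arrays)}")
        for p, a in zip(own, arrays):
            a = np.asarray(a, dtype=np.float64)
            if a.shape != p.value.shape:
                raise ValidationError(f"shape mismatch {a.shape} vs {p.value.shape} for {p.name}")
            p.value[...] = a

    def copy(self) -> "Network":
        return copy.deepcopy(self)


class Adam:
    """Adaptive-moment gradient descent (the package's default optimizer)."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ConfigurationError("learning rate must be positive")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
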