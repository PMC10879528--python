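"""Minimal dense neural-network layers with manual backpropagation.

Just enough machinery for the desk-scale conditional GAN and VAE backends:
fully connected layers, a few activations, an Adam optimizer and a
``Sequential`` container.  All arrays are float64 numpy; batches are
``(n_samples, n_features)``.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np


class Layer:
    params: List[np.ndarray]
    grads: List[np.ndarray]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style scaling keeps activations in range for ReLU-family nets
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ grad
        self.grads[1] += grad.sum(axis=0)
        return grad @ self.w.T


class ReLU(Layer):
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Tanh(Layer):
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y ** 2)


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    @property
    def params(self) -> List[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> List[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Adam:
    def __init__(self, params: List[np.ndarray], grads: List[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mlp(sizes: Sequence[int], rng: np.random.Generator,
        hidden: str = "relu", out: str | None = None) -> Sequential:
    """Fully connected net: ``sizes[0] -> ... -> sizes[-1]``."""
    acts = {"relu": ReLU, "lrelu": LeakyReLU, "tanh": Tanh}
    layers: List[Layer] = []
    for i in range(len(sizes) - 1):
        layers.append(Dense(sizes[i], sizes[i + 1], rng))
        if i < len(sizes) - 2:
            layers.append(acts[hidden]())
    if out is not None:
        layers.append(acts[out]())
    return Sequential(layers)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_with_logits(logits: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy against a constant target; returns (loss, dlogits)."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = float(-np.mean(target * np.log(p + eps) + (1 - target) * np.log(1 - p + eps)))
    dlogits = (p - target) / logits.size
    return loss, dlogits
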