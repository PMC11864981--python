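"""Minimal dense neural-network layers with manual backpropagation.

A compact CPU implementation covering exactly what the graph network
needs: dense layers, batch normalization, leaky-ReLU, inverted dropout,
a sequential container and an Adam optimizer. Parameter initialization,
dropout masks and data order all flow from explicit NumPy generators, so
runs are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A tensor with its gradient and Adam moment buffers."""

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine layer with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class BatchNorm(Layer):
    """Batch normalization over the row (node/item) dimension."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, train, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.value
        if not train or n == 1:
            return g * inv
        return (inv / n) * (n * g - g.sum(axis=0)
                            - xhat * (g * xhat).sum(axis=0))


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha
        self._mask = None

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0,1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list):
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with per-step bias correction; gradients reset after each step."""

    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p in self.params:
            p.m = self.beta1 * p.m + (1 - self.beta1) * p.grad
            p.v = self.beta2 * p.v + (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


# ---------------------------------------------------------------------- #
# losses (return value and gradient w.r.t. the raw scores)
# ---------------------------------------------------------------------- #
def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray,
                  mask: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over unmasked items; masked rows get zero grad."""
    n, c = logits.shape
    if mask is None:
        mask = np.ones(n, dtype=bool)
    valid = int(mask.sum())
    p = softmax(logits)
    grad = np.zeros_like(logits)
    if valid == 0:
        return 0.0, grad
    idx = np.flatnonzero(mask)
    eps = 1e-12
    loss = -np.log(p[idx, targets[idx]] + eps).mean()
    grad[idx] = p[idx]
    grad[idx, targets[idx]] -= 1.0
    grad[idx] /= valid
    return float(loss), grad


def mse_l1(pred: np.ndarray, target: np.ndarray,
           mask: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean squared error plus L1 norm for continuous targets."""
    pred = np.atleast_2d(pred)
    target = np.atleast_2d(target)
    n = pred.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    valid = int(mask.sum())
    grad = np.zeros_like(pred)
    if valid == 0:
        return 0.0, grad
    diff = pred - target
    idx = np.flatnonzero(mask)
    loss = float((diff[idx] ** 2).mean() + np.abs(diff[idx]).mean())
    per = diff[idx].size
    grad[idx] = (2.0 * diff[idx] + np.sign(diff[idx])) / per
    return loss, grad
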