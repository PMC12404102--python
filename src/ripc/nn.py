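"""Minimal numpy neural-network layers with hand-derived gradients.

The point network is a fixed feed-forward pipeline (shared pointwise affine
layers, batch normalization, ReLU, dropout, log-softmax), so reverse-mode
differentiation is implemented directly per layer rather than through a
general autodiff graph.  All arrays are float64: the models are small and
exact-ish arithmetic makes gradient checking and determinism tests clean.

Conventions
-----------
* A layer's ``forward`` caches whatever its ``backward`` needs; ``backward``
  takes d(loss)/d(output) and returns d(loss)/d(input) while accumulating
  parameter gradients in ``Param.grad``.
* Batch normalization normalizes over axis 0 (all grouped points of a batch
  are flattened onto that axis upstream) and keeps running statistics for
  evaluation mode (momentum 0.1, the conventional running-average choice).
* Dropout is "inverted": active only in training, scaling by 1/(1-p).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Dense", "BatchNorm", "ReLU", "Dropout", "LogSoftmax", "AdamW"]


class Param:
    """A trainable array with its gradient accumulator."""

    def __init__(self, value: np.ndarray, dtype=np.float64):
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Dense:
    """Affine map y = x W + b, shared across all points (rows)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float64):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out)), dtype)
        self.b = Param(np.zeros(c_out), dtype)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm:
    """Per-channel normalization over axis 0 with affine scale/shift."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float64):
        self.gamma = Param(np.ones(c), dtype)
        self.beta = Param(np.zeros(c), dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)
        dxhat = dy * self.gamma.value
        # gradient through batch mean and variance
        return (
            dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)
        ) * inv_std

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout:
    def __init__(self, p: float):
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = ((rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class LogSoftmax:
    """Row-wise log-softmax; exp of the output sums to one per row."""

    def forward(self, z: np.ndarray) -> np.ndarray:
        zmax = z.max(axis=-1, keepdims=True)
        logp = z - zmax - np.log(np.exp(z - zmax).sum(axis=-1, keepdims=True))
        self._p = np.exp(logp)
        return logp

    def backward(self, dlogp: np.ndarray) -> np.ndarray:
        return dlogp - self._p * dlogp.sum(axis=-1, keepdims=True)


class AdamW:
    """Adam with decoupled weight decay (applied to every parameter)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.value -= lr * (update + self.weight_decay * p.value)
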