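"""Minimal feed-forward network machinery on NumPy.

Implements exactly what the adversarial training scheme needs: dense layers,
batch normalisation, inverted dropout, ReLU/sigmoid activations, an MLP
container with explicit forward/backward passes, and RMSprop.  Gradients are
computed by straightforward reverse-mode accumulation; each layer caches its
forward inputs and produces parameter gradients plus the gradient with
respect to its input, so networks can be chained (e.g. backpropagating a
discriminator's input gradient into a generator) without an autodiff
framework.

All arithmetic is float64.  Training-mode stochasticity (dropout masks) is
drawn from a per-network generator, so a seeded model is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "BatchNorm",
    "MLP",
    "RMSprop",
    "softmax",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Dense:
    """Affine layer with He-scaled Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        if n_in < 1 or n_out < 1:
            raise ValueError("layer widths must be >= 1")
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self, "W", "dW"), (self, "b", "db")]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return []


class Sigmoid:
    def __init__(self):
        self._y = None

    def forward(self, x, train):
        self._y = sigmoid(x)
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)

    def params(self):
        return []


class Dropout:
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask

    def params(self):
        return []


class BatchNorm:
    """Batch normalisation with running statistics for evaluation mode."""

    def __init__(self, n: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (train, xhat, inv, x.shape[0])
        return self.gamma * xhat + self.beta

    def backward(self, g):
        if self._cache is None:
            raise RuntimeError("backward before forward")
        was_train, xhat, inv, m = self._cache
        if not was_train:
            # eval mode: running stats are constants w.r.t. the input
            self.dgamma = (g * xhat).sum(axis=0)
            self.dbeta = g.sum(axis=0)
            return g * self.gamma * inv
        self.dgamma = (g * xhat).sum(axis=0)
        self.dbeta = g.sum(axis=0)
        gx = g * self.gamma
        return inv / m * (m * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))

    def params(self):
        return [(self, "gamma", "dgamma"), (self, "beta", "dbeta")]


class MLP:
    """A chain of layers with explicit forward/backward."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Backpropagate an output gradient; returns the input gradient."""
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All persistent arrays (parameters + BN running stats), keyed."""
        out = {}
        for i, layer in enumerate(self.layers):
            for owner, name, _ in layer.params():
                out[f"{i}.{name}"] = getattr(owner, name)
            if isinstance(layer, BatchNorm):
                out[f"{i}.running_mean"] = layer.running_mean
                out[f"{i}.running_var"] = layer.running_var
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for owner, name, _ in layer.params():
                setattr(owner, name, np.array(arrays[f"{i}.{name}"]))
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(arrays[f"{i}.running_mean"])
                layer.running_var = np.array(arrays[f"{i}.running_var"])


class RMSprop:
    """RMSprop with the usual Keras defaults (lr 1e-3, rho 0.9, eps 1e-7)."""

    def __init__(self, net: MLP, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        self.net = net
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._cache = [np.zeros_like(getattr(o, p)) for o, p, _ in net.params()]

    def step(self) -> None:
        for slot, (owner, pname, gname) in zip(self._cache, self.net.params()):
            g = getattr(owner, gname)
            slot *= self.rho
            slot += (1.0 - self.rho) * g * g
            param = getattr(owner, pname)
            param -= self.lr * g / (np.sqrt(slot) + self.eps)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {str(i): c for i, c in enumerate(self._cache)}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        self._cache = [np.array(arrays[str(i)]) for i in range(len(self._cache))]
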