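"""Minimal dense neural-network layers with explicit backpropagation.

Everything is plain numpy: each layer caches what its backward pass needs,
parameters live in flat dicts keyed by layer name so that optimizers and
freeze masks can address them uniformly. This is deliberately small — the
models built on top are narrow multilayer perceptrons.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "LayerNorm", "ReLU", "MLP", "Adam", "init_dense"]


def init_dense(rng: np.random.Generator, n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
    """Kaiming-style init for a dense layer, float64 for reproducibility."""
    scale = np.sqrt(2.0 / n_in)
    w = rng.standard_normal((n_in, n_out)) * scale
    b = np.zeros(n_out)
    return w, b


class Dense:
    """Affine layer y = x W + b."""

    def __init__(self, name: str, n_in: int, n_out: int, rng: np.random.Generator):
        self.name = name
        self.n_in, self.n_out = n_in, n_out
        w, b = init_dense(rng, n_in, n_out)
        self.params = {f"{name}.W": w, f"{name}.b": b}
        self._x: np.ndarray | None = None

    def forward(self, params: dict, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if cache:
            self._x = x
        return x @ params[f"{self.name}.W"] + params[f"{self.name}.b"]

    def backward(self, params: dict, grads: dict, gy: np.ndarray) -> np.ndarray:
        x = self._x
        grads[f"{self.name}.W"] = grads.get(f"{self.name}.W", 0.0) + x.T @ gy
        grads[f"{self.name}.b"] = grads.get(f"{self.name}.b", 0.0) + gy.sum(axis=0)
        return gy @ params[f"{self.name}.W"].T


class LayerNorm:
    """Per-row normalization with learnable gain/bias.

    Normalizes across the feature axis of each sample independently, so the
    statistics do not leak information across cells in a minibatch.
    """

    eps = 1e-5

    def __init__(self, name: str, dim: int):
        self.name = name
        self.params = {f"{name}.g": np.ones(dim), f"{name}.b": np.zeros(dim)}
        self._cache: tuple | None = None

    def forward(self, params: dict, x: np.ndarray, cache: bool = True) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if cache:
            self._cache = (xhat, inv)
        return xhat * params[f"{self.name}.g"] + params[f"{self.name}.b"]

    def backward(self, params: dict, grads: dict, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = params[f"{self.name}.g"]
        grads[f"{self.name}.g"] = grads.get(f"{self.name}.g", 0.0) + (gy * xhat).sum(axis=0)
        grads[f"{self.name}.b"] = grads.get(f"{self.name}.b", 0.0) + gy.sum(axis=0)
        gxhat = gy * g
        d = xhat.shape[1]
        # standard layer-norm backward: remove mean and xhat-projection components
        gx = inv * (gxhat - gxhat.mean(axis=1, keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=1, keepdims=True))
        return gx


class ReLU:
    def __init__(self):
        self.params: dict = {}
        self._mask: np.ndarray | None = None

    def forward(self, params: dict, x: np.ndarray, cache: bool = True) -> np.ndarray:
        mask = x > 0
        if cache:
            self._mask = mask
        return x * mask

    def backward(self, params: dict, grads: dict, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MLP:
    """Stack of [Dense -> LayerNorm -> ReLU] blocks followed by nothing.

    Output heads are attached by the caller so that one trunk can feed
    several linear heads (e.g. mean and log-variance of a Gaussian).
    """

    def __init__(self, name: str, n_in: int, width: int, depth: int, rng: np.random.Generator):
        self.layers: list = []
        d = n_in
        for i in range(depth):
            self.layers.append(Dense(f"{name}.fc{i}", d, width, rng))
            self.layers.append(LayerNorm(f"{name}.ln{i}", width))
            self.layers.append(ReLU())
            d = width
        self.n_out = d

    @property
    def params(self) -> dict:
        out: dict = {}
        for layer in self.layers:
            out.update(layer.params)
        return out

    def forward(self, params: dict, x: np.ndarray, cache: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(params, x, cache=cache)
        return x

    def backward(self, params: dict, grads: dict, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(params, grads, gy)
        return gy


class Adam:
    """Adam over a parameter dict; keys absent from ``trainable`` never move.

    Fresh moment estimates per instance, so constructing a new optimizer for
    a new training phase (e.g. query mapping) guarantees frozen entries stay
    bitwise identical as long as their gradients are zeroed or omitted.
    """

    def __init__(self, trainable: set[str], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.trainable = set(trainable)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k in self.trainable:
            g = grads.get(k)
            if g is None:
                continue
            m = self.m.get(k, 0.0)
            v = self.v.get(k, 0.0)
            m = self.b1 * m + (1 - self.b1) * g
            v = self.b2 * v + (1 - self.b2) * (g * g)
            self.m[k], self.v[k] = m, v
            params[k] = params[k] - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
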