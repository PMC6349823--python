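"""Minimal feed-forward network machinery used by every learned component.

All function approximators in this package share one architectural motif: a
stack of fully connected ReLU layers whose output is complemented by a single
linear *residual* layer applied to the raw input, followed by one or more
linear output heads.  The networks are small (4-dimensional inputs, a few
hundred hidden units), so forward and backward passes are written directly in
numpy; gradients are analytic and are cross-checked against finite
differences in the test suite.

Weights follow Xavier (Glorot) uniform initialisation; optimisation uses Adam
with in-place parameter updates so that optimizer state stays attached to the
arrays it manages.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "xavier_uniform",
    "relu",
    "softplus",
    "sigmoid",
    "Linear",
    "ResidualMLP",
    "Adam",
    "collect_parameters",
]


def xavier_uniform(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    """Glorot uniform sample of shape (d_in, d_out)."""
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Linear:
    """Affine layer y = x W + b with accumulated gradients."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, name: str = "linear"):
        self.name = name
        self.W = xavier_uniform(rng, d_in, d_out)
        self.b = np.zeros(d_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W + self.b

    def backward(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients for upstream gradient ``g``; return dL/dx."""
        self.gW += x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T

    def zero_grad(self) -> None:
        self.gW[...] = 0.0
        self.gb[...] = 0.0

    def parameters(self):
        yield (f"{self.name}.W", self.W, self.gW)
        yield (f"{self.name}.b", self.b, self.gb)


class ResidualMLP:
    """``n_layers`` ReLU layers plus a single linear residual from the input.

    out = ReLU(L_n(... ReLU(L_1(x)))) + R(x)
    """

    def __init__(self, rng: np.random.Generator, d_in: int, width: int, n_layers: int,
                 name: str = "trunk"):
        self.name = name
        self.layers = []
        d = d_in
        for i in range(n_layers):
            self.layers.append(Linear(rng, d, width, name=f"{name}.fc{i}"))
            d = width
        self.res = Linear(rng, d_in, width, name=f"{name}.res")

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        h = x
        if cache is not None:
            cache.append(x)
        for layer in self.layers:
            h = relu(layer.forward(h))
            if cache is not None:
                cache.append(h)
        out = h + self.res.forward(x)
        return out

    def backward(self, cache: list, g: np.ndarray) -> np.ndarray:
        """Backprop ``g`` (N, width) through the trunk; returns dL/dx."""
        x = cache[0]
        gx = self.res.backward(x, g)
        gh = g
        for i in range(len(self.layers) - 1, -1, -1):
            h_out = cache[i + 1]
            gz = gh * (h_out > 0)
            gh = self.layers[i].backward(cache[i], gz)
        return gx + gh

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()
        self.res.zero_grad()

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()
        yield from self.res.parameters()


def collect_parameters(*modules):
    """Flatten (name, param, grad) triples from several layers/trunks."""
    out = []
    for m in modules:
        out.extend(m.parameters())
    return out


class Adam:
    """Adam on a fixed list of (name, param, grad) triples; updates in place."""

    def __init__(self, triples, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.triples = list(triples)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in self.triples]
        self.v = [np.zeros_like(p) for _, p, _ in self.triples]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (_, p, g), m, v in zip(self.triples, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SGD:
    """Plain gradient descent on (name, param, grad) triples."""

    def __init__(self, triples, lr: float = 1e-2):
        self.triples = list(triples)
        self.lr = lr

    def step(self) -> None:
        for _, p, g in self.triples:
            p -= self.lr * g


def save_checkpoint(path, model, **metadata) -> None:
    """Save a model's parameter arrays plus metadata in one npz archive."""
    arrays = {name: p for name, p, _ in model.parameters()}
    arrays["_metadata"] = np.array(
        [f"{k}={v}" for k, v in sorted(metadata.items())], dtype=object)
    np.savez(path, **arrays, allow_pickle=True)


def load_checkpoint(path, model) -> dict:
    """Load parameters into ``model`` in place; returns the metadata dict."""
    z = np.load(path, allow_pickle=True)
    for name, p, _ in model.parameters():
        np.copyto(p, z[name])
    meta = {}
    for item in z.get("_metadata", np.array([], dtype=object)):
        k, _, v = str(item).partition("=")
        meta[k] = v
    return meta
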