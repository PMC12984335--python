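"""Minimal feed-forward neural-network primitives on numpy.

Implements exactly the layer set the fusion autoencoder needs — linear,
batch normalization, ReLU, inverted dropout — with hand-written backward
passes and an Adam optimizer. Every layer caches its forward inputs, so one
``forward(train=True)`` followed by ``backward`` in reverse order yields
gradients; the gradient of each parameter accumulates into ``.grads`` until
``zero_grad``. Correctness of the analytic gradients is pinned by a
finite-difference oracle in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Linear", "BatchNorm1d", "ReLU", "Dropout", "Block", "Adam", "softmax"]


class Module:
    """Base: parameters stored as dict name -> array, grads mirror them."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def _register(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Module):
    """Affine map with Kaiming-uniform init: W, b ~ U(±1/sqrt(fan_in))."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        bound = 1.0 / np.sqrt(in_dim)
        self._register("W", rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self._register("b", rng.uniform(-bound, bound, size=out_dim))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ gout
        self.grads["b"] += gout.sum(axis=0)
        return gout @ self.params["W"].T


class BatchNorm1d(Module):
    """Per-feature batch normalization with running statistics for eval mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self._register("gamma", np.ones(dim))
        self._register("beta", np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self._invstd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._invstd
            n = x.shape[0]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            return self._xhat * self.params["gamma"] + self.params["beta"]
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        n = gout.shape[0]
        self.grads["gamma"] += (gout * xhat).sum(axis=0)
        self.grads["beta"] += gout.sum(axis=0)
        gxhat = gout * self.params["gamma"]
        return (invstd / n) * (
            n * gxhat - gxhat.sum(axis=0) - xhat * (gxhat * xhat).sum(axis=0)
        )


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout if self._mask is None else gout * self._mask


class Block(Module):
    """Encoder/decoder block: linear -> batch norm -> ReLU -> dropout."""

    def __init__(self, in_dim: int, out_dim: int, dropout: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.layers = [
            Linear(in_dim, out_dim, rng),
            BatchNorm1d(out_dim),
            ReLU(),
            Dropout(dropout, rng),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def modules(self) -> list[Module]:
        return list(self.layers)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam over a list of Modules (standard bias-corrected moments)."""

    def __init__(
        self,
        modules: list[Module],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.modules = modules
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in mod.params.items()} for mod in modules
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in mod.params.items()} for mod in modules
        ]

    def zero_grad(self) -> None:
        for mod in self.modules:
            mod.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for mod, m, v in zip(self.modules, self._m, self._v):
            for k, p in mod.params.items():
                g = mod.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
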