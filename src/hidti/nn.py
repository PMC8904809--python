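"""Minimal feed-forward neural network engine.

Implements exactly the pieces the DTI models need — dense layers, ReLU,
layer normalization with biased variance, inverted dropout, Adam — with
hand-written backpropagation on numpy arrays.  All randomness flows
through explicit ``numpy.random.Generator`` objects so that training is
bit-reproducible from a seed on a fixed platform.

Conventions
-----------
* Inputs are row-major batches ``X`` of shape ``(n, d)``; a single vector
  may be passed as shape ``(d,)`` and is promoted internally.
* Weight matrices are stored as ``(in_dim, out_dim)`` so the forward map
  is ``X @ W + b``.
* Initialization is uniform fan-in scaling: ``U(-1/sqrt(in), 1/sqrt(in))``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Linear",
    "ReLU",
    "LayerNorm",
    "Dropout",
    "Sequential",
    "Adam",
    "sigmoid",
    "binary_cross_entropy",
]

EPS_CLAMP = 1e-7


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binary_cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross entropy with probabilities clamped to [1e-7, 1-1e-7].

    Loss per element: ``-t*log(p) - (1-t)*log(1-p)``, averaged over all
    elements of the batch.
    """
    probs = np.asarray(probs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if probs.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: probs {probs.shape} vs targets {targets.shape}"
        )
    p = np.clip(probs, EPS_CLAMP, 1.0 - EPS_CLAMP)
    return float(np.mean(-targets * np.log(p) - (1.0 - targets) * np.log(1.0 - p)))


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base class: stateless API of forward/backward plus parameter listing."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        if in_dim <= 0 or out_dim <= 0:
            raise ValueError("layer dimensions must be positive")
        bound = 1.0 / np.sqrt(in_dim)
        self.W = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.b = Parameter(rng.uniform(-bound, bound, size=out_dim))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.W.value.shape[0]:
            raise ValueError(
                f"input width {x.shape[-1]} != expected {self.W.value.shape[0]}"
            )
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class LayerNorm(Layer):
    """Normalization over the feature axis with biased (population) variance.

    ``y = gain * (x - mean) / sqrt(var + eps) + bias`` where mean/var are
    taken per sample across features.
    """

    def __init__(self, dim: int, eps: float = 1e-5):
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gain, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)  # biased
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._xhat, self._inv_std = xhat, inv_std
        return self.gain.value * xhat + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.gain.grad += (dout * xhat).sum(axis=0)
        self.bias.grad += dout.sum(axis=0)
        dxhat = dout * self.gain.value
        # standard layer-norm backward for biased variance
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv_std * (dxhat - m1 - xhat * m2)


class Dropout(Layer):
    """Inverted dropout: active only when ``train=True``.

    The mask generator must be assigned (``layer.rng = ...``) by the
    training loop before any training-mode forward pass; inference never
    touches randomness.
    """

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_state(layers: Layer | list[Layer]) -> list[np.ndarray]:
    """Snapshot parameter values (deep copies) for best-weight restoration."""
    if isinstance(layers, Layer):
        layers = [layers]
    return [p.value.copy() for layer in layers for p in layer.parameters()]


def set_state(layers: Layer | list[Layer], state: list[np.ndarray]) -> None:
    if isinstance(layers, Layer):
        layers = [layers]
    params = [p for layer in layers for p in layer.parameters()]
    if len(params) != len(state):
        raise ValueError("state length mismatch")
    for p, s in zip(params, state):
        p.value[...] = s
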