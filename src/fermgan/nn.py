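"""A small dense-network stack with manual backpropagation.

The adversarial model and the surrogate regressor in this package are tiny
fully connected networks (a few hundred to ~1200 trainable parameters), so
the forward/backward passes are written directly in numpy: Dense layers with
selectable activations and L1 weight / L1 bias / L2 activity regularisation,
batch normalisation, inverted dropout, He/Glorot uniform initialisation, and
an Adam optimiser with optional global gradient-norm clipping.

Conventions follow the common deep-learning toolkits: losses are means over
all output elements, weight regularisation penalties are summed (not averaged
over the batch) while activity penalties are averaged over the batch, and
batch normalisation keeps exponential running moments for inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------

ACTIVATIONS = ("relu", "sigmoid", "tanh", "softmax", "linear")


def _act_forward(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "tanh":
        return np.tanh(z)
    if name == "softmax":
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)
    if name == "linear":
        return z
    raise ValueError(f"unknown activation {name!r}")


def _act_backward(name: str, z: np.ndarray, a: np.ndarray, grad_a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return grad_a * (z > 0.0)
    if name == "sigmoid":
        return grad_a * a * (1.0 - a)
    if name == "tanh":
        return grad_a * (1.0 - a * a)
    if name == "softmax":
        # full softmax Jacobian: J^T g = a * (g - <g, a>)
        dot = np.sum(grad_a * a, axis=1, keepdims=True)
        return a * (grad_a - dot)
    if name == "linear":
        return grad_a
    raise ValueError(f"unknown activation {name!r}")


def _init_kernel(name: str, fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    if name == "he_uniform":
        limit = np.sqrt(6.0 / fan_in)
    elif name == "glorot_uniform":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
    else:
        raise ValueError(f"unknown initializer {name!r}")
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Dense:
    """Fully connected layer with built-in activation and regularisers."""

    def __init__(
        self,
        in_dim: int,
        units: int,
        activation: str = "linear",
        kernel_init: str = "glorot_uniform",
        l1_kernel: float = 0.0,
        l1_bias: float = 0.0,
        l2_activity: float = 0.0,
    ) -> None:
        if units < 1:
            raise ValueError("units must be >= 1")
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        if min(l1_kernel, l1_bias, l2_activity) < 0:
            raise ValueError("regularizer coefficients must be >= 0")
        self.in_dim = in_dim
        self.units = units
        self.activation = activation
        self.kernel_init = kernel_init
        self.l1_kernel = l1_kernel
        self.l1_bias = l1_bias
        self.l2_activity = l2_activity
        self.W: np.ndarray | None = None
        self.b: np.ndarray | None = None
        self.gW = self.gb = None
        self._cache: tuple | None = None

    @property
    def out_dim(self) -> int:
        return self.units

    def init_params(self, rng: np.random.Generator) -> None:
        self.W = _init_kernel(self.kernel_init, self.in_dim, self.units, rng)
        self.b = np.zeros(self.units)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.gb]

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        z = x @ self.W + self.b
        a = _act_forward(self.activation, z)
        self._cache = (x, z, a)
        return a

    def backward(self, grad_a: np.ndarray) -> np.ndarray:
        x, z, a = self._cache
        n = x.shape[0]
        if self.l2_activity:
            grad_a = grad_a + (2.0 * self.l2_activity / n) * a
        grad_z = _act_backward(self.activation, z, a, grad_a)
        self.gW = x.T @ grad_z
        self.gb = grad_z.sum(axis=0)
        if self.l1_kernel:
            self.gW = self.gW + self.l1_kernel * np.sign(self.W)
        if self.l1_bias:
            self.gb = self.gb + self.l1_bias * np.sign(self.b)
        return grad_z @ self.W.T

    def reg_loss(self) -> float:
        loss = self.l1_kernel * np.abs(self.W).sum() + self.l1_bias * np.abs(self.b).sum()
        if self.l2_activity and self._cache is not None:
            x, _, a = self._cache
            loss += self.l2_activity * float((a * a).sum()) / x.shape[0]
        return float(loss)


class BatchNorm:
    """Batch normalisation with exponential running moments for inference."""

    def __init__(self, dim: int, momentum: float = 0.99, eps: float = 1e-3) -> None:
        self.dim = dim
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.g_gamma = self.g_beta = None
        self._cache: tuple | None = None

    @property
    def out_dim(self) -> int:
        return self.dim

    def init_params(self, rng: np.random.Generator) -> None:
        pass  # gamma/beta initialised deterministically

    @property
    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.g_gamma, self.g_beta]

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xn = (x - mu) * inv_std
        self._cache = (xn, inv_std, training, x.shape[0])
        return self.gamma * xn + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xn, inv_std, training, n = self._cache
        self.g_gamma = (grad * xn).sum(axis=0)
        self.g_beta = grad.sum(axis=0)
        g_xn = grad * self.gamma
        if not training:
            return g_xn * inv_std
        # full batch-statistics backward
        return (
            inv_std / n * (n * g_xn - g_xn.sum(axis=0) - xn * (g_xn * xn).sum(axis=0))
        )

    def reg_loss(self) -> float:
        return 0.0


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def init_params(self, rng: np.random.Generator) -> None:
        pass

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask

    def reg_loss(self) -> float:
        return 0.0


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------


class Network:
    """An ordered stack of layers with shared RNG for dropout sampling."""

    def __init__(self, layers: Sequence, seed: int | None = 0, name: str = "net") -> None:
        self.layers = list(layers)
        self.name = name
        self.rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init_params(self.rng)

    # -- passes -------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=float)
        for layer in self.layers:
            out = layer.forward(out, training, self.rng)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        grad = grad_out
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    # -- parameter access ---------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def set_params(self, values: Sequence[np.ndarray]) -> None:
        flat = list(values)
        i = 0
        for layer in self.layers:
            for j, p in enumerate(layer.params):
                p[...] = flat[i]
                i += 1

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def layer_param_counts(self) -> list[int]:
        return [sum(p.size for p in layer.params) for layer in self.layers]

    def reg_loss(self) -> float:
        return float(sum(layer.reg_loss() for layer in self.layers))

    # -- serialisation ------------------------------------------------------
    def state_dict(self) -> dict:
        state: dict = {"name": self.name, "params": [p.tolist() for p in self.params]}
        bn = [
            {"mean": l.running_mean.tolist(), "var": l.running_var.tolist()}
            for l in self.layers
            if isinstance(l, BatchNorm)
        ]
        state["batch_norm_moments"] = bn
        return state

    def load_state_dict(self, state: dict) -> None:
        self.set_params([np.asarray(p, float) for p in state["params"]])
        moments = iter(state.get("batch_norm_moments", []))
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                m = next(moments)
                layer.running_mean = np.asarray(m["mean"], float)
                layer.running_var = np.asarray(m["var"], float)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.state_dict()))

    def load(self, path: str | Path) -> None:
        self.load_state_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

_EPS = 1e-7


def binary_cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean BCE over all elements and its gradient w.r.t. predictions."""
    p = np.clip(y_pred, _EPS, 1.0 - _EPS)
    loss = float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))
    grad = (p - y_true) / (p * (1.0 - p)) / p.size
    return loss, grad


def mean_squared_error(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements and its gradient."""
    diff = y_pred - y_true
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OptimizerSpec:
    """Adam settings; ``clipnorm`` clips the global gradient norm if set."""

    learning_rate: float = 1e-3
    beta_1: float = 0.9
    beta_2: float = 0.999
    epsilon: float = 1e-7
    clipnorm: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.beta_1 < 1 and 0 < self.beta_2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        if self.clipnorm is not None and self.clipnorm <= 0:
            raise ValueError("clipnorm must be > 0")


class Adam:
    """Adam with bias correction and optional global-norm gradient clipping."""

    def __init__(self, spec: OptimizerSpec) -> None:
        self.spec = spec
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        s = self.spec
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        if s.clipnorm is not None:
            norm = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
            if norm > s.clipnorm:
                grads = [g * (s.clipnorm / norm) for g in grads]
        self.t += 1
        bc1 = 1.0 - s.beta_1**self.t
        bc2 = 1.0 - s.beta_2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= s.beta_1
            m += (1.0 - s.beta_1) * g
            v *= s.beta_2
            v += (1.0 - s.beta_2) * g * g
            p -= s.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + s.epsilon)
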