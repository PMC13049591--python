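"""Base layer protocol, elementwise layers, dense layer, batch norm, and the
network container. Shapes are per-sample (batch axis excluded) everywhere in
``build``; gradients accumulate into ``layer.g`` mirroring ``layer.p``."""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "Layer", "Dense", "ReLU", "ELU", "Dropout", "BatchNorm",
    "Flatten", "Reshape", "Transpose", "Network", "glorot",
]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class Layer:
    """A differentiable transform with named parameters ``p`` / grads ``g``."""

    name: str = ""

    def __init__(self) -> None:
        self.p: dict[str, np.ndarray] = {}
        self.g: dict[str, np.ndarray] = {}

    def build(self, in_shape: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
        """Allocate parameters for per-sample ``in_shape``; return out shape."""
        return in_shape

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.g = {k: np.zeros_like(v) for k, v in self.p.items()}

    def n_params(self) -> int:
        return int(sum(v.size for v in self.p.values()))

    def get_state(self) -> dict[str, np.ndarray]:
        """Snapshot of parameters plus any non-trainable running state."""
        return copy.deepcopy(self.p)

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.p:
            self.p[k][...] = state[k]


class Dense(Layer):
    """Affine map along the last axis (works on (N, F) and (N, T, F) inputs)."""

    def __init__(self, units: int, name: str = "dense") -> None:
        super().__init__()
        self.units = units
        self.name = name

    def build(self, in_shape, rng):
        f = in_shape[-1]
        self.p = {
            "W": glorot(rng, (f, self.units), f, self.units),
            "b": np.zeros(self.units),
        }
        self.zero_grad()
        return in_shape[:-1] + (self.units,)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.p["W"] + self.p["b"]

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.g["W"] += x2.T @ dy2
        self.g["b"] += dy2.sum(axis=0)
        return dy @ self.p["W"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=False):
        self._neg = x <= 0
        self._expm = self.alpha * np.expm1(np.minimum(x, 0.0))
        return np.where(self._neg, self._expm, x)

    def backward(self, dy):
        return dy * np.where(self._neg, self._expm + self.alpha, 1.0)


class Dropout(Layer):
    """Inverted dropout; identity at inference. Draws from the build rng."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def build(self, in_shape, rng):
        self.rng = rng
        return in_shape

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm(Layer):
    """Batch normalization over all axes except the feature axis."""

    def __init__(self, feature_axis: int = 1, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.axis = feature_axis
        self.momentum = momentum
        self.eps = eps

    def build(self, in_shape, rng):
        # in_shape is per-sample; feature axis 1 in batch coords = axis 0 here
        c = in_shape[self.axis - 1] if self.axis >= 1 else in_shape[self.axis]
        self._bshape = [1] * (len(in_shape) + 1)
        self._bshape[self.axis] = c
        self.p = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.zero_grad()
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        return in_shape

    def _reduce_axes(self, ndim: int) -> tuple[int, ...]:
        return tuple(a for a in range(ndim) if a != self.axis)

    def forward(self, x, train=False):
        axes = self._reduce_axes(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = self._bshape
        self._inv = 1.0 / np.sqrt(var.reshape(shape) + self.eps)
        self._xhat = (x - mean.reshape(shape)) * self._inv
        self._m = x.size // x.shape[self.axis]
        self._train = train
        return self.p["gamma"].reshape(shape) * self._xhat + self.p["beta"].reshape(shape)

    def backward(self, dy):
        axes = self._reduce_axes(dy.ndim)
        shape = self._bshape
        self.g["gamma"] += (dy * self._xhat).sum(axis=axes)
        self.g["beta"] += dy.sum(axis=axes)
        gam = self.p["gamma"].reshape(shape)
        if not self._train:
            return dy * gam * self._inv
        m = self._m
        dxhat = dy * gam
        term = dxhat - dxhat.mean(axis=axes, keepdims=True) \
            - self._xhat * (dxhat * self._xhat).sum(axis=axes, keepdims=True) / m
        return term * self._inv

    def get_state(self):
        state = copy.deepcopy(self.p)
        state["_running_mean"] = self.running_mean.copy()
        state["_running_var"] = self.running_var.copy()
        return state

    def set_state(self, state):
        for k in self.p:
            self.p[k][...] = state[k]
        self.running_mean = state["_running_mean"].copy()
        self.running_var = state["_running_var"].copy()


class Flatten(Layer):
    def build(self, in_shape, rng):
        self._in = in_shape
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    """Reshape the per-sample trailing axes to ``target`` (batch preserved)."""

    def __init__(self, target: tuple[int, ...]) -> None:
        super().__init__()
        self.target = target

    def build(self, in_shape, rng):
        if int(np.prod(in_shape)) != int(np.prod(self.target)):
            raise ValueError(f"cannot reshape {in_shape} to {self.target}")
        return self.target

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Transpose(Layer):
    """Permute per-sample axes; ``perm`` indexes the per-sample shape."""

    def __init__(self, perm: tuple[int, ...]) -> None:
        super().__init__()
        self.perm = perm

    def build(self, in_shape, rng):
        return tuple(in_shape[i] for i in self.perm)

    def forward(self, x, train=False):
        full = (0,) + tuple(p + 1 for p in self.perm)
        self._inv = np.argsort(full)
        return x.transpose(full)

    def backward(self, dy):
        return dy.transpose(self._inv)


class Network:
    """An ordered chain of layers with seeded initialization."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...], seed: int = 0) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            try:
                shape = layer.build(shape, rng)
            except Exception as exc:
                raise type(exc)(
                    f"building layer {layer.name or type(layer).__name__}: {exc}"
                ) from exc
        self.output_shape = shape

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self) -> list[np.ndarray]:
        return [v for layer in self.layers for v in layer.p.values()]

    def gradients(self) -> list[np.ndarray]:
        return [v for layer in self.layers for v in layer.g.values()]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [layer.get_state() for layer in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            layer.set_state(w)
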