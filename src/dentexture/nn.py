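"""Minimal CNN engine: layers, softmax cross-entropy, and Adam.

A compact, fully deterministic numpy implementation sized for small
grayscale-image classifiers: 2D convolution (same padding) via im2col,
non-overlapping max pooling, inverted dropout, dense layers, ReLU, and a
softmax cross-entropy head. Forward/backward passes operate on
``(batch, height, width, channels)`` float32 tensors; dense layers on
``(batch, features)``.

Weight initialization is He-normal, drawn from the generator passed to
``Network.initialize`` so training runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError


class Layer:
    """Base layer: stateless unless it declares ``params``."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())


class Input(Layer):
    def __init__(self, shape: tuple[int, int, int]):
        super().__init__()
        self.shape = shape

    def forward(self, x, training, rng):
        if x.shape[1:] != self.shape:
            raise ParameterError(f"expected input {self.shape}, got {x.shape[1:]}")
        return x

    def backward(self, grad):
        return grad


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) zero-padded to same -> (B,H,W,k*k*C) patch matrix."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, k - 1 - p), (p, k - 1 - p), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # windows: (B, H, W, C, k, k) -> (B, H, W, k, k, C)
    windows = windows.transpose(0, 1, 2, 4, 5, 3)
    b, h, w = x.shape[0], x.shape[1], x.shape[2]
    return np.ascontiguousarray(windows).reshape(b, h, w, -1)


class Conv2D(Layer):
    """3x3-style convolution, stride 1, zero 'same' padding, ReLU optional."""

    def __init__(self, filters: int, kernel_size: int, relu: bool = True):
        super().__init__()
        self.f = filters
        self.k = kernel_size
        self.relu = relu
        self.in_channels: int | None = None

    def build(self, in_channels: int):
        self.in_channels = in_channels
        self.params = {
            "W": np.zeros((self.k * self.k * in_channels, self.f), dtype=np.float32),
            "b": np.zeros(self.f, dtype=np.float32),
        }

    def initialize(self, rng):
        fan_in = self.k * self.k * self.in_channels
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), self.params["W"].shape
        ).astype(np.float32)
        self.params["b"][:] = 0.0

    def forward(self, x, training, rng):
        cols = _im2col(x, self.k)  # (B,H,W,kkC)
        z = cols @ self.params["W"] + self.params["b"]
        self._cols = cols
        if self.relu:
            self._mask = z > 0
            z = np.maximum(z, 0)
        return z

    def backward(self, grad):
        if self.relu:
            grad = grad * self._mask
        b, h, w, _ = grad.shape
        g2 = grad.reshape(-1, self.f)
        cols2 = self._cols.reshape(-1, self.k * self.k * self.in_channels)
        self.grads = {"W": cols2.T @ g2, "b": g2.sum(axis=0)}
        # scatter gradient back through im2col (col2im)
        gc = (g2 @ self.params["W"].T).reshape(
            b, h, w, self.k, self.k, self.in_channels
        )
        p = self.k // 2
        hp, wp = h + self.k - 1, w + self.k - 1
        gx = np.zeros((b, hp, wp, self.in_channels), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                gx[:, i : i + h, j : j + w, :] += gc[:, :, :, i, j, :]
        return gx[:, p : p + h, p : p + w, :]


class MaxPool2D(Layer):
    """Non-overlapping pooling; input dims must divide by the pool size."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.s = size

    def forward(self, x, training, rng):
        b, h, w, c = x.shape
        s = self.s
        if h % s or w % s:
            raise ParameterError(f"pooling {s} does not divide input {h}x{w}")
        xr = x.reshape(b, h // s, s, w // s, s, c)
        out = xr.max(axis=(2, 4))
        m = xr == out[:, :, None, :, None, :]
        # break ties toward a single winner so the gradient is not duplicated
        mt = m.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // s, w // s, s * s, c)
        mt = mt & (np.cumsum(mt, axis=3) == 1)
        self._mask = mt.reshape(b, h // s, w // s, s, s, c).transpose(0, 1, 3, 2, 4, 5)
        return out

    def backward(self, grad):
        b, hh, ww, c = grad.shape
        g = grad[:, :, None, :, None, :] * self._mask
        return g.reshape(b, hh * self.s, ww * self.s, c)


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ParameterError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, units: int, relu: bool = True):
        super().__init__()
        self.units = units
        self.relu = relu
        self.in_features: int | None = None

    def build(self, in_features: int):
        self.in_features = in_features
        self.params = {
            "W": np.zeros((in_features, self.units), dtype=np.float32),
            "b": np.zeros(self.units, dtype=np.float32),
        }

    def initialize(self, rng):
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / self.in_features), self.params["W"].shape
        ).astype(np.float32)
        self.params["b"][:] = 0.0

    def forward(self, x, training, rng):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.relu:
            self._mask = z > 0
            z = np.maximum(z, 0)
        return z

    def backward(self, grad):
        if self.relu:
            grad = grad * self._mask
        self.grads = {"W": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.params["W"].T


class Softmax(Layer):
    """Softmax output; pairs with cross-entropy so backward expects
    (probabilities - one_hot) to be passed straight through."""

    def forward(self, x, training, rng):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, grad):
        return grad


class Network:
    """A plain sequential stack with named layers."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers
        self._built = False

    @property
    def layer_names(self) -> list[str]:
        return [name for name, _ in self.layers]

    def build(self, input_shape: tuple[int, int, int]) -> None:
        shape: tuple = input_shape
        for _, layer in self.layers:
            if isinstance(layer, Conv2D):
                layer.build(shape[2])
                shape = (shape[0], shape[1], layer.f)
            elif isinstance(layer, MaxPool2D):
                if shape[0] % layer.s or shape[1] % layer.s:
                    raise ParameterError(
                        f"pool size {layer.s} incompatible with feature map {shape}"
                    )
                shape = (shape[0] // layer.s, shape[1] // layer.s, shape[2])
            elif isinstance(layer, Flatten):
                shape = (int(np.prod(shape)),)
            elif isinstance(layer, Dense):
                if len(shape) != 1:
                    raise ParameterError("dense layer requires flattened input")
                layer.build(shape[0])
                shape = (layer.units,)
        self._built = True

    def initialize(self, rng: np.random.Generator) -> None:
        if not self._built:
            raise ParameterError("build() the network before initializing")
        for _, layer in self.layers:
            layer.initialize(rng)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng()
        out = x.astype(np.float32)
        for _, layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, grad: np.ndarray) -> None:
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)

    def n_params(self) -> int:
        return sum(layer.n_params() for _, layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for _, l in self.layers for p in l.params.values()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for _, l in self.layers:
            for k in l.params:
                l.params[k] = next(it).copy()


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy against integer labels."""
    p = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.clip(p, 1e-12, None)).mean())


class Adam:
    def __init__(self, network: Network, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.net = network
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, l in network.layers for p in l.params.values()]
        self.v = [np.zeros_like(p) for _, l in network.layers for p in l.params.values()]

    def step(self) -> None:
        self.t += 1
        i = 0
        for _, layer in self.net.layers:
            for key in layer.params:
                g = layer.grads.get(key)
                if g is None:
                    i += 1
                    continue
                g = g.astype(np.float32)
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1**self.t)
                vhat = self.v[i] / (1 - self.b2**self.t)
                layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1
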