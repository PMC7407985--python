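"""Minimal feed-forward building blocks with explicit backpropagation.

Layers store their parameters and, after ``backward``, the matching gradients.
Convolutional tensors use channels-last layout ``(N, H, W, C)``.  Everything
is plain NumPy; correctness of every analytic gradient is pinned by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Dropout",
    "BatchNorm",
    "Conv2D",
    "MaxPool2D",
    "Flatten",
    "softmax",
    "softmax_cross_entropy",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Layer:
    """Base layer: ``params``/``grads`` are dicts of same-keyed arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map with He-scaled Gaussian initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params = {
            "w": (rng.standard_normal((d_in, d_out)) * scale).astype(dtype),
            "b": np.zeros(d_out, dtype=dtype),
        }

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"w": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["w"].T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (features/channels).

    Running statistics (momentum 0.9) are used at inference.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(n_features, dtype=dtype),
            "beta": np.zeros(n_features, dtype=dtype),
        }
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(x.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = float(np.prod([x.shape[a] for a in axes])) if training else None
        self._inv_sd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_sd
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = self._axes
        gamma = self.params["gamma"]
        self.grads = {
            "gamma": (dy * self._xhat).sum(axis=axes),
            "beta": dy.sum(axis=axes),
        }
        dxhat = dy * gamma
        if self._m is None:  # inference-mode backward (fixed statistics)
            return dxhat * self._inv_sd
        m = self._m
        return (
            self._inv_sd
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        )


class Conv2D(Layer):
    """Valid-padding 2-D convolution (cross-correlation), channels-last."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kh: int,
        kw: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        scale = np.sqrt(2.0 / (kh * kw * c_in))
        self.params = {
            "w": (rng.standard_normal((kh * kw * c_in, c_out)) * scale).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }

    def forward(self, x, training=False):
        n, h, w, _ = x.shape
        kh, kw = self.kh, self.kw
        ho, wo = h - kh + 1, w - kw + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
        # (N, Ho, Wo, C, kh, kw) -> (N*Ho*Wo, kh*kw*C)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, kh * kw * self.c_in)
        self._cols, self._xshape, self._out_hw = cols, x.shape, (ho, wo)
        out = cols @ self.params["w"] + self.params["b"]
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, dy):
        n, h, w, _ = self._xshape
        ho, wo = self._out_hw
        kh, kw = self.kh, self.kw
        dy_flat = dy.reshape(n * ho * wo, self.c_out)
        self.grads = {"w": self._cols.T @ dy_flat, "b": dy_flat.sum(axis=0)}
        dcols = (dy_flat @ self.params["w"].T).reshape(n, ho, wo, kh, kw, self.c_in)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        for i in range(kh):
            for j in range(kw):
                dx[:, i:i + ho, j:j + wo, :] += dcols[:, :, :, i, j, :]
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing remainder rows/cols are trimmed."""

    def __init__(self, ph: int, pw: int) -> None:
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        ph, pw = self.ph, self.pw
        hp, wp = h // ph, w // pw
        xt = x[:, : hp * ph, : wp * pw, :]
        blocks = (
            xt.reshape(n, hp, ph, wp, pw, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, hp, wp, c, ph * pw)
        )
        self._argmax = blocks.argmax(axis=-1)
        self._xshape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dy):
        n, h, w, c = self._xshape
        ph, pw = self.ph, self.pw
        hp, wp = h // ph, w // pw
        dblocks = np.zeros((n, hp, wp, c, ph * pw), dtype=dy.dtype)
        np.put_along_axis(dblocks, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        dx[:, : hp * ph, : wp * pw, :] = (
            dblocks.reshape(n, hp, wp, c, ph, pw)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, hp * ph, wp * pw, c)
        )
        return dx


class Reshape(Layer):
    """Reshape trailing dimensions, keeping the batch axis."""

    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)
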