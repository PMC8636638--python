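"""Minimal CNN engine used by the count regressor.

Implements just the layers needed for a small convolutional regression
network on greyscale images — 3x3 same-padding convolution (via im2col),
ReLU, 2x2 max pooling, global average pooling and dense layers — together
with reverse-mode gradients and an Adam optimiser.  Everything is plain
``float32`` NumPy, so runs are bit-deterministic for a fixed seed and the
engine stays fast enough for desk-scale training at 64x64 resolution.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
]


class Layer:
    """Base class: a differentiable map with named parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv2d(Layer):
    """3x3 (or kxk) convolution, stride 1, zero same-padding.

    Weights are stored flattened as (C_out, C_in*k*k) so both passes reduce
    to one large matmul over im2col patches.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same-padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        # He initialisation, appropriate for the ReLU nonlinearity that follows
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(c_out, dtype=np.float32)}
        self.zero_grad()
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # (B,C,H,W,k,k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * self.k * self.k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        y = cols @ self.params["W"].T + self.params["b"]
        if train:
            self._cols = cols
            self._xshape = (b, c, h, w)
        return y.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cols is None or self._xshape is None:
            raise RuntimeError("backward called before a training-mode forward")
        b, c, h, w = self._xshape
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out))
        self.grads["W"] += dy_flat.T @ self._cols
        self.grads["b"] += dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.params["W"]).reshape(b, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        # scatter-add of the k*k shifted patch gradients (col2im)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called before a training-mode forward")
        return dy * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2x2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            mask = xr == y[:, :, :, None, :, None]
            # split gradient evenly among tied maxima so the pass stays exact
            self._mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
            self._shape = (b, c, h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None or self._shape is None:
            raise RuntimeError("backward called before a training-mode forward")
        b, c, h, w = self._shape
        dx = self._mask * dy[:, :, :, None, :, None]
        return dx.reshape(b, c, h, w).astype(np.float32)


class GlobalAvgPool(Layer):
    """(B,C,H,W) -> (B,C) spatial mean."""

    def __init__(self) -> None:
        super().__init__()
        self._hw: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._hw is None:
            raise RuntimeError("backward called before a training-mode forward")
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None] / (h * w), dy.shape + (h, w)).astype(np.float32)


class Dense(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        if zero_init:
            w = np.zeros((n_out, n_in))
        else:
            rng = rng or np.random.default_rng(0)
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(n_out, dtype=np.float32)}
        self.zero_grad()
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called before a training-mode forward")
        self.grads["W"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        self._outputs: list[np.ndarray] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = []
        for layer in self.layers:
            x = layer.forward(x, train=train)
            outs.append(x)
        if train:
            self._outputs = outs
        return x

    def backward(self, dy: np.ndarray, stop_at: int = 0) -> np.ndarray:
        """Propagate gradients down to (and including) layer index ``stop_at``.

        Returns the gradient flowing *into* layer ``stop_at``'s input when
        ``stop_at`` is 0, or into that layer otherwise; with ``stop_at > 0``
        earlier layers are untouched (used to skip frozen trunks and for
        grad-CAM, which only needs gradients at an intermediate activation).
        """
        for layer in reversed(self.layers[stop_at:]):
            dy = layer.backward(dy)
        return dy

    def output_of(self, index: int) -> np.ndarray:
        if self._outputs is None:
            raise RuntimeError("no cached activations; run forward(train=True) first")
        return self._outputs[index]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


class Adam:
    """Adam with decoupled (AdamW-style) weight decay and per-group LRs.

    ``param_groups`` is a list of dicts ``{"layers": [...], "lr": float}``;
    the per-step learning rate is ``lr * lr_scale`` where ``lr_scale`` comes
    from the one-cycle schedule.
    """

    def __init__(
        self,
        param_groups: list[dict],
        beta1: float = 0.9,
        beta2: float = 0.99,
        eps: float = 1e-5,
        weight_decay: float = 1e-2,
    ):
        self.param_groups = param_groups
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for group in self.param_groups:
            lr = group["lr"] * lr_scale
            if lr == 0.0:
                continue
            for layer in group["layers"]:
                for name, p in layer.params.items():
                    g = layer.grads[name]
                    key = id(p)
                    m = self._m.setdefault(key, np.zeros_like(p))
                    v = self._v.setdefault(key, np.zeros_like(p))
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g * g
                    mhat = m / (1 - b1**self.t)
                    vhat = v / (1 - b2**self.t)
                    if self.weight_decay and name == "W":
                        p *= 1.0 - lr * self.weight_decay
                    p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for group in self.param_groups:
            for layer in group["layers"]:
                layer.zero_grad()
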