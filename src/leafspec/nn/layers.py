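"""Minimal feed-forward layers with explicit backpropagation.

Everything here operates on plain numpy arrays.  Shapes follow the usual
1-D convolution convention: ``(batch, channels, length)`` for convolutional
layers and ``(batch, features)`` for fully connected ones.  Each layer
caches what its backward pass needs during ``forward(..., training=True)``;
gradients accumulate into ``layer.grads`` keyed like ``layer.params``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "Flatten",
    "AvgPool1d",
    "Linear",
    "Sequential",
]


class Layer:
    """Base class: a parameterised, differentiable array transform."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            if k in self.grads and self.grads[k].shape == v.shape:
                self.grads[k].fill(0)
            else:
                self.grads[k] = np.zeros_like(v)

    # -- persistence -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k][...] = state[k]


def _dilated_corr(x: np.ndarray, W: np.ndarray, dilation: int) -> np.ndarray:
    """'Same'-padded dilated cross-correlation.

    x: (N, C_in, L); W: (C_out, C_in, k) with k odd.  Returns (N, C_out, L).
    Implemented as an im2col gather followed by one batched matmul.
    """
    N, C, L = x.shape
    C_out, C_in, k = W.shape
    if C != C_in:
        raise ValueError(f"input has {C} channels, kernel expects {C_in}")
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    idx = np.arange(L)[None, :] + dilation * np.arange(k)[:, None]  # (k, L)
    cols = xp[:, :, idx]  # (N, C, k, L)
    cols2 = cols.reshape(N, C * k, L)
    y = np.matmul(W.reshape(C_out, C * k), cols2)  # (N, C_out, L)
    return y, cols2


class Conv1d(Layer):
    """Dilated 1-D convolution (cross-correlation), stride 1, 'same' zero padding.

    Output channel c_o is ``sum_ci W[c_o, c_i] * x[c_i] + b[c_o]`` where
    ``*`` slides the dilated kernel along the wavelength axis.  Zero padding
    keeps the sequence length fixed, which composes naturally with the
    spectral-trimming convention of zero-filled trimmed ends.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 5,
                 dilation: int = 2, rng=None, dtype=np.float32) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.dilation = dilation
        self.params = {
            "W": (rng.standard_normal((out_channels, in_channels, kernel_size)) * scale
                  ).astype(dtype),
            "b": np.zeros(out_channels, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x, training=False, rng=None):
        y, cols2 = _dilated_corr(x, self.params["W"], self.dilation)
        y += self.params["b"][:, None]
        self._cache = cols2 if training else None
        self._in_shape = x.shape
        return y

    def backward(self, dy):
        W = self.params["W"]
        C_out, C_in, k = W.shape
        cols2 = self._cache
        self.grads["b"] += dy.sum(axis=(0, 2))
        dW = np.tensordot(dy, cols2, axes=([0, 2], [0, 2]))  # (C_out, C_in*k)
        self.grads["W"] += dW.reshape(W.shape)
        # Gradient w.r.t. the input of a stride-1 'same' correlation is the
        # 'same' correlation of dy with the kernel flipped and transposed.
        W_t = np.flip(W, axis=2).transpose(1, 0, 2)  # (C_in, C_out, k)
        dx, _ = _dilated_corr(dy, np.ascontiguousarray(W_t), self.dilation)
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, length) with affine scale/shift."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False, rng=None):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv_std[:, None]
        if training:
            self._cache = (xhat, inv_std)
        return self.params["gamma"][:, None] * xhat + self.params["beta"][:, None]

    def backward(self, dy):
        xhat, inv_std = self._cache
        N, C, L = dy.shape
        m = N * L
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] += dy.sum(axis=(0, 2))
        dxhat = dy * self.params["gamma"][:, None]
        # Standard batch-norm input gradient, fused form.
        term = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True))
        return term * inv_std[:, None]

    def state_dict(self):
        state = super().state_dict()
        state["running_mean"] = self.running_mean.copy()
        state["running_var"] = self.running_var.copy()
        return state

    def load_state_dict(self, state):
        super().load_state_dict(state)
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity at inference."""

    def __init__(self, p: float = 0.2) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an RNG")
        self._mask = ((rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class AvgPool1d(Layer):
    """Non-overlapping mean pooling; pads by edge replication when needed."""

    def __init__(self, window: int = 10) -> None:
        super().__init__()
        if window < 1:
            raise ValueError("pooling window must be >= 1")
        self.window = window

    def forward(self, x, training=False, rng=None):
        w = self.window
        L = x.shape[-1]
        self._L = L
        rem = (-L) % w
        if rem:
            x = np.concatenate([x, np.repeat(x[..., -1:], rem, axis=-1)], axis=-1)
        shp = x.shape[:-1] + (x.shape[-1] // w, w)
        return x.reshape(shp).mean(axis=-1)

    def backward(self, dy):
        w, L = self.window, self._L
        dxp = np.repeat(dy / w, w, axis=-1)
        dx = dxp[..., :L].copy()
        if dxp.shape[-1] > L:  # fold edge-replication gradient onto the last value
            dx[..., -1] += dxp[..., L:].sum(axis=-1)
        return dx


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng=None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.params = {
            "W": (rng.standard_normal((in_features, out_features)) * scale).astype(dtype),
            "b": np.zeros(out_features, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x, training=False, rng=None):
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Sequential(Layer):
    """A chain of layers sharing one forward/backward interface."""

    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self):
        """Yield (unique key, params dict, grads dict, name) for the optimiser."""
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "named_params"):
                for key, p, g, k in layer.named_params():
                    yield f"{i}.{key}", p, g, k
            else:
                for k in layer.params:
                    yield f"{i}.{k}", layer.params, layer.grads, k

    def parameter_count(self) -> int:
        return sum(int(np.prod(p[k].shape)) for _, p, _, k in self.named_params())

    def state_dict(self):
        return {str(i): layer.state_dict() for i, layer in enumerate(self.layers)}

    def load_state_dict(self, state):
        for i, layer in enumerate(self.layers):
            layer.load_state_dict(state[str(i)])
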