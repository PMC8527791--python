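"""Adam optimiser and the masked mean-squared-error loss."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "masked_mse", "masked_mse_grad"]


class Adam:
    """Adam with the standard bias correction (Kingma & Ba defaults except lr)."""

    def __init__(self, model, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self._buf: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for key, params, grads, k in self.model.named_params():
            g = grads[k]
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            m, v = self.m[key], self.v[key]
            buf = self._buf.setdefault(key, np.empty_like(g))
            # fully in-place moment and parameter updates: some of these
            # arrays are hundreds of MB, so no per-step temporaries
            m *= b1
            np.multiply(g, 1 - b1, out=buf)
            m += buf
            v *= b2
            np.square(g, out=buf)
            buf *= 1 - b2
            v += buf
            np.divide(v, bias2, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= self.lr / bias1
            params[k] -= buf


def _as_columns(y, y_hat, mask):
    """1-D inputs are a single trait (column), not a single sample (row)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y_hat.ndim == 1:
        y_hat = y_hat[:, None]
    if mask is None:
        mask = np.ones(y.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 1:
        mask = mask[:, None]
    return y, y_hat, mask


def masked_mse(y: np.ndarray, y_hat: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean squared error over observed entries, summed across traits.

    For a single target this is the plain MSE ``(1/n) * sum (y - y_hat)^2``.
    With multiple traits and a missingness mask, each trait contributes its
    own mean over observed pairs and the per-trait means are summed, so
    traits with few measurements are not drowned out by well-sampled ones.
    """
    y, y_hat, mask = _as_columns(y, y_hat, mask)
    if y.shape != y_hat.shape or y.shape != mask.shape:
        raise ValueError("y, y_hat and mask must share a shape")
    n_per_trait = mask.sum(axis=0)
    if n_per_trait.sum() == 0:
        raise ValueError("masked MSE undefined: no observed (y, y_hat) pairs")
    diff = np.where(mask, y - y_hat, 0.0)
    per_trait = (diff**2).sum(axis=0) / np.maximum(n_per_trait, 1)
    return float(per_trait[n_per_trait > 0].sum())


def masked_mse_grad(y: np.ndarray, y_hat: np.ndarray,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Gradient of :func:`masked_mse` with respect to ``y_hat``."""
    y, y_hat, mask = _as_columns(y, y_hat, mask)
    n_per_trait = np.maximum(mask.sum(axis=0), 1)
    return np.where(mask, -2.0 * (y - y_hat) / n_per_trait, 0.0)
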