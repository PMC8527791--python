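"""Training-time augmentations: horizontal shifts and spectral trimming.

Two augmentations compensate for the small labelled sample sizes typical of
leaf-level trait datasets:

* **Random horizontal shifts** translate a spectrum by up to ±5 grid
  positions (1 nm each), emulating small wavelength-registration error, and
  are used to expand the training set offline by a fixed rate.
* **Spectral trimming** zeroes both ends of the spectrum at randomly drawn
  bounds each time a training example is presented, so a fixed-input-length
  network learns to cope with instruments covering narrower ranges
  (e.g. VNIR-only sensors).  Bounds come from truncated normal
  distributions; pairs spanning less than a minimum number of valid
  wavelengths are rejected and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MAX_SHIFT",
    "TrimDistribution",
    "random_shift",
    "expand_training_set",
    "sample_trim_bounds",
    "apply_spectral_trim",
]

MAX_SHIFT = 5


def random_shift(v: np.ndarray, shift: int) -> np.ndarray:
    """Translate values by ``shift`` grid positions, replicating edge values.

    A positive shift moves the spectrum toward higher wavelengths; vacated
    positions are filled with the nearest original edge value so no
    artificial zeros appear inside the valid range.  Length is unchanged.
    """
    shift = int(shift)
    if abs(shift) > MAX_SHIFT:
        raise ValueError(f"|shift| must be <= {MAX_SHIFT}, got {shift}")
    v = np.asarray(v)
    if shift == 0:
        return v.copy()
    idx = np.clip(np.arange(v.shape[-1]) - shift, 0, v.shape[-1] - 1)
    return v[..., idx]


def expand_training_set(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    rate: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Append shift-augmented copies of training samples.

    ``round(n * rate)`` augmented samples are appended after the originals,
    each a uniformly chosen training sample (with replacement) translated by
    a uniformly random nonzero shift in [-5, 5]; labels and masks are copied
    unchanged.  At the standard 50% rate, 772 training samples become 1158.
    """
    if rate < 0:
        raise ValueError("augmentation rate must be >= 0")
    X = np.asarray(X)
    y = np.atleast_2d(np.asarray(y))
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot augment an empty training set")
    n_new = int(round(n * rate))
    if n_new == 0:
        return X.copy(), y.copy(), mask.copy()
    rng = np.random.default_rng(seed)
    src = rng.integers(0, n, size=n_new)
    shifts = rng.integers(1, 2 * MAX_SHIFT + 1, size=n_new)  # 1..10 -> nonzero in [-5,5]
    shifts = np.where(shifts > MAX_SHIFT, MAX_SHIFT - shifts, shifts)
    X_aug = np.stack([random_shift(X[i], s) for i, s in zip(src, shifts)])
    return (
        np.concatenate([X, X_aug]),
        np.concatenate([y, y[src]]),
        np.concatenate([mask, mask[src]]),
    )


@dataclass(frozen=True)
class TrimDistribution:
    """Sampler parameters for spectral-trimming bounds (all in nm).

    The low bound is drawn from a normal with mean 400 and sd 100 truncated
    to [400, 700]; the high bound from a normal with mean 2400 and sd 500
    truncated to [1000, 2400].  Pairs leaving less than ``min_span`` nm of
    valid signal are rejected and redrawn.
    """

    low_mean: float = 400.0
    low_sd: float = 100.0
    low_bounds: tuple = (400.0, 700.0)
    high_mean: float = 2400.0
    high_sd: float = 500.0
    high_bounds: tuple = (1000.0, 2400.0)
    min_span: float = 350.0

    def __post_init__(self) -> None:
        if self.min_span <= 0:
            raise ValueError("min_span must be positive")
        if not (self.low_bounds[0] <= self.low_bounds[1]):
            raise ValueError("low_bounds must be ordered")
        if not (self.high_bounds[0] <= self.high_bounds[1]):
            raise ValueError("high_bounds must be ordered")
        if self.high_bounds[1] - self.low_bounds[0] < self.min_span:
            raise ValueError("bounds admit no pair satisfying the span constraint")

    def _truncnorm(self, mean, sd, bounds):
        if sd <= 0:
            # Degenerate limit: all mass at the mean clipped into bounds.
            point = float(np.clip(mean, *bounds))
            return stats.uniform(loc=point, scale=0.0)
        a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
        return stats.truncnorm(a, b, loc=mean, scale=sd)

    @property
    def low_dist(self):
        return self._truncnorm(self.low_mean, self.low_sd, self.low_bounds)

    @property
    def high_dist(self):
        return self._truncnorm(self.high_mean, self.high_sd, self.high_bounds)


def sample_trim_bounds(
    dist: TrimDistribution, rng: np.random.Generator, size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (low, high) trimming bounds satisfying the span constraint.

    Marginals are the stated truncated normals; pairs with
    ``high - low < min_span`` are rejected and resampled, which preserves
    the marginals conditioned on the constraint.  Returns scalars when
    ``size`` is None, else two arrays of length ``size``.
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    low = np.empty(n)
    high = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        lo = np.atleast_1d(dist.low_dist.rvs(size=todo.size, random_state=rng))
        hi = np.atleast_1d(dist.high_dist.rvs(size=todo.size, random_state=rng))
        low[todo] = lo
        high[todo] = hi
        todo = todo[hi - lo < dist.min_span]
    if scalar:
        return float(low[0]), float(high[0])
    return low, high


def apply_spectral_trim(
    v: np.ndarray, low: float, high: float, grid_low: int = 400
) -> np.ndarray:
    """Zero reflectance outside [low, high] nm, keeping the input length fixed.

    ``v``'s last axis is assumed to lie on the 1 nm grid starting at
    ``grid_low``.  Values at wavelengths strictly below ``low`` or strictly
    above ``high`` are set to zero; the interior is returned unchanged.
    """
    if low >= high:
        raise ValueError(f"invalid trim bounds: low {low} >= high {high}")
    v = np.asarray(v)
    wl = grid_low + np.arange(v.shape[-1])
    out = v.copy()
    out[..., (wl < low) | (wl > high)] = 0.0
    return out
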