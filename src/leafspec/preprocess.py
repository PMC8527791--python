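"""Trimming, outlier filtering, pooling, trait alignment and data splits.

Reflectance below 400 nm and above 2400 nm has a poor signal-to-noise
ratio on full-range field spectroradiometers, so model inputs are trimmed
to the half-open window [400, 2400) — exactly 2000 wavelengths at 1 nm.
Spectra whose reflectance at 800 nm falls outside [0.35, 0.6] are treated
as measurement failures (bad leaf-clip contact, stray light) and removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import TRAIT_NAMES, SpectrumSet

__all__ = [
    "TraitMatrix",
    "SplitDataset",
    "trim_to_range",
    "filter_outliers",
    "average_pool",
    "split_dataset",
    "read_traits_csv",
    "write_traits_csv",
    "OUTLIER_BAND",
]

#: Inclusive reflectance band at 800 nm for plausible leaf spectra.
OUTLIER_BAND = (0.35, 0.6)

#: Default trimming window (half-open, nm).
DEFAULT_RANGE = (400, 2400)


@dataclass
class TraitMatrix:
    """Per-sample values of the ten physiological traits with a missingness mask.

    ``values`` is ``(n_samples, 10)`` in the canonical trait order; ``mask``
    is boolean with True where the trait was measured.  Unmeasured entries
    hold NaN.
    """

    sample_ids: list[str]
    values: np.ndarray
    mask: np.ndarray
    trait_names: tuple = TRAIT_NAMES

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.mask = np.atleast_2d(np.asarray(self.mask, dtype=bool))
        n, t = self.values.shape
        if self.mask.shape != (n, t):
            raise ValueError("mask shape must match values shape")
        if len(self.sample_ids) != n:
            raise ValueError("one sample id per row required")
        if t != len(self.trait_names):
            raise ValueError(f"expected {len(self.trait_names)} trait columns, got {t}")
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan
        if n and not self.mask.any(axis=1).all():
            bad = [self.sample_ids[i] for i in np.flatnonzero(~self.mask.any(axis=1))]
            raise ValueError(f"samples with no observed trait: {bad}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=list(self.trait_names))

    def subset(self, indices) -> "TraitMatrix":
        indices = np.asarray(indices)
        return TraitMatrix(
            [self.sample_ids[i] for i in indices],
            self.values[indices],
            self.mask[indices],
            self.trait_names,
        )


def read_traits_csv(path) -> TraitMatrix:
    """Read a trait table: first column sample id, then the ten trait columns.

    Blank cells denote missing measurements.
    """
    df = pd.read_csv(path, index_col=0)
    missing = [t for t in TRAIT_NAMES if t not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trait columns {missing}")
    vals = df.loc[:, list(TRAIT_NAMES)].to_numpy(dtype=float)
    return TraitMatrix([str(i) for i in df.index], vals, ~np.isnan(vals))


def write_traits_csv(traits: TraitMatrix, path) -> None:
    df = traits.to_frame()
    df.index.name = "sample"
    df.to_csv(path, float_format="%.10g")


@dataclass
class SplitDataset:
    """Aligned spectra + traits with a train/validation/test partition label per sample."""

    spectra: SpectrumSet
    traits: TraitMatrix
    partition: np.ndarray  # array of {"train","validation","test"} per sample
    seed: int

    def __post_init__(self) -> None:
        self.partition = np.asarray(self.partition, dtype=object)
        if self.spectra.n_observations != self.traits.n_samples:
            raise ValueError("spectra and traits must hold the same samples")
        if self.spectra.names != self.traits.sample_ids:
            raise ValueError("spectra and traits must be aligned by sample id")
        if self.partition.shape != (self.traits.n_samples,):
            raise ValueError("one partition label per sample required")
        labels = set(self.partition.tolist())
        if not labels <= {"train", "validation", "test"}:
            raise ValueError(f"unknown partition labels: {labels}")

    def indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.partition == part)

    def subset(self, part: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(spectra values, trait values, trait mask) for one partition."""
        idx = self.indices(part)
        return self.spectra.values[idx], self.traits.values[idx], self.traits.mask[idx]


def trim_to_range(s: SpectrumSet, low: int = 400, high: int = 2400) -> SpectrumSet:
    """Restrict a SpectrumSet to the half-open wavelength window [low, high).

    The half-open convention makes the default window exactly 2000
    wavelengths (400..2399 nm), the fixed model input length.  Spectra
    covering less than the window are returned as-is over the overlap; the
    model-facing code zero-pads them onto the full grid.
    """
    if low >= high:
        raise ValueError(f"empty wavelength window [{low}, {high})")
    w = s.wavelengths
    keep = (w >= low) & (w < high)
    if not keep.any():
        raise ValueError(
            f"window [{low}, {high}) does not overlap grid [{w[0]}, {w[-1]}]"
        )
    out = SpectrumSet(w[keep], s.values[:, keep], list(s.names), s.provenance)
    return out


def pad_to_grid(s: SpectrumSet, low: int = 400, high: int = 2400) -> np.ndarray:
    """Embed spectra onto the fixed [low, high) grid, zero-filling missing coverage.

    Zero filling matches the spectral-trimming augmentation convention, so a
    model trained with trimming treats absent wavelengths as trimmed ends.
    """
    grid = np.arange(low, high)
    out = np.zeros((s.n_observations, grid.size), dtype=float)
    w = s.wavelengths
    keep = (w >= low) & (w < high)
    if keep.any():
        cols = (w[keep] - low).astype(int)
        out[:, cols] = s.values[:, keep]
    return out


def filter_outliers(s: SpectrumSet, band: tuple = OUTLIER_BAND) -> tuple[SpectrumSet, list[str]]:
    """Remove observations whose reflectance at 800 nm lies outside ``band``.

    The band is inclusive: boundary values are kept.  Returns the surviving
    SpectrumSet (values untouched) and the removed observation names.
    """
    r800 = s.reflectance_at(800)
    lo, hi = band
    bad = (r800 < lo) | (r800 > hi)
    removed = [s.names[i] for i in np.flatnonzero(bad)]
    keep = np.flatnonzero(~bad)
    kept = SpectrumSet(
        s.wavelengths.copy(), s.values[keep], [s.names[i] for i in keep], s.provenance
    )
    return kept, removed


def average_pool(v: np.ndarray, window: int = 10) -> np.ndarray:
    """Non-overlapping mean pooling along the last axis.

    Smooths detector noise before the convolutional stack.  If the length is
    not divisible by ``window`` the input is padded by replicating the final
    value, so the output length is ``ceil(L / window)``.
    """
    if window < 1:
        raise ValueError("pooling window must be >= 1")
    v = np.asarray(v)
    L = v.shape[-1]
    rem = (-L) % window
    if rem:
        pad = np.repeat(v[..., -1:], rem, axis=-1)
        v = np.concatenate([v, pad], axis=-1)
    new_shape = v.shape[:-1] + (v.shape[-1] // window, window)
    return v.reshape(new_shape).mean(axis=-1)


def split_dataset(
    spectra: SpectrumSet,
    traits: TraitMatrix,
    fractions: tuple = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> SplitDataset:
    """Randomly partition samples into train/validation/test.

    Assignment is at the sample level — each sample (with all its trait
    values) lands wholly in one partition, so multi-task training cannot
    leak test information through a shared spectrum.  Sizes are
    ``floor(n*f)`` for validation and test with the remainder going to
    train; deterministic given ``seed``.
    """
    f_train, f_val, f_test = fractions
    if not np.isclose(f_train + f_val + f_test, 1.0):
        raise ValueError("fractions must sum to 1")
    n = spectra.n_observations
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_val = int(np.floor(n * f_val))
    n_test = int(np.floor(n * f_test))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    partition = np.empty(n, dtype=object)
    partition[order[:n_val]] = "validation"
    partition[order[n_val : n_val + n_test]] = "test"
    partition[order[n_val + n_test :]] = "train"
    return SplitDataset(spectra, traits, partition, seed)
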