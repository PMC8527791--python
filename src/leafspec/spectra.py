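"""Reading, validation and splice correction of leaf reflectance spectra.

The on-disk format is the plain CSV used by field spectroscopy pipelines:
the first column holds integer wavelengths in 1 nm increments, the header
row holds observation names, and every other column is one observation's
reflectance (unitless, nominally in [0, 1]).

Multi-detector spectroradiometers (e.g. ASD FieldSpec instruments) splice
separate VNIR and SWIR detectors together, leaving small additive
discontinuities ("jumps") at the splice wavelengths, typically 1000 nm and
1800 nm (1830 nm on some units). :func:`jump_correct` removes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_NAMES",
    "SpectrumSet",
    "SpectraSchemaError",
    "read_spectra_csv",
    "jump_correct",
    "write_predictions_csv",
    "read_predictions_csv",
]

#: Canonical trait column order used throughout the package.
TRAIT_NAMES = (
    "LMA",
    "Narea",
    "SPAD",
    "Nmass",
    "Vcmax",
    "Vcmax25",
    "J",
    "A",
    "gs",
    "Vcmax25/Narea",
)

#: Wavelength bounds accepted for user-supplied splice positions (nm).
JUMP_WAVELENGTH_BOUNDS = (355, 2495)


class SpectraSchemaError(ValueError):
    """Raised when a spectra CSV does not conform to the expected schema."""


@dataclass
class SpectrumSet:
    """A shared 1 nm wavelength grid plus named reflectance vectors.

    Parameters
    ----------
    wavelengths
        Strictly increasing integer grid with step exactly 1 nm.
    values
        Array of shape ``(n_observations, n_wavelengths)``.
    names
        Unique observation names, one per row of ``values``.
    provenance
        Free-text tag describing where the spectra came from.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    names: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.names = list(self.names)
        w = self.wavelengths
        if w.ndim != 1 or w.size < 2:
            raise SpectraSchemaError("wavelength grid must be a 1-D array with >= 2 points")
        if not np.allclose(w, np.round(w)):
            raise SpectraSchemaError("wavelengths must be integers (nm)")
        self.wavelengths = np.round(w).astype(int)
        if not np.all(np.diff(self.wavelengths) == 1):
            raise SpectraSchemaError("wavelengths must increase in exact 1 nm increments")
        if self.values.shape[1] != self.wavelengths.size:
            raise SpectraSchemaError(
                f"reflectance vectors have length {self.values.shape[1]}, "
                f"expected {self.wavelengths.size}"
            )
        if len(self.names) != self.values.shape[0]:
            raise SpectraSchemaError("one name per observation required")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise SpectraSchemaError(f"duplicate observation names: {dupes}")

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    def index_of(self, wavelength: int) -> int:
        """Grid index of an integer wavelength; raises if absent."""
        lo = int(self.wavelengths[0])
        if not (lo <= wavelength <= int(self.wavelengths[-1])):
            raise ValueError(f"wavelength {wavelength} nm outside grid "
                             f"[{lo}, {int(self.wavelengths[-1])}]")
        return int(wavelength - lo)

    def reflectance_at(self, wavelength: int) -> np.ndarray:
        """Reflectance of every observation at one wavelength."""
        return self.values[:, self.index_of(wavelength)]

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.wavelengths.copy(), self.values.copy(), list(self.names), self.provenance
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame in the on-disk layout (wavelength index, one column per observation)."""
        return pd.DataFrame(
            self.values.T, index=pd.Index(self.wavelengths, name="wavelength"), columns=self.names
        )


def read_spectra_csv(path, max_observations: int = 100) -> SpectrumSet:
    """Read a spectra CSV (wavelength column first, one observation per column).

    At most ``max_observations`` observations are kept; if the file holds
    more, the first ``max_observations`` are used and a warning is emitted.
    The cap exists for resource sharing in hosted deployments and is
    therefore a plain parameter, not a hard limit.
    """
    if max_observations < 1:
        raise ValueError("max_observations must be a positive integer")
    import csv

    try:
        with open(path, newline="") as fh:
            header = next(csv.reader(fh), None)
    except OSError as exc:
        raise SpectraSchemaError(f"{path}: cannot read file") from exc
    if header:
        raw_names = [h.strip() for h in header[1:]]
        if len(set(raw_names)) != len(raw_names):
            dupes = sorted({n for n in raw_names if raw_names.count(n) > 1})
            raise SpectraSchemaError(f"{path}: duplicate observation names {dupes}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SpectraSchemaError(f"{path}: empty file") from exc
    if df.shape[1] < 2:
        raise SpectraSchemaError(
            f"{path}: needs a wavelength column plus at least one observation column "
            f"(found {df.shape[1]} column(s))"
        )
    wl_raw = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if wl_raw.isna().any():
        row = int(wl_raw.isna().idxmax()) + 2  # +2: header plus 1-based
        raise SpectraSchemaError(f"{path}: non-numeric wavelength at file row {row}, column 1")
    wavelengths = wl_raw.to_numpy()
    if not np.allclose(np.diff(wavelengths), 1.0):
        bad = int(np.flatnonzero(~np.isclose(np.diff(wavelengths), 1.0))[0]) + 2
        raise SpectraSchemaError(
            f"{path}: wavelengths must increase in 1 nm increments (violated at file row {bad})"
        )
    names = [str(c) for c in df.columns[1:]]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SpectraSchemaError(f"{path}: duplicate observation names {dupes}")
    if len(names) > max_observations:
        warnings.warn(
            f"{path}: file contains {len(names)} observations; only the first "
            f"{max_observations} are processed",
            stacklevel=2,
        )
        names = names[:max_observations]
    values = df.iloc[:, 1 : 1 + len(names)].apply(pd.to_numeric, errors="coerce").to_numpy().T
    if np.isnan(values).any():
        obs, pos = np.argwhere(np.isnan(values))[0]
        raise SpectraSchemaError(
            f"{path}: non-numeric reflectance for observation '{names[obs]}' at file row {pos + 2}"
        )
    if (values < 0).any() or (values > 1).any():
        warnings.warn(
            f"{path}: reflectance values outside [0, 1] present "
            f"(min {values.min():.4g}, max {values.max():.4g})",
            stacklevel=2,
        )
    return SpectrumSet(wavelengths, values, names, provenance=str(path))


def write_spectra_csv(s: SpectrumSet, path) -> None:
    """Write a SpectrumSet in the same CSV layout the reader accepts."""
    df = s.to_frame().reset_index()
    df.to_csv(path, index=False)


def _splice_offsets(values: np.ndarray, idx: int, half_window: int = 5) -> np.ndarray:
    """Additive offset for the segment right of ``idx`` (per observation).

    The offset makes the first-difference across the splice equal the mean
    first-difference of the ``half_window`` differences on each side.
    """
    d = np.diff(values, axis=1)
    left = d[:, max(idx - half_window, 0) : idx]
    right = d[:, idx + 1 : idx + 1 + half_window]
    local = np.concatenate([left, right], axis=1)
    target = local.mean(axis=1)
    return target - d[:, idx]


def jump_correct(
    s: SpectrumSet, jump_wavelengths, half_window: int = 5, mode: str = "additive"
) -> SpectrumSet:
    """Remove detector-splice discontinuities at the given wavelengths.

    For each splice wavelength ``j`` (processed left to right) the segment
    at wavelengths > ``j`` is offset so that the first-difference across the
    splice equals the mean of the ``half_window`` first-differences on each
    side.  An additive offset models the artifact as a detector offset;
    ``mode="multiplicative"`` rescales the right segment instead.

    All other first-differences are unchanged and the output grid is
    identical to the input.  The operation is idempotent.
    """
    if mode not in ("additive", "multiplicative"):
        raise ValueError(f"unknown jump-correction mode {mode!r}")
    lo, hi = JUMP_WAVELENGTH_BOUNDS
    out = s.copy()
    for j in sorted(int(j) for j in jump_wavelengths):
        if not (lo <= j <= hi):
            raise ValueError(
                f"jump wavelength {j} nm outside the supported range [{lo}, {hi}] nm"
            )
        if not (s.wavelengths[0] <= j < s.wavelengths[-1]):
            raise ValueError(f"jump wavelength {j} nm outside the spectrum grid")
        idx = out.index_of(j)
        offset = _splice_offsets(out.values, idx, half_window)
        if mode == "additive":
            out.values[:, idx + 1 :] += offset[:, None]
        else:
            base = out.values[:, idx + 1]
            scale = np.where(base != 0, (base + offset) / np.where(base == 0, 1.0, base), 1.0)
            out.values[:, idx + 1 :] *= scale[:, None]
    return out


def write_predictions_csv(predictions: pd.DataFrame, path) -> None:
    """Write per-observation trait predictions as CSV.

    ``predictions`` must have one row per observation (index = observation
    name) and the ten canonical trait columns; columns are written in the
    canonical order.
    """
    missing = [t for t in TRAIT_NAMES if t not in predictions.columns]
    if missing:
        raise ValueError(f"prediction table is missing trait columns: {missing}")
    out = predictions.loc[:, list(TRAIT_NAMES)].copy()
    out.index.name = "observation"
    out.to_csv(path, float_format="%.10g")


def read_predictions_csv(path) -> pd.DataFrame:
    """Read a prediction table written by :func:`write_predictions_csv`."""
    return pd.read_csv(path, index_col=0)
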