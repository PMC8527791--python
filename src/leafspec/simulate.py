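"""Synthetic leaf spectra with trait-linked structure, artifacts and missingness.

The generator produces datasets shaped like real leaf-clip campaigns so the
whole pipeline is trainable and testable without any download:

* ten correlated physiological traits whose locations and spreads default
  to the published summary statistics of the wheat trait distributions,
* reflectance on the 1 nm [400, 2400) grid built from a smooth leaf-like
  envelope — chlorophyll absorption troughs around 450 and 670 nm, a green
  peak near 550 nm, a sharp red edge near 720 nm, an NIR plateau with
  reflectance at 800 nm inside [0.35, 0.6] for non-outliers, and Gaussian
  water-absorption dips near 1200/1450/1940 nm,
* linear trait-to-feature linkage: pigment/nitrogen latents drive the
  visible features and red edge, structural latents (LMA, Narea) drive the
  NIR plateau and SWIR water-band depths — so the planted signal is
  recoverable by both linear (PLSR) and convolutional models,
* detector-splice steps at configurable wavelengths, an outlier fraction
  violating the 800 nm plausibility band, white noise, and per-trait
  missingness matching the published per-trait sample counts.

This is a phenomenological emulator, not a radiative-transfer model: it
reproduces the statistical structure the predictors rely on, not leaf
optics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .preprocess import TraitMatrix, write_traits_csv
from .spectra import TRAIT_NAMES, SpectrumSet, write_spectra_csv

__all__ = [
    "PUBLISHED_TRAIT_STATS",
    "SimConfig",
    "GroundTruth",
    "generate_dataset",
    "inject_detector_jumps",
    "save_dataset",
]

#: Published per-trait summary statistics: (sample count, mean, sd).
#: Counts are out of 1013 total samples and set the default missingness.
PUBLISHED_TRAIT_STATS = {
    "LMA": (525, 59.32, 12.54),
    "Narea": (1013, 2.59, 0.77),
    "SPAD": (614, 48.5, 8.27),
    "Nmass": (615, 42.89, 8.6),
    "Vcmax": (488, 170.36, 65.78),
    "Vcmax25": (488, 148.02, 40.1),
    "J": (488, 218.17, 56.2),
    "A": (488, 24.99, 6.4),
    "gs": (488, 0.48, 0.21),
    "Vcmax25/Narea": (488, 59.95, 14.04),
}

# Factor loadings (structure, nitrogen/pigment, photosynthesis) used to build
# the default inter-trait correlation matrix as L L^T (unit diagonal), which
# is positive semi-definite by construction.  Magnitudes are plausible
# placeholders for a wheat panel, not measured values.
_FACTOR_LOADINGS = np.array([
    [0.85, 0.10, 0.00],   # LMA
    [0.60, 0.60, 0.20],   # Narea
    [0.10, 0.80, 0.20],   # SPAD
    [-0.20, 0.85, 0.20],  # Nmass
    [0.10, 0.30, 0.80],   # Vcmax
    [0.10, 0.30, 0.82],   # Vcmax25
    [0.10, 0.30, 0.80],   # J
    [0.00, 0.25, 0.75],   # A
    [0.00, 0.10, 0.55],   # gs
    [-0.50, -0.30, 0.50], # Vcmax25/Narea
])


def default_correlation() -> np.ndarray:
    C = _FACTOR_LOADINGS @ _FACTOR_LOADINGS.T
    np.fill_diagonal(C, 1.0)
    return C


#: Linear linkage from standardized latent traits to spectral features.
#: Keys are feature names; values are (intercept, {trait: coefficient}).
DEFAULT_LINKAGE = {
    "chl_trough_670": (0.035, {"SPAD": 0.010, "Nmass": 0.005}),
    "chl_trough_450": (0.030, {"SPAD": 0.006}),
    "green_peak": (0.035, {"SPAD": -0.008}),
    "red_edge_pos": (720.0, {"SPAD": 4.0}),
    "nir_plateau": (0.475, {"LMA": 0.025, "Narea": -0.012}),
    # water bands are relative absorption depths (fraction of local level)
    "water_1450": (0.35, {"LMA": 0.060, "Narea": 0.040, "gs": 0.016}),
    "water_1940": (0.62, {"LMA": 0.080, "Narea": 0.060, "gs": 0.024}),
    "water_1200": (0.10, {"LMA": 0.020}),
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic campaign."""

    n_samples: int = 1013
    seed: int = 0
    trait_means: dict = field(
        default_factory=lambda: {t: v[1] for t, v in PUBLISHED_TRAIT_STATS.items()})
    trait_stds: dict = field(
        default_factory=lambda: {t: v[2] for t, v in PUBLISHED_TRAIT_STATS.items()})
    #: fraction of samples with the trait observed (counts / 1013 by default)
    observed_fractions: dict = field(
        default_factory=lambda: {t: v[0] / 1013 for t, v in PUBLISHED_TRAIT_STATS.items()})
    correlation: np.ndarray = field(default_factory=default_correlation)
    linkage: dict = field(default_factory=lambda: dict(DEFAULT_LINKAGE))
    noise_sd: float = 0.004
    #: additive detector-splice steps injected above these wavelengths (nm)
    jump_magnitudes: dict = field(default_factory=lambda: {1000: 0.02, 1800: -0.015})
    apply_jumps: bool = True
    outlier_fraction: float = 0.0

    def __post_init__(self) -> None:
        C = np.asarray(self.correlation, dtype=float)
        if C.shape != (10, 10) or not np.allclose(C, C.T):
            raise ValueError("correlation must be a symmetric 10 x 10 matrix")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        self.correlation = C
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Generative record kept for oracle tests."""

    latents: np.ndarray          # (n, 10) standardized correlated latents
    features: dict               # feature name -> (n,) realized values
    linkage: dict                # the planted feature <- trait coefficients
    clean_values: np.ndarray     # spectra before noise, outliers and jumps
    outlier_names: list
    n_clipped: int               # reflectance values clipped into [0, 1]


def _truncnorm_params(target_mean: float, target_sd: float,
                      lower: float = 0.0) -> tuple[float, float]:
    """(mu, sigma) of a lower-truncated normal whose truncated moments match targets."""
    if (target_mean - lower) / target_sd > 4.0:
        return target_mean, target_sd  # truncation negligible

    def moments(params):
        mu, log_sig = params
        sig = np.exp(log_sig)
        a = (lower - mu) / sig
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sig, moments="mv")
        return [m - target_mean, np.sqrt(v) - target_sd]

    sol = optimize.fsolve(moments, [target_mean, np.log(target_sd)], full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def _gauss(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def _render_spectra(wl: np.ndarray, features: dict) -> np.ndarray:
    """Deterministic leaf-like envelope from realized spectral features."""
    s = 1.0 / (1.0 + np.exp(-(wl[None, :] - features["red_edge_pos"][:, None]) / 18.0))
    vis = (0.10
           + features["green_peak"][:, None] * _gauss(wl, 550, 40)[None, :]
           - features["chl_trough_670"][:, None] * _gauss(wl, 670, 45)[None, :]
           - features["chl_trough_450"][:, None] * _gauss(wl, 450, 35)[None, :])
    plateau = features["nir_plateau"][:, None]
    r = vis * (1 - s) + plateau * s
    decline = 1.0 - 0.22 / (1.0 + np.exp(-(wl - 1550.0) / 250.0))
    r = r * decline[None, :]
    # Relative water absorption: multiplicative, so reflectance stays positive.
    dips = (np.clip(features["water_1450"], 0, 0.95)[:, None] * _gauss(wl, 1450, 55)[None, :]
            + np.clip(features["water_1940"], 0, 0.95)[:, None] * _gauss(wl, 1940, 75)[None, :]
            + np.clip(features["water_1200"], 0, 0.95)[:, None] * _gauss(wl, 1200, 45)[None, :])
    return r * (1.0 - s * np.clip(dips, 0.0, 0.97))


def generate_dataset(cfg: SimConfig) -> tuple[SpectrumSet, TraitMatrix, GroundTruth]:
    """Draw an aligned synthetic (spectra, traits) dataset plus its ground truth.

    Deterministic given ``cfg.seed``.  Trait marginals are lower-truncated
    normals (all traits are physically non-negative) whose post-truncation
    moments match the configured targets; the joint dependence is a Gaussian
    copula with the configured correlation matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    names = [f"sim{i:04d}" for i in range(n)]
    wl = np.arange(400, 2400)

    # Correlated standard-normal latents, one per trait.
    L = np.linalg.cholesky(cfg.correlation + 1e-12 * np.eye(10))
    z = rng.standard_normal((n, 10)) @ L.T

    # Trait values via moment-matched truncated-normal marginals.
    values = np.empty((n, 10))
    for j, t in enumerate(TRAIT_NAMES):
        mu, sig = _truncnorm_params(cfg.trait_means[t], cfg.trait_stds[t])
        a = -mu / sig
        values[:, j] = stats.truncnorm.ppf(stats.norm.cdf(z[:, j]), a, np.inf,
                                           loc=mu, scale=sig)

    # Spectral features as planted linear functions of the latents.
    zmap = {t: z[:, j] for j, t in enumerate(TRAIT_NAMES)}
    features = {}
    for feat, (intercept, coefs) in cfg.linkage.items():
        f = np.full(n, float(intercept))
        for trait, c in coefs.items():
            f = f + c * zmap[trait]
        features[feat] = f

    # Outliers: push the NIR plateau outside the 800 nm plausibility band.
    n_out = int(round(n * cfg.outlier_fraction))
    out_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
    if n_out:
        low_half = rng.random(n_out) < 0.5
        features["nir_plateau"] = features["nir_plateau"].copy()
        features["nir_plateau"][out_idx] = np.where(
            low_half, rng.uniform(0.24, 0.32, n_out), rng.uniform(0.63, 0.72, n_out))
    else:
        features["nir_plateau"] = np.clip(features["nir_plateau"], 0.37, 0.59)
    if n_out:
        keep = np.ones(n, bool)
        keep[out_idx] = False
        features["nir_plateau"][keep] = np.clip(features["nir_plateau"][keep], 0.37, 0.59)

    clean = _render_spectra(wl, features)
    spectra_values = clean + rng.normal(0.0, cfg.noise_sd, clean.shape)

    if cfg.apply_jumps:
        for j_wl, mag in sorted(cfg.jump_magnitudes.items()):
            spectra_values[:, wl > j_wl] += mag

    clipped = (spectra_values < 0) | (spectra_values > 1)
    n_clipped = int(clipped.sum())
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} reflectance values into [0, 1]")
        spectra_values = np.clip(spectra_values, 0.0, 1.0)

    # Per-trait missingness; every sample keeps at least one observed trait.
    mask = np.empty((n, 10), dtype=bool)
    for j, t in enumerate(TRAIT_NAMES):
        mask[:, j] = rng.random(n) < cfg.observed_fractions[t]
    empty = ~mask.any(axis=1)
    if empty.any():
        mask[np.flatnonzero(empty), rng.integers(0, 10, int(empty.sum()))] = True

    spectra = SpectrumSet(wl, spectra_values, names, provenance=f"synthetic(seed={cfg.seed})")
    traits = TraitMatrix(names, values, mask)
    truth = GroundTruth(
        latents=z,
        features=features,
        linkage=dict(cfg.linkage),
        clean_values=clean,
        outlier_names=[names[i] for i in sorted(out_idx.tolist())],
        n_clipped=n_clipped,
    )
    return spectra, traits, truth


def inject_detector_jumps(s: SpectrumSet, jumps) -> SpectrumSet:
    """Add a constant step above each (wavelength, magnitude); cumulative.

    Emulates the splice artifacts of multi-detector spectroradiometers at
    e.g. 1000 and 1800 nm (1830 nm on some instruments).
    """
    out = s.copy()
    for j_wl, mag in jumps:
        if not (s.wavelengths[0] <= j_wl <= s.wavelengths[-1]):
            raise ValueError(f"jump wavelength {j_wl} nm outside the grid")
        out.values[:, out.wavelengths > j_wl] += mag
    return out


def save_dataset(spectra: SpectrumSet, traits: TraitMatrix, truth: GroundTruth,
                 outdir) -> None:
    """Write spectra CSV, traits CSV and a ground-truth JSON sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_spectra_csv(spectra, outdir / "spectra.csv")
    write_traits_csv(traits, outdir / "traits.csv")
    sidecar = {
        "linkage": {k: [v[0], v[1]] for k, v in truth.linkage.items()},
        "outlier_names": truth.outlier_names,
        "n_clipped": truth.n_clipped,
        "features": {k: v.tolist() for k, v in truth.features.items()},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
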