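import numpy as np
import pytest

from leafspec.preprocess import TraitMatrix
from leafspec.spectra import SpectrumSet


@pytest.fixture
def smooth_spectra():
    """Three quadratic spectra on the 400..2399 grid (locally linear differences)."""
    wl = np.arange(400, 2400)
    x = (wl - 400) / 2000.0
    values = np.stack([
        0.30 + 0.20 * x - 0.10 * x**2,
        0.45 + 0.05 * x - 0.15 * x**2,
        0.40 * np.ones_like(x),
    ])
    return SpectrumSet(wl, values, ["a", "b", "c"], provenance="fixture")


@pytest.fixture
def small_traits():
    rng = np.random.default_rng(42)
    values = rng.normal(50, 10, size=(3, 10))
    mask = np.ones((3, 10), dtype=bool)
    mask[0, 4] = False
    values[0, 4] = np.nan
    return TraitMatrix(["a", "b", "c"], values, mask)


@pytest.fixture
def spectra_csv(tmp_path, smooth_spectra):
    df = smooth_spectra.to_frame().reset_index()
    path = tmp_path / "spectra.csv"
    df.to_csv(path, index=False)
    return path
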