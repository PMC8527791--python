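"""Statistical and structural properties of the synthetic-spectra generator."""

import json

import numpy as np
import pytest

from leafspec.preprocess import OUTLIER_BAND, filter_outliers
from leafspec.simulate import (
    SimConfig,
    generate_dataset,
    inject_detector_jumps,
    save_dataset,
)
from leafspec.spectra import TRAIT_NAMES, jump_correct, read_spectra_csv


@pytest.fixture(scope="module")
def small_dataset():
    cfg = SimConfig(n_samples=250, seed=11, outlier_fraction=0.04)
    return cfg, *generate_dataset(cfg)


class TestGenerateDataset:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_samples=40, seed=5)
        s1, t1, _ = generate_dataset(cfg)
        s2, t2, _ = generate_dataset(SimConfig(n_samples=40, seed=5))
        np.testing.assert_array_equal(s1.values, s2.values)
        np.testing.assert_array_equal(t1.values[t1.mask], t2.values[t2.mask])

    def test_non_outliers_satisfy_800nm_band(self, small_dataset):
        cfg, s, t, gt = small_dataset
        r800 = s.reflectance_at(800)
        lo, hi = OUTLIER_BAND
        keep = np.array([n not in gt.outlier_names for n in s.names])
        assert (r800[keep] >= lo).all() and (r800[keep] <= hi).all()

    def test_outlier_count_is_rounded_fraction(self, small_dataset):
        cfg, s, t, gt = small_dataset
        assert len(gt.outlier_names) == round(cfg.n_samples * cfg.outlier_fraction)
        kept, removed = filter_outliers(s)
        assert set(removed) == set(gt.outlier_names)

    def test_trait_moments_match_targets_within_3se(self):
        cfg = SimConfig(n_samples=2000, seed=3, apply_jumps=False)
        _, traits, _ = generate_dataset(cfg)
        df = traits.to_frame()
        for name in TRAIT_NAMES:
            col = df[name].dropna()
            target_mean = cfg.trait_means[name]
            target_sd = cfg.trait_stds[name]
            se_mean = target_sd / np.sqrt(len(col))
            se_sd = target_sd / np.sqrt(2 * len(col))
            assert abs(col.mean() - target_mean) < 3 * se_mean, name
            assert abs(col.std() - target_sd) < 4 * se_sd, name

    def test_missingness_fractions_and_no_empty_samples(self, small_dataset):
        cfg, s, t, gt = small_dataset
        frac = t.mask.mean(axis=0)
        for j, name in enumerate(TRAIT_NAMES):
            expected = cfg.observed_fractions[name]
            # binomial 4-sigma bound
            tol = 4 * np.sqrt(expected * (1 - expected) / cfg.n_samples) + 1e-9
            assert abs(frac[j] - expected) <= tol, name
        assert t.mask.any(axis=1).all()

    def test_values_bounded_after_artifacts(self, small_dataset):
        _, s, _, _ = small_dataset
        assert (s.values >= 0).all() and (s.values <= 1).all()

    def test_linkage_recovered_by_least_squares(self, small_dataset):
        """Regressing each planted spectral feature on the latent traits
        returns the planted linkage coefficients (signal exists)."""
        cfg, s, t, gt = small_dataset
        Z = gt.latents
        keep = np.array([n not in gt.outlier_names for n in s.names])
        design = np.column_stack([np.ones(keep.sum()), Z[keep]])
        for feat, (intercept, coefs) in cfg.linkage.items():
            beta, *_ = np.linalg.lstsq(design, gt.features[feat][keep], rcond=None)
            assert beta[0] == pytest.approx(intercept, abs=1e-6)
            planted = np.zeros(10)
            for trait, c in coefs.items():
                planted[TRAIT_NAMES.index(trait)] = c
            np.testing.assert_allclose(beta[1:], planted, atol=1e-6)

    def test_infeasible_correlation_rejected(self):
        C = np.full((10, 10), 0.99)
        np.fill_diagonal(C, 1.0)
        C[0, 1] = C[1, 0] = -0.99  # wildly inconsistent with the rest
        with pytest.raises(ValueError, match="positive semi-definite"):
            SimConfig(n_samples=10, correlation=C)

    def test_spectra_have_red_edge_and_water_bands(self, small_dataset):
        """Qualitative envelope: NIR plateau above visible, dips at water bands."""
        _, s, _, gt = small_dataset
        clean = gt.clean_values
        wl = s.wavelengths
        vis = clean[:, (wl >= 600) & (wl <= 690)].mean()
        nir = clean[:, (wl >= 780) & (wl <= 900)].mean()
        at_1940 = clean[:, wl == 1940].mean()
        shoulder = clean[:, wl == 1700].mean()
        assert nir > 2 * vis
        assert at_1940 < 0.6 * shoulder


class TestInjectDetectorJumps:
    def test_zero_magnitude_is_identity(self, smooth_spectra):
        out = inject_detector_jumps(smooth_spectra, [(1000, 0.0)])
        np.testing.assert_array_equal(out.values, smooth_spectra.values)

    def test_round_trip_with_jump_correct(self, smooth_spectra):
        injected = inject_detector_jumps(smooth_spectra,
                                         [(1000, 0.05), (1800, -0.03)])
        fixed = jump_correct(injected, [1000, 1800])
        np.testing.assert_allclose(fixed.values, smooth_spectra.values, atol=1e-9)

    @pytest.mark.parametrize("pos", [1000, 1800, 1830])
    def test_supported_positions(self, smooth_spectra, pos):
        out = inject_detector_jumps(smooth_spectra, [(pos, 0.02)])
        idx = smooth_spectra.index_of(pos)
        np.testing.assert_array_equal(out.values[:, : idx + 1],
                                      smooth_spectra.values[:, : idx + 1])
        np.testing.assert_allclose(out.values[:, idx + 1 :],
                                   smooth_spectra.values[:, idx + 1 :] + 0.02)

    def test_outside_grid_rejected(self, smooth_spectra):
        with pytest.raises(ValueError):
            inject_detector_jumps(smooth_spectra, [(2450, 0.1)])

    def test_cumulative_jumps(self, smooth_spectra):
        out = inject_detector_jumps(smooth_spectra, [(1000, 0.02), (1800, 0.02)])
        idx = smooth_spectra.index_of(2000)
        np.testing.assert_allclose(out.values[:, idx],
                                   smooth_spectra.values[:, idx] + 0.04)


class TestSaveDataset:
    def test_emits_readable_csv_schema_and_sidecar(self, tmp_path):
        cfg = SimConfig(n_samples=8, seed=2)
        s, t, gt = generate_dataset(cfg)
        save_dataset(s, t, gt, tmp_path)
        back = read_spectra_csv(tmp_path / "spectra.csv", max_observations=10)
        assert back.names == s.names
        np.testing.assert_allclose(back.values, s.values, atol=1e-9)
        sidecar = json.loads((tmp_path / "ground_truth.json").read_text())
        assert set(sidecar["linkage"]) == set(cfg.linkage)
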