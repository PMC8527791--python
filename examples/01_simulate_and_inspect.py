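"""Generate a synthetic leaf-spectra campaign and inspect its structure.

Builds 200 samples of trait-linked reflectance with detector-splice steps
and per-trait missingness, then prints the trait summary and the 800 nm
reflectance band that separates plausible leaf spectra from outliers.
"""
from leafspec import SimConfig, generate_dataset

cfg = SimConfig(n_samples=200, seed=7, outlier_fraction=0.05)
spectra, traits, truth = generate_dataset(cfg)

print(traits.to_frame().describe().loc[["mean", "std"]].round(2))
r800 = spectra.reflectance_at(800)
print(f"\nreflectance at 800 nm: min {r800.min():.3f}, max {r800.max():.3f}")
print(f"planted outliers (outside [0.35, 0.60] at 800 nm): {len(truth.outlier_names)}")
# The mean/std rows above should sit near the configured trait targets;
# the outlier count matches round(n * outlier_fraction).
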