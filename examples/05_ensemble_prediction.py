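"""Combine predictors with the plain-mean ensemble.

Fits a quick PLSR and MLP on synthetic data and averages their predictions;
the ensemble output for each observation and trait is exactly the mean of
the member outputs.
"""
import numpy as np

from leafspec import (
    SimConfig, TrainConfig, build_model, ensemble_predict, generate_dataset,
    split_dataset, train_with_early_stopping,
)
from leafspec.models import PLSRModel
from leafspec.train import _dataset_arrays

spectra, traits, _ = generate_dataset(SimConfig(n_samples=150, seed=2))
split = split_dataset(spectra, traits, seed=0)
X, y, mask = _dataset_arrays(split, PLSRModel().trait_names)["train"]

plsr = PLSRModel(n_components=8).fit(X, y, mask)
mlp = build_model("mlp", seed=0)
mlp, _ = train_with_early_stopping(
    mlp, split, TrainConfig(epochs=10, eval_interval=10, batch_size=32, seed=0,
                            spectral_trim=False, shift_rate=0.0))

ens = ensemble_predict([plsr, mlp], spectra)
member_mean = (plsr.predict(spectra) + mlp.predict(spectra)) / 2
print("max |ensemble - member mean|:", float(np.abs(ens - member_mean).max().max()))
print(ens.head(3).round(2))
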