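"""Tune and fit the PLSR chemometrics baseline; pick a range for narrow input.

Searches the component count on the validation split, fits the full-range
model, and shows how an input covering only 400-1650 nm is matched to the
largest predetermined PLSR training range it fully contains.
"""
import numpy as np

from leafspec import SimConfig, generate_dataset, jump_correct, match_plsr_range, split_dataset
from leafspec.models import PLSRModel
from leafspec.train import _dataset_arrays, evaluate_model, tune_baseline_hyperparams
from leafspec.preprocess import trim_to_range

spectra, traits, _ = generate_dataset(SimConfig(n_samples=350, seed=0))
spectra = jump_correct(spectra, [1000, 1800])
split = split_dataset(spectra, traits, seed=0)

chosen = tune_baseline_hyperparams("plsr", split)
print(f"components maximising mean validation R^2: {chosen['n_components']}")
model = PLSRModel(n_components=chosen["n_components"])
X, y, mask = _dataset_arrays(split, model.trait_names)["train"]
model.fit(X, y, mask)
print(evaluate_model(model, split).per_trait["R2"].round(3).to_dict())

narrow = trim_to_range(spectra, 400, 1651)
print(f"input covering [400, 1650] nm maps to PLSR range {match_plsr_range(narrow)}")
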