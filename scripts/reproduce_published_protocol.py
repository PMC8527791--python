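"""Full-scale training protocol for a real spectra + traits dataset.

The published evaluation trains every model for 1000 epochs (validation
every 10, Adam lr 1e-4, shift augmentation +50%, spectral trimming for the
CNNs), repeats each fit with three random seeds and reports the mean
per-trait R^2, Abs(Bias%) and REP on the held-out 20% test split.  The
original wheat dataset must be downloaded separately by the user; point
--spectra/--traits at its CSVs.  Expect hours of CPU time at full scale.

Usage:
    python scripts/reproduce_published_protocol.py \
        --spectra spectra.csv --traits traits.csv --model cnn-multi --out metrics.csv
"""

from __future__ import annotations

import argparse

import leafspec as ls
from leafspec.models import PLSRModel, XGBoostModel, build_model
from leafspec.train import (
    MetricsReport,
    TrainConfig,
    _dataset_arrays,
    evaluate_model,
    train_with_early_stopping,
    tune_baseline_hyperparams,
)


def fit_one(kind: str, split, seed: int):
    if kind in ("cnn-multi", "cnn-single", "mlp", "lstm"):
        model = build_model(kind, seed=seed) if kind != "cnn-single" else None
        if kind in ("cnn-single", "lstm"):
            raise SystemExit("single-task kinds: run once per trait via the CLI")
        cfg = TrainConfig(epochs=1000, eval_interval=10, seed=seed)
        model, _ = train_with_early_stopping(model, split, cfg, verbose=True)
        return model
    X, y, mask = _dataset_arrays(split, ls.TRAIT_NAMES)["train"]
    if kind == "plsr":
        chosen = tune_baseline_hyperparams("plsr", split)
        return PLSRModel(n_components=chosen["n_components"]).fit(X, y, mask)
    if kind == "xgboost":
        chosen = tune_baseline_hyperparams("xgboost", split)
        return XGBoostModel(chosen["learning_rate"], chosen["max_depth"],
                            chosen["colsample_bytree"], seed=seed).fit(X, y, mask)
    raise SystemExit(f"unsupported kind {kind}")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--spectra", required=True)
    ap.add_argument("--traits", required=True)
    ap.add_argument("--model", default="cnn-multi")
    ap.add_argument("--jumps", default="1000,1800")
    ap.add_argument("--seeds", default="0,1,2")
    ap.add_argument("--out", required=True)
    args = ap.parse_args()

    s = ls.read_spectra_csv(args.spectra, max_observations=10**9)
    if args.jumps:
        s = ls.jump_correct(s, [int(j) for j in args.jumps.split(",")])
    s, removed = ls.filter_outliers(s)
    print(f"removed {len(removed)} outlier spectra")
    t = ls.read_traits_csv(args.traits)
    t = t.subset([t.sample_ids.index(n) for n in s.names])

    reports = []
    for seed in (int(x) for x in args.seeds.split(",")):
        split = ls.split_dataset(s, t, seed=seed)
        model = fit_one(args.model, split, seed)
        reports.append(evaluate_model(model, split))
    agg = MetricsReport.aggregate(reports)
    print(agg.per_trait.round(3))
    agg.per_trait.to_csv(args.out)


if __name__ == "__main__":
    main()
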