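"""Loss, metrics, early stopping and baseline tuning."""

import numpy as np
import pandas as pd
import pytest

from leafspec.models import CNNConfig, ConvLayerSpec, PLSRModel, build_model
from leafspec.preprocess import TraitMatrix, split_dataset
from leafspec.spectra import TRAIT_NAMES, SpectrumSet
from leafspec.train import (
    EvaluationPair,
    MetricsReport,
    TrainConfig,
    compute_metrics,
    mse_loss,
    train_with_early_stopping,
    tune_baseline_hyperparams,
    XGBOOST_GRID,
)


class TestMseLoss:
    def test_perfect_fit_is_zero(self):
        pair = EvaluationPair(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert mse_loss(pair) == 0.0

    def test_hand_arithmetic(self):
        pair = EvaluationPair(np.array([1.0, 3.0]), np.array([2.0, 2.0]))
        assert mse_loss(pair) == pytest.approx(1.0)

    def test_all_masked_raises(self):
        pair = EvaluationPair(np.ones(3), np.zeros(3), np.zeros(3, bool))
        with pytest.raises(ValueError):
            mse_loss(pair)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, bias, rep = compute_metrics(EvaluationPair(y, y.copy()))
        assert (r2, bias, rep) == (1.0, 0.0, 0.0)

    def test_mean_predictor_scores_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        pred = np.full(4, y.mean())
        r2, bias, rep = compute_metrics(EvaluationPair(y, pred))
        assert r2 == pytest.approx(0.0)
        assert bias == pytest.approx(0.0)

    def test_negative_r2_for_anticorrelated_prediction(self):
        r2, _, _ = compute_metrics(EvaluationPair(np.array([0.0, 1.0]),
                                                  np.array([1.0, 0.0])))
        assert r2 == pytest.approx(-3.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compute_metrics(EvaluationPair(np.ones(3), np.zeros(3)))

    def test_zero_mean_percentage_metrics_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            compute_metrics(EvaluationPair(np.array([-1.0, 1.0]),
                                           np.array([0.0, 0.5])))

    def test_scale_invariances(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(10, 20, 50)
        pred = y + rng.normal(0, 1, 50)
        r2a, biasa, repa = compute_metrics(EvaluationPair(y, pred))
        # R2 invariant under simultaneous affine rescaling
        r2b, _, _ = compute_metrics(EvaluationPair(3 * y + 7, 3 * pred + 7))
        assert r2b == pytest.approx(r2a)
        # Bias% and REP invariant under positive multiplicative rescaling
        r2c, biasc, repc = compute_metrics(EvaluationPair(5 * y, 5 * pred))
        assert (biasc, repc) == (pytest.approx(biasa), pytest.approx(repa))
        assert r2c == pytest.approx(r2a)


def _toy_split(n=60, n_traits=10, seed=0, noise=0.02):
    """Spectra whose band means determine the traits linearly."""
    rng = np.random.default_rng(seed)
    wl = np.arange(400, 2400)
    base = 0.45 + 0.0 * wl
    coefs = rng.uniform(0.3, 1.0, n_traits)
    amp = rng.uniform(-1, 1, (n, n_traits))
    vals = np.tile(base, (n, 1))
    centres = np.linspace(500, 2300, n_traits)
    for j, c in enumerate(centres):
        bump = np.exp(-0.5 * ((wl - c) / 60.0) ** 2)
        vals += 0.05 * amp[:, [j]] * bump[None, :]
    vals += rng.normal(0, 0.002, vals.shape)
    names = [f"s{i}" for i in range(n)]
    traits = 50 + 10 * amp * coefs + rng.normal(0, noise, (n, n_traits))
    s = SpectrumSet(wl, np.clip(vals, 0, 1), names)
    t = TraitMatrix(names, traits, np.ones((n, n_traits), bool))
    return split_dataset(s, t, seed=seed)


def _tiny_cnn_config():
    return CNNConfig(conv_layers=(ConvLayerSpec(4), ConvLayerSpec(8)),
                     fc_sizes=(32, 16), n_outputs=10)


class TestEarlyStopping:
    def test_history_and_checkpoint_selection(self):
        split = _toy_split()
        model = build_model("cnn-multi", config=_tiny_cnn_config(), seed=0)
        cfg = TrainConfig(epochs=30, eval_interval=10, batch_size=16, seed=0,
                          spectral_trim=False, shift_rate=0.0)
        model, history = train_with_early_stopping(model, split, cfg)
        assert len(history) == 3
        assert [h["epoch"] for h in history] == [10, 20, 30]
        # retained weights reproduce the best recorded validation loss
        from leafspec.train import _dataset_arrays
        from leafspec.nn import masked_mse

        data = _dataset_arrays(split, model.trait_names)
        Xv, yv, mv = data["validation"]
        zv = np.where(mv, model.scaler.transform(yv), 0.0)
        pred = model.net.forward(np.asarray(Xv, np.float32)[:, None, :], training=False)
        recomputed = masked_mse(zv, pred, mv)
        assert recomputed == pytest.approx(min(h["val_loss"] for h in history),
                                           rel=1e-5)

    def test_deterministic_given_seed(self):
        split = _toy_split()
        cfg = TrainConfig(epochs=10, eval_interval=10, batch_size=16, seed=4,
                          spectral_trim=False, shift_rate=0.5)
        h1 = train_with_early_stopping(
            build_model("cnn-multi", config=_tiny_cnn_config(), seed=1), split, cfg)[1]
        h2 = train_with_early_stopping(
            build_model("cnn-multi", config=_tiny_cnn_config(), seed=1), split, cfg)[1]
        assert h1 == h2

    def test_interval_must_divide_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=105, eval_interval=10)

    def test_divergence_aborts_with_diagnostic(self):
        split = _toy_split()
        model = build_model("mlp", config=_tiny_cnn_config(), seed=0)
        cfg = TrainConfig(epochs=10, eval_interval=10, batch_size=16, seed=0,
                          learning_rate=1e12, spectral_trim=False, shift_rate=0.0)
        with pytest.raises(RuntimeError, match="diverged"):
            train_with_early_stopping(model, split, cfg)


class TestTuneBaselines:
    def test_plsr_component_choice_matches_exhaustive_oracle(self):
        # Low-rank linear data: the tuned k must achieve the max validation
        # score over an independent exhaustive re-evaluation.
        split = _toy_split(n=80, seed=3)
        chosen = tune_baseline_hyperparams("plsr", split, max_components=12)
        assert 1 <= chosen["n_components"] <= 30
        from leafspec.train import _dataset_arrays, _validation_r2

        data = _dataset_arrays(split, TRAIT_NAMES)
        X, y, m = data["train"]
        scores = {}
        for k in range(1, 13):
            mod = PLSRModel(n_components=k).fit(X, y, m)
            scores[k] = _validation_r2(mod, data)
        assert scores[chosen["n_components"]] == pytest.approx(max(scores.values()))

    def test_component_search_capped_with_warning(self):
        split = _toy_split(n=20)
        with pytest.warns(UserWarning, match="capping"):
            chosen = tune_baseline_hyperparams("plsr", split)
        assert chosen["n_components"] <= 13

    def test_xgboost_choice_is_grid_member(self):
        split = _toy_split(n=40, n_traits=10, seed=1)
        # single-trait search keeps the 120-point grid affordable
        chosen = tune_baseline_hyperparams("xgboost", split, trait_names=("LMA",),
                                           n_estimators=5)
        assert chosen["learning_rate"] in XGBOOST_GRID["learning_rate"]
        assert chosen["max_depth"] in XGBOOST_GRID["max_depth"]
        assert chosen["colsample_bytree"] in XGBOOST_GRID["colsample_bytree"]


class TestMetricsReport:
    def test_aggregate_means_across_seeds(self):
        df1 = pd.DataFrame({"R2": [0.8], "AbsBiasPct": [1.0], "REP": [10.0]},
                           index=["LMA"])
        df2 = pd.DataFrame({"R2": [0.6], "AbsBiasPct": [3.0], "REP": [20.0]},
                           index=["LMA"])
        agg = MetricsReport.aggregate([
            MetricsReport("plsr", df1, seeds=(0,)),
            MetricsReport("plsr", df2, seeds=(1,)),
        ])
        assert agg.per_trait.loc["LMA", "R2"] == pytest.approx(0.7)
        assert agg.seeds == (0, 1)

    def test_aggregate_rejects_mixed_kinds(self):
        df = pd.DataFrame({"R2": [0.5], "AbsBiasPct": [1.0], "REP": [5.0]},
                          index=["LMA"])
        with pytest.raises(ValueError):
            MetricsReport.aggregate([MetricsReport("plsr", df),
                                     MetricsReport("mlp", df)])
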