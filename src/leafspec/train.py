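"""Loss, early-stopping training loop, baseline tuning and evaluation metrics.

Neural models train for a fixed number of epochs with Adam; the validation
partition is evaluated at a fixed interval and the parameters with the
lowest masked validation MSE are retained ("early stopping by checkpoint").
Test-set quality is summarised per trait by three chemometrics metrics:

* R² — coefficient of determination ``1 - SS_res / SS_tot`` (can go
  negative when predictions are worse than the observed mean),
* Abs(Bias%) — ``100 * |mean(y_hat) - mean(y)| / mean(y)``,
* REP — relative error of prediction, ``100 * RMSE / mean(y)``.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import TrimDistribution, expand_training_set, sample_trim_bounds
from .models import PLSRModel, PredictorModel, TargetScaler, XGBoostModel, _NetModel
from .nn import Adam, masked_mse, masked_mse_grad
from .preprocess import SplitDataset, pad_to_grid, trim_to_range
from .spectra import TRAIT_NAMES

__all__ = [
    "TrainConfig",
    "EvaluationPair",
    "MetricsReport",
    "mse_loss",
    "train_with_early_stopping",
    "tune_baseline_hyperparams",
    "compute_metrics",
    "evaluate_model",
    "XGBOOST_GRID",
    "PLSR_COMPONENT_RANGE",
]

#: Printed hyperparameter search spaces for the baselines.
PLSR_COMPONENT_RANGE = (1, 30)
XGBOOST_GRID = {
    "learning_rate": (0.01, 0.02, 0.05, 0.06, 0.08, 0.1),
    "max_depth": (3, 5, 7, 9, 11),
    "colsample_bytree": (0.3, 0.5, 0.8, 1.0),
}


@dataclass
class TrainConfig:
    """Settings of the neural training loop.

    ``epochs``/``eval_interval`` implement checkpoint-style early stopping:
    train to the end, keep the weights with the best validation loss along
    the way.  ``shift_rate`` expands the training set offline with randomly
    shifted copies; ``spectral_trim`` switches the online trimming
    augmentation (applied only to models that opt in).
    """

    epochs: int = 1000
    eval_interval: int = 10
    learning_rate: float = 1e-4
    batch_size: int = 32
    seed: int = 0
    shift_rate: float = 0.5
    spectral_trim: bool = True
    trim_distribution: TrimDistribution = field(default_factory=TrimDistribution)

    def __post_init__(self) -> None:
        if self.epochs % self.eval_interval != 0:
            raise ValueError("eval_interval must divide epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EvaluationPair:
    """Observed vs predicted values with a validity mask."""

    y: np.ndarray
    y_hat: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        if self.y.shape != self.y_hat.shape:
            raise ValueError("y and y_hat must share a shape")
        if self.mask is None:
            self.mask = np.ones(self.y.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n(self) -> int:
        return int(self.mask.sum())


def mse_loss(pair: EvaluationPair) -> float:
    """Masked mean squared error (per-trait means summed for multi-task pairs)."""
    return masked_mse(pair.y, pair.y_hat, pair.mask)


def _dataset_arrays(split: SplitDataset, trait_names) -> dict:
    """Fixed-grid spectra and per-partition targets for the requested traits."""
    X = pad_to_grid(trim_to_range(split.spectra), 400, 2400)
    cols = [TRAIT_NAMES.index(t) for t in trait_names]
    out = {}
    for part in ("train", "validation", "test"):
        idx = split.indices(part)
        out[part] = (X[idx], split.traits.values[np.ix_(idx, cols)],
                     split.traits.mask[np.ix_(idx, cols)])
    return out


def train_with_early_stopping(model: _NetModel, split: SplitDataset,
                              cfg: TrainConfig | None = None,
                              verbose: bool = False):
    """Train a network, retaining the checkpoint with the best validation loss.

    Returns ``(model, history)`` where ``history`` is a list of
    ``{"epoch", "train_loss", "val_loss"}`` records, one per evaluation.
    The model is left holding the best checkpoint's weights.  Deterministic
    given ``cfg.seed`` (single-threaded numpy).
    """
    cfg = cfg or TrainConfig()
    data = _dataset_arrays(split, model.trait_names)
    X_tr, y_tr, m_tr = data["train"]
    X_val, y_val, m_val = data["validation"]
    if X_tr.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("training and validation partitions must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    if cfg.shift_rate > 0:
        X_tr, y_tr, m_tr = expand_training_set(
            X_tr, y_tr, m_tr, rate=cfg.shift_rate,
            seed=int(rng.integers(2**31)))

    model.scaler = TargetScaler.fit(y_tr, m_tr)
    z_tr = np.where(m_tr, model.scaler.transform(y_tr), 0.0)
    z_val = np.where(m_val, model.scaler.transform(y_val), 0.0)
    X_val32 = np.asarray(X_val, dtype=np.float32)

    trim = cfg.spectral_trim and getattr(model, "spectral_trim", False)
    opt = Adam(model.net, lr=cfg.learning_rate)
    n = X_tr.shape[0]
    history: list[dict] = []
    best = {"val_loss": np.inf, "state": None}

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = X_tr[idx]
            if trim:
                low, high = sample_trim_bounds(cfg.trim_distribution, rng, size=idx.size)
                wl = 400 + np.arange(xb.shape[1])
                keep = (wl[None, :] >= low[:, None]) & (wl[None, :] <= high[:, None])
                xb = np.where(keep, xb, 0.0)
            yb, mb = z_tr[idx], m_tr[idx]
            if not mb.any():
                continue
            model.net.zero_grad()
            pred = model.forward(xb, training=True, rng=rng)
            loss = masked_mse(yb, pred, mb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss}); "
                    "lower the learning rate or check the inputs"
                )
            grad = masked_mse_grad(yb, pred, mb).astype(np.float32)
            model.net.backward(grad)
            opt.step()
            epoch_loss += loss * idx.size
        if epoch % cfg.eval_interval == 0:
            pred_val = model.net.forward(X_val32[:, None, :], training=False)
            val_loss = masked_mse(z_val, pred_val, m_val)
            history.append({
                "epoch": epoch,
                "train_loss": epoch_loss / n,
                "val_loss": float(val_loss),
            })
            if verbose:
                print(f"epoch {epoch:5d}  train {epoch_loss / n:.5f}  val {val_loss:.5f}",
                      flush=True)
            if val_loss < best["val_loss"]:
                best = {"val_loss": float(val_loss),
                        "state": copy.deepcopy(model.net.state_dict())}
    if best["state"] is not None:
        model.net.load_state_dict(best["state"])
    model.fitted = True
    return model, history


def _validation_r2(model: PredictorModel, data: dict) -> float:
    """Mean R² across traits on the validation partition (NaN-safe)."""
    X_val, y_val, m_val = data["validation"]
    pred = model.predict_values(X_val)
    scores = []
    for j in range(y_val.shape[1]):
        rows = m_val[:, j] & np.isfinite(pred[:, j])
        if rows.sum() < 2 or np.var(y_val[rows, j]) == 0:
            continue
        scores.append(r_squared(y_val[rows, j], pred[rows, j]))
    return float(np.mean(scores)) if scores else -np.inf


def tune_baseline_hyperparams(kind: str, split: SplitDataset,
                              trait_names=TRAIT_NAMES,
                              wavelength_range: tuple = (400, 2400),
                              n_estimators: int = 100,
                              max_components: int | None = None) -> dict:
    """Choose baseline hyperparameters by mean validation R².

    PLSR: component count searched over 1..30 (capped below the training
    sample count, with a warning).  XGBoost: (learning rate, max depth,
    column subsample) over the fixed 6 x 5 x 4 grid.  Ties break toward the
    simpler model — fewer components, shallower trees.
    """
    data = _dataset_arrays(split, trait_names)
    X_tr, y_tr, m_tr = data["train"]
    if kind == "plsr":
        lo, hi = PLSR_COMPONENT_RANGE
        hi = min(hi, max_components or hi)
        cap = X_tr.shape[0] - 1
        if cap < hi:
            warnings.warn(
                f"training set smaller than the component search upper bound; "
                f"capping the search at {cap} components")
            hi = max(lo, cap)
        best_k, best_score = lo, -np.inf
        for k in range(lo, hi + 1):
            m = PLSRModel(wavelength_range, n_components=k, trait_names=trait_names)
            m.fit(X_tr, y_tr, m_tr)
            score = _validation_r2(m, data)
            if score > best_score:  # strict: ties keep the smaller k
                best_k, best_score = k, score
        return {"n_components": best_k, "validation_r2": best_score}
    if kind == "xgboost":
        best, best_score = None, -np.inf
        for depth in XGBOOST_GRID["max_depth"]:
            for lr in XGBOOST_GRID["learning_rate"]:
                for cs in XGBOOST_GRID["colsample_bytree"]:
                    m = XGBoostModel(lr, depth, cs, n_estimators=n_estimators,
                                     wavelength_range=wavelength_range,
                                     trait_names=trait_names)
                    m.fit(X_tr, y_tr, m_tr)
                    score = _validation_r2(m, data)
                    if score > best_score:  # depth ascends first: ties stay shallow
                        best_score = score
                        best = {"learning_rate": lr, "max_depth": depth,
                                "colsample_bytree": cs}
        return {**best, "validation_r2": best_score}
    raise ValueError(f"unknown baseline kind {kind!r}")


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination; negative when worse than the mean predictor."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values have zero variance")
    ss_res = float(((y - y_hat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def compute_metrics(pair: EvaluationPair) -> tuple[float, float, float]:
    """(R², Abs(Bias%), REP) over the valid entries of an evaluation pair."""
    rows = pair.mask
    y, y_hat = pair.y[rows], pair.y_hat[rows]
    if y.size < 2:
        raise ValueError("metrics need at least 2 valid pairs")
    mean_y = float(y.mean())
    r2 = r_squared(y, y_hat)
    if mean_y == 0:
        raise ValueError("percentage metrics undefined: mean(y) is zero")
    bias_pct = abs(100.0 * (float(y_hat.mean()) - mean_y) / mean_y)
    rep = 100.0 * float(np.sqrt(np.mean((y - y_hat) ** 2))) / mean_y
    return r2, bias_pct, rep


@dataclass
class MetricsReport:
    """Per-trait test metrics for one model (optionally averaged over seeds)."""

    model_kind: str
    per_trait: pd.DataFrame  # index: trait; columns: R2, AbsBiasPct, REP
    seeds: tuple = (0,)

    @property
    def mean(self) -> pd.Series:
        return self.per_trait.mean(axis=0)

    @classmethod
    def aggregate(cls, reports: list["MetricsReport"]) -> "MetricsReport":
        """Mean across runs with different seeds (the standard reporting rule)."""
        if not reports:
            raise ValueError("nothing to aggregate")
        kinds = {r.model_kind for r in reports}
        if len(kinds) != 1:
            raise ValueError(f"cannot aggregate across model kinds {kinds}")
        per = sum(r.per_trait for r in reports) / len(reports)
        seeds = tuple(s for r in reports for s in r.seeds)
        return cls(reports[0].model_kind, per, seeds)


def evaluate_model(model: PredictorModel, split: SplitDataset,
                   partition: str = "test") -> MetricsReport:
    """Compute per-trait (R², Abs(Bias%), REP) on one partition."""
    data = _dataset_arrays(split, model.trait_names)
    X, y, mask = data[partition]
    pred = model.predict_values(X)
    rows_out = {}
    for j, name in enumerate(model.trait_names):
        rows = mask[:, j] & np.isfinite(pred[:, j])
        if rows.sum() < 2:
            rows_out[name] = (np.nan, np.nan, np.nan)
            continue
        pair = EvaluationPair(y[rows, j], pred[rows, j])
        rows_out[name] = compute_metrics(pair)
    df = pd.DataFrame(rows_out, index=["R2", "AbsBiasPct", "REP"]).T
    return MetricsReport(model.kind, df, seeds=(split.seed,))
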