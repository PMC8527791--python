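"""The predictor family: dilated 1D CNN, MLP, LSTM, PLSR, XGBoost, ensemble.

The central model is a dilated 1-D convolutional network over the pooled
reflectance sequence.  Dilation widens the receptive field: a stride-1
stack sees ``1 + sum((k_l - 1) * d_l)`` input elements per output neuron,
so four kernel-5, dilation-2 layers view 33 pooled positions (330 nm of raw
spectrum) — enough context to relate pigment features in the visible range
to water/structure features in the SWIR after pooling and flattening.

The multi-task variant shares the whole network across the ten traits and
only the final fully connected layer has ten outputs; single-task variants
are identical with one output.  Classical baselines (PLSR per fixed
wavelength range, XGBoost) and a plain-mean ensemble complete the family.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from . import nn
from .preprocess import pad_to_grid, trim_to_range
from .spectra import TRAIT_NAMES, SpectrumSet

__all__ = [
    "ConvLayerSpec",
    "CNNConfig",
    "LSTMConfig",
    "PredictorModel",
    "dilated_conv1d",
    "receptive_field",
    "build_model",
    "ensemble_predict",
    "match_plsr_range",
    "PLSR_RANGE_OPTIONS",
    "DEFAULT_ENSEMBLE_MEMBERS",
    "save_model",
    "load_model",
]

#: Fixed wavelength ranges (half-open, nm) for which separate PLSR models exist.
PLSR_RANGE_OPTIONS = ((400, 900), (400, 1000), (400, 1700), (400, 2400))

#: Default ensemble membership: both spectrally-trimmed CNNs plus full-range PLSR.
DEFAULT_ENSEMBLE_MEMBERS = ("cnn-multi", "cnn-single", "plsr")


@dataclass(frozen=True)
class ConvLayerSpec:
    """One dilated convolutional layer: kernel, channels, dilation, batch norm, ReLU."""

    out_channels: int
    kernel_size: int = 5
    dilation: int = 2
    stride: int = 1
    batch_norm: bool = True
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.dilation < 1 or self.out_channels < 1:
            raise ValueError("dilation and out_channels must be >= 1")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class CNNConfig:
    """Architecture of the convolutional trait predictor.

    Defaults reproduce the reference architecture: average-pool 10, four
    kernel-5 dilation-2 conv layers with 75/150/225/300 channels (each with
    batch norm and ReLU), then fully connected 800 -> 200 with ReLU and
    dropout 0.2 after each hidden layer, and a 10-output (multi-task) or
    1-output (single-task) linear head.
    """

    input_length: int = 2000
    pool_window: int = 10
    conv_layers: tuple = (
        ConvLayerSpec(75),
        ConvLayerSpec(150),
        ConvLayerSpec(225),
        ConvLayerSpec(300),
    )
    fc_sizes: tuple = (800, 200)
    dropout: float = 0.2
    n_outputs: int = 10

    def __post_init__(self) -> None:
        if self.n_outputs not in (1, 10):
            raise ValueError("n_outputs must be 1 (single-task) or 10 (multi-task)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def pooled_length(self) -> int:
        return -(-self.input_length // self.pool_window)


@dataclass(frozen=True)
class LSTMConfig:
    """Recurrent baseline: pooled input, 2-layer bidirectional LSTM, FC 200 head."""

    input_length: int = 2000
    pool_window: int = 10
    hidden_size: int = 100
    num_layers: int = 2
    bidirectional: bool = True
    fc_size: int = 200
    n_outputs: int = 1


def dilated_conv1d(x: np.ndarray, layer: ConvLayerSpec, W: np.ndarray,
                   B: np.ndarray) -> np.ndarray:
    """Apply one dilated 1-D convolution layer to ``x`` of shape (channels, length).

    Output channel ``c_o`` is ``f(sum_ci W[c_o, c_i] (*) x[c_i] + B[c_o])``
    where ``(*)`` is the dilated, stride-1, 'same'-zero-padded sliding dot
    product and ``f`` the layer activation.  Batch normalisation, being a
    training-time statistic, is handled by the network, not this pure op.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must have shape (channels, length)")
    W = np.asarray(W, dtype=float)
    B = np.asarray(B, dtype=float)
    if W.shape != (layer.out_channels, x.shape[0], layer.kernel_size):
        raise ValueError(
            f"kernel shape {W.shape} incompatible with layer "
            f"(expected {(layer.out_channels, x.shape[0], layer.kernel_size)})"
        )
    from .nn.layers import _dilated_corr

    y, _ = _dilated_corr(x[None], W, layer.dilation)
    y = y[0] + B[:, None]
    if layer.activation == "relu":
        y = np.maximum(y, 0)
    return y


def receptive_field(filter_sizes, dilations, strides=None) -> int:
    """Input elements seen by one output neuron of a stride-1 dilated stack.

    For stride-1 layers the receptive field grows by ``(k_l - 1) * d_l``
    per layer: ``rf = 1 + sum_l (k_l - 1) * d_l``.  The worked two-layer
    example — kernels (5, 5), dilations (1, 2) — gives 1 + 4 + 8 = 13.
    """
    filter_sizes = list(filter_sizes)
    dilations = list(dilations)
    if strides is None:
        strides = [1] * len(filter_sizes)
    strides = list(strides)
    if not filter_sizes:
        raise ValueError("at least one layer required")
    if not (len(filter_sizes) == len(dilations) == len(strides)):
        raise ValueError("filter_sizes, dilations and strides must have equal length")
    if any(s != 1 for s in strides):
        raise ValueError("only stride-1 stacks are supported")
    rf = 1
    for k, d in zip(filter_sizes, dilations):
        rf += (k - 1) * d
    return rf


@dataclass
class TargetScaler:
    """Per-trait z-scoring fitted on training data and inverted at prediction.

    The ten traits span three orders of magnitude (stomatal conductance
    ~0.5 vs electron transport ~220), so an unscaled multi-task MSE would be
    dominated by the large-valued traits.
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, y: np.ndarray, mask: np.ndarray) -> "TargetScaler":
        y = np.where(mask, y, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(y, axis=0)
            std = np.nanstd(y, axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        std = np.where(np.isnan(std) | (std == 0), 1.0, std)
        return cls(mean, std)

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.std + self.mean


class PredictorModel:
    """Common interface: map spectra on the fixed [400, 2400) grid to trait values."""

    kind: str = "base"

    def __init__(self, trait_names=TRAIT_NAMES) -> None:
        self.trait_names = tuple(trait_names)
        self.fitted = False

    # Subclasses implement prediction on the raw feature matrix.
    def predict_values(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, s: SpectrumSet) -> pd.DataFrame:
        """Predict traits for every observation of a SpectrumSet.

        The spectra are trimmed to [400, 2400) and zero-padded onto the full
        grid where coverage is narrower, consistent with the zero-filled
        spectral-trimming convention used in training.
        """
        X = pad_to_grid(trim_to_range(s), 400, 2400)
        values = self.predict_values(X)
        return pd.DataFrame(values, index=list(s.names), columns=list(self.trait_names))

    def config_dict(self) -> dict:
        raise NotImplementedError


class _NetModel(PredictorModel):
    """Shared plumbing for the numpy network-backed predictors."""

    def __init__(self, config, trait_names, seed: int = 0) -> None:
        super().__init__(trait_names)
        self.config = config
        self.seed = seed
        self.net = self._build_net(np.random.default_rng(seed))
        self.scaler: TargetScaler | None = None

    def _build_net(self, rng) -> nn.Sequential:
        raise NotImplementedError

    def forward(self, X: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        return self.net.forward(X[:, None, :], training=training, rng=rng)

    def predict_values(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is None:
            raise RuntimeError("model has no fitted target scaler; train it first")
        z = self.forward(X, training=False).astype(float)
        return self.scaler.inverse(z)

    def config_dict(self) -> dict:
        def encode(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: encode(v) for k, v in asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            return obj

        return {
            "kind": self.kind,
            "traits": list(self.trait_names),
            "config": encode(self.config),
        }


class CNNModel(_NetModel):
    """Dilated 1-D CNN predictor (multi-task when it has ten outputs)."""

    def __init__(self, config: CNNConfig | None = None, trait_names=TRAIT_NAMES,
                 seed: int = 0, spectral_trim: bool = True) -> None:
        config = config or CNNConfig(n_outputs=len(tuple(trait_names)))
        if config.n_outputs != len(tuple(trait_names)):
            raise ValueError("n_outputs must match the number of predicted traits")
        self.kind = "cnn-multi" if config.n_outputs > 1 else "cnn-single"
        #: whether online spectral trimming is applied while training this model
        self.spectral_trim = spectral_trim
        super().__init__(config, trait_names, seed)

    def _build_net(self, rng) -> nn.Sequential:
        cfg = self.config
        layers: list[nn.Layer] = [nn.AvgPool1d(cfg.pool_window)]
        in_ch = 1
        for spec in cfg.conv_layers:
            layers.append(nn.Conv1d(in_ch, spec.out_channels, spec.kernel_size,
                                    spec.dilation, rng=rng))
            if spec.batch_norm:
                layers.append(nn.BatchNorm1d(spec.out_channels))
            if spec.activation == "relu":
                layers.append(nn.ReLU())
            in_ch = spec.out_channels
        layers.append(nn.Flatten())
        width = in_ch * cfg.pooled_length
        for fc in cfg.fc_sizes:
            layers.append(nn.Linear(width, fc, rng=rng))
            layers.append(nn.ReLU())
            layers.append(nn.Dropout(cfg.dropout))
            width = fc
        layers.append(nn.Linear(width, cfg.n_outputs, rng=rng))
        return nn.Sequential(layers)


class MLPModel(_NetModel):
    """Fully connected baseline on the pooled spectrum.

    Reuses the CNN's pooled input and fully connected head (800 -> 200 with
    ReLU and dropout) without the convolutional stack, so the comparison
    against the CNN isolates the contribution of the convolutions.
    """

    kind = "mlp"

    def __init__(self, config: CNNConfig | None = None, trait_names=TRAIT_NAMES,
                 seed: int = 0) -> None:
        config = config or CNNConfig(n_outputs=len(tuple(trait_names)))
        self.spectral_trim = False
        super().__init__(config, trait_names, seed)

    def _build_net(self, rng) -> nn.Sequential:
        cfg = self.config
        layers: list[nn.Layer] = [nn.AvgPool1d(cfg.pool_window), nn.Flatten()]
        width = cfg.pooled_length
        for fc in cfg.fc_sizes:
            layers.append(nn.Linear(width, fc, rng=rng))
            layers.append(nn.ReLU())
            layers.append(nn.Dropout(cfg.dropout))
            width = fc
        layers.append(nn.Linear(width, cfg.n_outputs, rng=rng))
        return nn.Sequential(layers)


class _ToSequence(nn.Layer):
    """(batch, channels, length) -> (batch, length, channels) adapter."""

    def forward(self, x, training=False, rng=None):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dy):
        return np.ascontiguousarray(dy.transpose(0, 2, 1))


class LSTMModel(_NetModel):
    """Single-task recurrent baseline over the pooled reflectance sequence."""

    kind = "lstm"

    def __init__(self, config: LSTMConfig | None = None, trait_names=("LMA",),
                 seed: int = 0) -> None:
        config = config or LSTMConfig()
        if config.n_outputs != len(tuple(trait_names)):
            raise ValueError("n_outputs must match the number of predicted traits")
        self.spectral_trim = False
        super().__init__(config, trait_names, seed)

    def _build_net(self, rng) -> nn.Sequential:
        cfg = self.config
        encoder = nn.LSTMEncoder(1, cfg.hidden_size, cfg.num_layers,
                                 cfg.bidirectional, rng=rng)
        return nn.Sequential([
            nn.AvgPool1d(cfg.pool_window),
            _ToSequence(),
            encoder,
            nn.Linear(encoder.output_size, cfg.fc_size, rng=rng),
            nn.ReLU(),
            nn.Linear(cfg.fc_size, cfg.n_outputs, rng=rng),
        ])


class PLSRModel(PredictorModel):
    """Partial least squares baseline on raw per-nm reflectance of a fixed range.

    One scikit-learn PLS regression per trait (missingness differs across
    traits) sharing a single component count chosen on the validation set.
    """

    kind = "plsr"

    def __init__(self, wavelength_range: tuple = (400, 2400), n_components: int = 10,
                 trait_names=TRAIT_NAMES) -> None:
        super().__init__(trait_names)
        if tuple(wavelength_range) not in PLSR_RANGE_OPTIONS:
            raise ValueError(
                f"wavelength_range must be one of {PLSR_RANGE_OPTIONS}"
            )
        self.wavelength_range = tuple(wavelength_range)
        self.n_components = int(n_components)
        self.models: dict[str, PLSRegression] = {}

    def _slice(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.wavelength_range
        return X[:, lo - 400 : hi - 400]

    def fit(self, X: np.ndarray, y: np.ndarray, mask: np.ndarray) -> "PLSRModel":
        Xr = self._slice(np.asarray(X, dtype=float))
        y = np.atleast_2d(y)
        mask = np.atleast_2d(mask)
        for j, name in enumerate(self.trait_names):
            rows = np.flatnonzero(mask[:, j])
            if rows.size < 2:
                continue
            k = min(self.n_components, rows.size - 1, Xr.shape[1])
            m = PLSRegression(n_components=k, scale=True)
            m.fit(Xr[rows], y[rows, j])
            self.models[name] = m
        self.fitted = True
        return self

    def predict_values(self, X: np.ndarray) -> np.ndarray:
        Xr = self._slice(np.asarray(X, dtype=float))
        out = np.full((Xr.shape[0], len(self.trait_names)), np.nan)
        for j, name in enumerate(self.trait_names):
            if name in self.models:
                out[:, j] = self.models[name].predict(Xr).ravel()
        return out

    def predict(self, s: SpectrumSet) -> pd.DataFrame:
        lo, hi = self.wavelength_range
        if not (s.wavelengths[0] <= lo and s.wavelengths[-1] >= hi - 1):
            raise ValueError(
                f"spectra cover [{s.wavelengths[0]}, {s.wavelengths[-1]}] nm but this "
                f"PLSR variant requires full coverage of [{lo}, {hi}) nm"
            )
        X = pad_to_grid(trim_to_range(s), 400, 2400)
        values = self.predict_values(X)
        return pd.DataFrame(values, index=list(s.names), columns=list(self.trait_names))

    def config_dict(self) -> dict:
        return {
            "kind": self.kind,
            "traits": list(self.trait_names),
            "config": {"range": list(self.wavelength_range),
                       "n_components": self.n_components},
        }


class XGBoostModel(PredictorModel):
    """Gradient-boosted-trees baseline, one booster per trait on raw reflectance."""

    kind = "xgboost"

    def __init__(self, learning_rate: float = 0.05, max_depth: int = 5,
                 colsample_bytree: float = 0.5, n_estimators: int = 100,
                 wavelength_range: tuple = (400, 2400),
                 trait_names=TRAIT_NAMES, seed: int = 0) -> None:
        super().__init__(trait_names)
        self.params = {
            "learning_rate": learning_rate,
            "max_depth": max_depth,
            "colsample_bytree": colsample_bytree,
            "n_estimators": n_estimators,
        }
        self.wavelength_range = tuple(wavelength_range)
        self.seed = seed
        self.models = {}

    def _slice(self, X):
        lo, hi = self.wavelength_range
        return X[:, lo - 400 : hi - 400]

    def fit(self, X, y, mask) -> "XGBoostModel":
        import xgboost as xgb

        Xr = self._slice(np.asarray(X, dtype=float))
        y = np.atleast_2d(y)
        mask = np.atleast_2d(mask)
        for j, name in enumerate(self.trait_names):
            rows = np.flatnonzero(mask[:, j])
            if rows.size < 2:
                continue
            m = xgb.XGBRegressor(random_state=self.seed, n_jobs=1,
                                 verbosity=0, **self.params)
            m.fit(Xr[rows], y[rows, j])
            self.models[name] = m
        self.fitted = True
        return self

    def predict_values(self, X):
        Xr = self._slice(np.asarray(X, dtype=float))
        out = np.full((Xr.shape[0], len(self.trait_names)), np.nan)
        for j, name in enumerate(self.trait_names):
            if name in self.models:
                out[:, j] = self.models[name].predict(Xr)
        return out

    def config_dict(self) -> dict:
        return {"kind": self.kind, "traits": list(self.trait_names),
                "config": {**self.params, "range": list(self.wavelength_range)}}


class EnsembleModel(PredictorModel):
    """Plain-mean ensemble over member predictions.

    The reference membership is the spectrally-trimmed multi-task CNN, the
    spectrally-trimmed single-task CNNs and the full-range PLSR model.
    """

    kind = "ensemble"

    def __init__(self, members: list[PredictorModel], trait_names=TRAIT_NAMES) -> None:
        super().__init__(trait_names)
        if not members:
            raise ValueError("ensemble needs at least one member")
        for m in members:
            missing = set(trait_names) - set(m.trait_names)
            if missing:
                raise ValueError(
                    f"member {m.kind!r} does not predict traits {sorted(missing)}"
                )
        self.members = list(members)

    def predict_values(self, X: np.ndarray) -> np.ndarray:
        preds = []
        for m in self.members:
            cols = [m.trait_names.index(t) for t in self.trait_names]
            preds.append(m.predict_values(X)[:, cols])
        return np.mean(preds, axis=0)

    def config_dict(self) -> dict:
        return {"kind": self.kind, "traits": list(self.trait_names),
                "config": {"members": [m.config_dict() for m in self.members]}}


def ensemble_predict(members: list[PredictorModel], s: SpectrumSet,
                     trait_names=TRAIT_NAMES) -> pd.DataFrame:
    """Arithmetic mean of member predictions per observation per trait."""
    return EnsembleModel(members, trait_names).predict(s)


def match_plsr_range(s: SpectrumSet) -> tuple:
    """Largest predetermined PLSR range fully contained in the spectra's coverage."""
    lo, hi = int(s.wavelengths[0]), int(s.wavelengths[-1]) + 1  # half-open coverage
    contained = [r for r in PLSR_RANGE_OPTIONS if lo <= r[0] and r[1] <= hi]
    if not contained:
        raise ValueError(
            f"coverage [{lo}, {hi}) nm is narrower than the minimum supported "
            f"PLSR range [400, 900)"
        )
    return max(contained, key=lambda r: r[1] - r[0])


def build_model(kind: str, config=None, trait_names=TRAIT_NAMES, seed: int = 0,
                **kwargs) -> PredictorModel:
    """Construct an unfitted predictor of the requested kind.

    ``kind`` is one of ``cnn-multi``, ``cnn-single``, ``mlp``, ``lstm``,
    ``plsr``, ``xgboost``.  Single-output kinds (``cnn-single``, ``lstm``)
    expect ``trait_names`` with exactly one entry.
    """
    kind = kind.lower()
    if kind == "cnn-multi":
        cfg = config or CNNConfig(n_outputs=len(tuple(trait_names)))
        return CNNModel(cfg, trait_names, seed=seed, **kwargs)
    if kind == "cnn-single":
        names = tuple(trait_names)
        if len(names) != 1:
            raise ValueError("cnn-single predicts exactly one trait")
        cfg = config or CNNConfig(n_outputs=1)
        return CNNModel(cfg, names, seed=seed, **kwargs)
    if kind == "mlp":
        cfg = config or CNNConfig(n_outputs=len(tuple(trait_names)))
        return MLPModel(cfg, trait_names, seed=seed)
    if kind == "lstm":
        names = tuple(trait_names)
        if len(names) != 1:
            raise ValueError("lstm predicts exactly one trait")
        return LSTMModel(config, names, seed=seed)
    if kind == "plsr":
        return PLSRModel(trait_names=trait_names, **kwargs)
    if kind == "xgboost":
        return XGBoostModel(trait_names=trait_names, seed=seed, **kwargs)
    raise ValueError(f"unknown model kind {kind!r}")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def save_model(model: PredictorModel, path) -> None:
    """Persist a predictor as a self-describing archive (config + state).

    The archive stores the builder configuration and its hash; loading
    rejects archives whose configuration no longer hashes to the stored
    value, guarding against architecture drift.
    """
    cfg = model.config_dict()
    payload = {"config": cfg, "config_hash": _config_hash(cfg), "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> PredictorModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfg = payload["config"]
    if _config_hash(cfg) != payload["config_hash"]:
        raise ValueError(f"{path}: config hash mismatch — archive is corrupt or stale")
    model = payload["model"]
    rebuilt = model.config_dict()
    if _config_hash(rebuilt) != payload["config_hash"]:
        raise ValueError(f"{path}: stored model does not match its declared config")
    return model
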