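"""The nine fusion x backbone classifiers.

Fusion strategies
    early         one backbone over all 40 concatenated features
    intermediate  one backbone + attention pool per feature group, pooled
                  vectors concatenated into a shared feed-forward head
    late          a full per-group model each ending in a probability,
                  averaged into the final prediction

Backbones
    bilstm             Bi-LSTM over the full sequence + attention pooling
    window_block_lstm  the sequence cut into consecutive 1 s (30-frame)
                       windows, a shared LSTM + attention per window, then
                       attention over the window vectors
    transformer        mean-pool every 15 frames, sinusoidal positions, one
                       transformer encoder block, mean over time

Reference layer widths (Bi-LSTM hidden 128 early; per-group 64/16/128/128
intermediate; window-block 64 early, 32/32/64/64 intermediate; transformer
block with head size 512 and feed-forward dim 2048) are baked into
:func:`default_config` and overridable.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from facedep import schema
from facedep.nn import (
    AdditiveAttention,
    BiLSTM,
    LSTM,
    Linear,
    Module,
    Tensor,
    TransformerBlock,
    avg_pool_time,
    concatenate,
    sinusoidal_positions,
)
from facedep.openface_io import DEFAULT_HORIZON, FeatureScaler

FUSIONS = ("early", "intermediate", "late")
BACKBONES = ("bilstm", "window_block_lstm", "transformer")

_GROUP_HIDDEN = {
    "bilstm": {"Pose": 64, "Gaze": 16, "AU_r": 128, "AU_c": 128},
    "window_block_lstm": {"Pose": 32, "Gaze": 32, "AU_r": 64, "AU_c": 64},
}


@dataclass
class TransformerParams:
    blocks: int = 1
    head_size: int = 512
    n_heads: int = 1
    ff_dim: int = 2048
    pool_stride: int = 15


@dataclass
class ModelConfig:
    fusion: str
    backbone: str
    horizon: int = DEFAULT_HORIZON
    window_len: int = 30
    hidden: int = 128                                  # early-fusion width
    group_hidden: dict[str, int] = field(default_factory=dict)
    head_widths: tuple[int, ...] = (64, 32, 1)
    transformer: TransformerParams = field(default_factory=TransformerParams)

    def __post_init__(self) -> None:
        if self.fusion not in FUSIONS:
            raise ValueError(f"unknown fusion {self.fusion!r}; expected {FUSIONS}")
        if self.backbone not in BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; expected {BACKBONES}")
        if isinstance(self.transformer, dict):
            self.transformer = TransformerParams(**self.transformer)
        self.head_widths = tuple(self.head_widths)
        if self.head_widths[-1] != 1:
            raise ValueError("head_widths must terminate in 1")
        extra = set(self.group_hidden) - set(schema.GROUP_SLICES)
        if extra:
            raise ValueError(f"unknown feature groups in group_hidden: {extra}")
        if self.backbone == "window_block_lstm" and self.horizon % self.window_len:
            raise ValueError(
                f"horizon {self.horizon} is not divisible by window length "
                f"{self.window_len}"
            )

    @property
    def n_windows(self) -> int:
        return self.horizon // self.window_len

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "ModelConfig":
        raw = json.loads(payload)
        raw["head_widths"] = tuple(raw["head_widths"])
        return cls(**raw)


def default_config(fusion: str, backbone: str,
                   horizon: int = DEFAULT_HORIZON) -> ModelConfig:
    """The reference configuration for each of the nine models."""
    cfg = ModelConfig(fusion=fusion, backbone=backbone, horizon=horizon)
    if fusion == "early":
        if backbone == "bilstm":
            cfg.hidden, cfg.head_widths = 128, (64, 32, 1)
        elif backbone == "window_block_lstm":
            cfg.hidden, cfg.head_widths = 64, (32, 16, 1)
        else:
            cfg.head_widths = (64, 32, 1)
    else:
        if backbone in _GROUP_HIDDEN:
            cfg.group_hidden = dict(_GROUP_HIDDEN[backbone])
        if backbone == "window_block_lstm":
            cfg.head_widths = (128, 64, 32, 16, 1)
        else:
            cfg.head_widths = (128, 64, 1)
        if fusion == "late":
            # late fusion doubles the feed-forward widths (final 1 kept)
            cfg.head_widths = tuple(w * 2 for w in cfg.head_widths[:-1]) + (1,)
    return cfg


@dataclass(frozen=True)
class Prediction:
    """Depressed-probability plus the thresholded decision."""

    p: float
    decision: int
    threshold: float = 0.5

    @classmethod
    def from_prob(cls, p: float, threshold: float = 0.5) -> "Prediction":
        p = float(p)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of range: {p}")
        return cls(p=p, decision=int(p >= threshold), threshold=threshold)


# ---------------------------------------------------------------------------
# functional building blocks (also exposed standalone)
# ---------------------------------------------------------------------------

def window_reshape(series: np.ndarray, window_len: int) -> np.ndarray:
    """Cut a (T, F) series into consecutive windows: (T/w, w, F)."""
    series = np.asarray(series)
    t = series.shape[0]
    if t % window_len:
        raise ValueError(
            f"sequence length {t} is not divisible by window length {window_len}"
        )
    return series.reshape(t // window_len, window_len, series.shape[1])


def inverse_window_reshape(windows: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`window_reshape`."""
    windows = np.asarray(windows)
    n, w, f = windows.shape
    return windows.reshape(n * w, f)


def attention_pool(hidden_states: np.ndarray,
                   attention: AdditiveAttention | None = None,
                   seed: int = 0) -> np.ndarray:
    """Pool a (T, H) matrix to an (H,) vector with additive attention."""
    h = np.asarray(hidden_states, dtype=float)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("hidden_states must be a (T, H) matrix with T >= 1")
    if attention is None:
        attention = AdditiveAttention(h.shape[1], np.random.default_rng(seed))
    pooled = attention(Tensor(h[None]))
    return pooled.data[0]


def late_fusion_aggregate(group_probs, threshold: float = 0.5) -> Prediction:
    """Average per-group probabilities into the final prediction."""
    probs = [float(p) for p in group_probs]
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise ValueError(f"probabilities out of range: {probs}")
    return Prediction.from_prob(sum(probs) / len(probs), threshold)


# ---------------------------------------------------------------------------
# encoders: (B, T, F) -> (B, D)
# ---------------------------------------------------------------------------

class _BiLSTMEncoder(Module):
    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.lstm = BiLSTM(input_dim, hidden, rng)
        self.attention = AdditiveAttention(2 * hidden, rng)
        self.out_dim = 2 * hidden

    def forward(self, x: Tensor) -> Tensor:
        return self.attention(self.lstm(x))


class _WindowBlockEncoder(Module):
    """Shared LSTM + attention per 30-frame window, attention over windows."""

    def __init__(self, input_dim: int, hidden: int, window_len: int,
                 rng: np.random.Generator):
        self.window_len = window_len
        self.lstm = LSTM(input_dim, hidden, rng)
        self.frame_attention = AdditiveAttention(hidden, rng)
        self.window_attention = AdditiveAttention(hidden, rng)
        self.out_dim = hidden

    def forward(self, x: Tensor) -> Tensor:
        B, T, F = x.shape
        if T % self.window_len:
            raise ValueError(
                f"sequence length {T} not divisible by window {self.window_len}"
            )
        n_w = T // self.window_len
        windows = x.reshape(B * n_w, self.window_len, F)
        h = self.lstm(windows)                            # (B*n_w, L, H)
        pooled = self.frame_attention(h)                  # (B*n_w, H)
        vectors = pooled.reshape(B, n_w, self.out_dim)    # (B, n_w, H)
        return self.window_attention(vectors)             # (B, H)


class _TransformerEncoder(Module):
    """Mean-pool by stride, add sinusoidal positions, encode, mean over time."""

    def __init__(self, input_dim: int, params: TransformerParams,
                 rng: np.random.Generator):
        self.params = params
        self.blocks = [
            TransformerBlock(input_dim, params.head_size, params.n_heads,
                             params.ff_dim, rng)
            for _ in range(params.blocks)
        ]
        self.out_dim = input_dim

    def forward(self, x: Tensor) -> Tensor:
        pooled = avg_pool_time(x, self.params.pool_stride)
        enc = sinusoidal_positions(pooled.shape[1], pooled.shape[2])
        pooled = pooled + Tensor(enc[None])
        for block in self.blocks:
            pooled = block(pooled)
        return pooled.mean(axis=1)


def _make_encoder(backbone: str, input_dim: int, hidden: int,
                  config: ModelConfig, rng: np.random.Generator) -> Module:
    if backbone == "bilstm":
        return _BiLSTMEncoder(input_dim, hidden, rng)
    if backbone == "window_block_lstm":
        return _WindowBlockEncoder(input_dim, hidden, config.window_len, rng)
    return _TransformerEncoder(input_dim, config.transformer, rng)


class _Head(Module):
    """Feed-forward stack: ReLU hidden layers, sigmoid width-1 output."""

    def __init__(self, input_dim: int, widths: tuple[int, ...],
                 rng: np.random.Generator):
        self.layers = []
        d = input_dim
        for w in widths[:-1]:
            self.layers.append(Linear(d, w, rng, activation="relu"))
            d = w
        self.layers.append(Linear(d, 1, rng, activation="sigmoid"))

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x.reshape(x.shape[0])                      # (B,)


# ---------------------------------------------------------------------------
# full models: (B, T, 40) -> (B,) probability of depressed
# ---------------------------------------------------------------------------

class _FusionModel(Module):
    config: ModelConfig

    def _coerce(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=float))
        if x.ndim != 3:
            raise ValueError(f"expected a (B, T, F) batch, got shape {x.shape}")
        return x

    def predict_proba(self, x) -> np.ndarray:
        from facedep.nn import no_grad
        with no_grad():
            return self.forward(x).data


class EarlyFusionModel(_FusionModel):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        n_features = len(schema.SELECTED_FEATURES)
        self.encoder = _make_encoder(config.backbone, n_features,
                                     config.hidden, config, rng)
        self.head = _Head(self.encoder.out_dim, config.head_widths, rng)

    def forward(self, x) -> Tensor:
        return self.head(self.encoder(self._coerce(x)))


class IntermediateFusionModel(_FusionModel):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        widths = schema.group_widths()
        self.encoders = {}
        concat_dim = 0
        for name, sl in schema.GROUP_SLICES.items():
            hidden = config.group_hidden.get(name, config.hidden)
            enc = _make_encoder(config.backbone, widths[name], hidden,
                                config, rng)
            self.encoders[name] = enc
            concat_dim += enc.out_dim
        self.head = _Head(concat_dim, config.head_widths, rng)

    def forward(self, x) -> Tensor:
        x = self._coerce(x)
        pooled = [
            self.encoders[name](x[:, :, sl])
            for name, sl in schema.GROUP_SLICES.items()
        ]
        return self.head(concatenate(pooled, axis=-1))


class LateFusionModel(_FusionModel):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        widths = schema.group_widths()
        self.encoders, self.heads = {}, {}
        for name, sl in schema.GROUP_SLICES.items():
            hidden = config.group_hidden.get(name, config.hidden)
            enc = _make_encoder(config.backbone, widths[name], hidden,
                                config, rng)
            self.encoders[name] = enc
            self.heads[name] = _Head(enc.out_dim, config.head_widths, rng)

    def group_probabilities(self, x) -> Tensor:
        x = self._coerce(x)
        probs = [
            self.heads[name](self.encoders[name](x[:, :, sl])).reshape(
                x.shape[0], 1)
            for name, sl in schema.GROUP_SLICES.items()
        ]
        return concatenate(probs, axis=1)                 # (B, 4)

    def forward(self, x) -> Tensor:
        return self.group_probabilities(x).mean(axis=1)


_FUSION_CLASSES = {
    "early": EarlyFusionModel,
    "intermediate": IntermediateFusionModel,
    "late": LateFusionModel,
}


def build_model(config: ModelConfig, seed: int = 0) -> _FusionModel:
    """Instantiate the classifier described by ``config`` (seeded init)."""
    rng = np.random.default_rng(seed)
    return _FUSION_CLASSES[config.fusion](config, rng)


def save_checkpoint(path: str | os.PathLike, model: _FusionModel,
                    scaler: FeatureScaler | None = None) -> None:
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    arrays["config_json"] = np.array(model.config.to_json())
    if scaler is not None and scaler.mean_ is not None:
        arrays["scaler_mean"] = scaler.mean_
        arrays["scaler_scale"] = scaler.scale_
    np.savez(path, **arrays)


def load_checkpoint(path: str | os.PathLike):
    """Returns ``(model, scaler_or_None)``; the config rides inside the file."""
    with np.load(path, allow_pickle=False) as npz:
        config = ModelConfig.from_json(str(npz["config_json"]))
        state = {
            k.removeprefix("param::"): npz[k]
            for k in npz.files if k.startswith("param::")
        }
        scaler = None
        if "scaler_mean" in npz.files:
            scaler = FeatureScaler.from_arrays(npz["scaler_mean"],
                                               npz["scaler_scale"])
    model = build_model(config)
    model.load_state_dict(state)
    return model, scaler
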