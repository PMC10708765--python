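"""Ingestion of OpenFace-dialect CSVs: parse, join, select, pad, scale.

Per-participant interview answers arrive as separate CSV segments; segments
are concatenated in manifest order, projected down to the 40 retained
feature columns, z-scaled with training-split statistics, and zero-padded to
a fixed horizon so every series shares one shape.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from facedep import schema

logger = logging.getLogger(__name__)

#: 11 minutes at 30 frames/s
DEFAULT_HORIZON = 11 * 60 * 30


class SchemaError(ValueError):
    """Raised when a CSV does not carry the canonical feature columns."""


@dataclass
class RawFeatureTable:
    """One parsed CSV segment: the full 49-column per-frame feature table."""

    frame_index: np.ndarray  # (T,) int
    timestamp: np.ndarray    # (T,) float seconds
    values: np.ndarray       # (T, 49) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.timestamp = np.asarray(self.timestamp, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(schema.ALL_FEATURES):
            raise SchemaError(
                f"expected {len(schema.ALL_FEATURES)} feature columns, "
                f"got shape {self.values.shape}"
            )
        if len(self.frame_index) != len(self.values):
            raise SchemaError("frame_index length does not match values")
        if len(self.frame_index) > 1 and not np.all(np.diff(self.frame_index) > 0):
            raise SchemaError("frame_index must be strictly increasing within a file")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def columns(self) -> list[str]:
        return list(schema.ALL_FEATURES)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, schema.ALL_FEATURES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=schema.ALL_FEATURES)
        df.insert(0, schema.TIMESTAMP_COLUMN, self.timestamp)
        df.insert(0, schema.FRAME_COLUMN, self.frame_index)
        return df


@dataclass
class FeatureSeries:
    """One participant's (T x 40) selected-feature matrix."""

    values: np.ndarray                        # (T, 40) float
    participant_id: str = ""
    original_length: int = -1                 # frames before padding
    group_slices: dict[str, slice] = field(
        default_factory=lambda: dict(schema.GROUP_SLICES)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_sel = len(schema.SELECTED_FEATURES)
        if self.values.ndim != 2 or self.values.shape[1] != n_sel:
            raise SchemaError(
                f"expected {n_sel} selected columns, got shape {self.values.shape}"
            )
        if self.original_length < 0:
            self.original_length = self.values.shape[0]

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return list(schema.SELECTED_FEATURES)

    def group(self, name: str) -> np.ndarray:
        return self.values[:, self.group_slices[name]]


def read_openface_csv(path: str | os.PathLike) -> RawFeatureTable:
    """Parse an OpenFace-dialect CSV into a :class:`RawFeatureTable`.

    Recognized feature columns are mapped to canonical names; extra columns
    (confidence, landmarks, ...) are dropped with a logged notice.  A missing
    canonical column raises :class:`SchemaError` naming the absent columns.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    rename, extras = {}, []
    for col in df.columns:
        canon = schema.canonical_name(str(col))
        if canon is None:
            extras.append(str(col))
        else:
            rename[col] = canon
    df = df.rename(columns=rename)
    if extras:
        logger.info("%s: dropping %d unrecognized columns: %s",
                    path, len(extras), ", ".join(extras))
    missing = [c for c in schema.ALL_FEATURES if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing canonical columns: {', '.join(missing)}"
        )
    n = len(df)
    if schema.FRAME_COLUMN in df.columns:
        frame_index = df[schema.FRAME_COLUMN].to_numpy(dtype=int)
        # OpenFace numbers frames from 1; renumber from 0
        frame_index = frame_index - frame_index[0] if n else frame_index
    else:
        frame_index = np.arange(n)
    if schema.TIMESTAMP_COLUMN in df.columns:
        timestamp = df[schema.TIMESTAMP_COLUMN].to_numpy(dtype=float)
    else:
        timestamp = frame_index / 30.0
    return RawFeatureTable(
        frame_index=frame_index,
        timestamp=timestamp,
        values=df[schema.ALL_FEATURES].to_numpy(dtype=float),
    )


def join_participant_segments(tables: list[RawFeatureTable]) -> RawFeatureTable:
    """Concatenate per-question segments row-wise, renumbering frames 0..T-1."""
    if not tables:
        raise ValueError("cannot join an empty list of segments")
    values = np.concatenate([t.values for t in tables], axis=0)
    timestamp = np.concatenate([t.timestamp for t in tables], axis=0)
    return RawFeatureTable(
        frame_index=np.arange(values.shape[0]),
        timestamp=timestamp,
        values=values,
    )


def select_features(
    table: RawFeatureTable | FeatureSeries, participant_id: str = ""
) -> FeatureSeries:
    """Project the 49-column table onto the 40 retained feature columns.

    Drops the 3 head-pose location and 6 gaze-vector columns; output column
    order is Pose(3) + Gaze(2) + AU_r(17) + AU_c(18).  Applying the selection
    to an already-selected :class:`FeatureSeries` is a no-op.
    """
    if isinstance(table, FeatureSeries):
        return table
    idx = [schema.ALL_FEATURES.index(c) for c in schema.SELECTED_FEATURES]
    return FeatureSeries(
        values=table.values[:, idx],
        participant_id=participant_id,
    )


def pad_to_horizon(
    series: FeatureSeries, horizon: int = DEFAULT_HORIZON
) -> FeatureSeries:
    """Append all-zero rows so the series has exactly ``horizon`` frames."""
    t = len(series)
    if t > horizon:
        raise ValueError(
            f"series of length {t} exceeds the padding horizon {horizon}"
        )
    if t == horizon:
        return series
    pad = np.zeros((horizon - t, series.values.shape[1]))
    return replace(
        series,
        values=np.concatenate([series.values, pad], axis=0),
        original_length=series.original_length,
    )


class FeatureScaler:
    """Per-feature z-scaling fitted on training-split statistics.

    Fitting and transforming both ignore padded rows, so zero padding stays
    exactly zero after scaling.  Constant features get unit scale.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, series_list: list[FeatureSeries]) -> "FeatureScaler":
        rows = np.concatenate(
            [s.values[: s.original_length] for s in series_list], axis=0
        )
        self.mean_ = rows.mean(axis=0)
        scale = rows.std(axis=0)
        scale[scale == 0.0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, series: FeatureSeries) -> FeatureSeries:
        if self.mean_ is None:
            raise RuntimeError("FeatureScaler.transform called before fit")
        values = series.values.copy()
        n = series.original_length
        values[:n] = (values[:n] - self.mean_) / self.scale_
        return replace(series, values=values)

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {"mean": self.mean_, "scale": self.scale_}

    @classmethod
    def from_arrays(cls, mean: np.ndarray, scale: np.ndarray) -> "FeatureScaler":
        out = cls()
        out.mean_ = np.asarray(mean, dtype=float)
        out.scale_ = np.asarray(scale, dtype=float)
        return out


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a participant manifest CSV (participant_id, file_path, severity)."""
    df = pd.read_csv(path)
    required = {"participant_id", "file_path", "severity"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_participant(paths: list[str | os.PathLike],
                     participant_id: str = "") -> FeatureSeries:
    """Read, join and select all segments of one participant.

    Segments are joined in the given order; callers sort paths
    lexicographically when the manifest carries no explicit order.
    """
    tables = [read_openface_csv(p) for p in paths]
    return select_features(join_participant_segments(tables), participant_id)


def save_cohort(path: str | os.PathLike,
                series_list: list[FeatureSeries],
                severities: list[str],
                scaler: FeatureScaler | None = None) -> None:
    """Pack padded per-participant matrices into one ``.npz`` archive."""
    arrays: dict[str, np.ndarray] = {
        "participant_ids": np.array([s.participant_id for s in series_list]),
        "severities": np.array(list(severities)),
        "original_lengths": np.array([s.original_length for s in series_list]),
        "values": np.stack([s.values for s in series_list]),
    }
    if scaler is not None and scaler.mean_ is not None:
        arrays["scaler_mean"] = scaler.mean_
        arrays["scaler_scale"] = scaler.scale_
    np.savez_compressed(path, **arrays)


def load_cohort(path: str | os.PathLike):
    """Inverse of :func:`save_cohort`.

    Returns ``(series_list, severities, scaler_or_None)``.
    """
    with np.load(path, allow_pickle=False) as npz:
        values = npz["values"]
        ids = [str(x) for x in npz["participant_ids"]]
        severities = [str(x) for x in npz["severities"]]
        lengths = npz["original_lengths"]
        scaler = None
        if "scaler_mean" in npz:
            scaler = FeatureScaler.from_arrays(npz["scaler_mean"],
                                               npz["scaler_scale"])
    series_list = [
        FeatureSeries(values=values[i], participant_id=ids[i],
                      original_length=int(lengths[i]))
        for i in range(values.shape[0])
    ]
    return series_list, severities, scaler
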