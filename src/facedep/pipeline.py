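"""End-to-end glue: manifest -> loaded samples -> prepared splits.

Order of operations: join segments, select 40 features, split by severity
stratum, fit the feature scaler on the training split, z-scale, then pad —
so padded rows stay exactly zero and no test statistics leak into training.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

from facedep import openface_io
from facedep.cohort import (
    CohortSample,
    SplitManifest,
    balance_by_duplication,
    smooth_labels,
    stratified_split,
)
from facedep.openface_io import FeatureScaler, pad_to_horizon


def load_cohort_samples(manifest_path: str | os.PathLike) -> list[CohortSample]:
    """Read a participant manifest and load every participant's series.

    Multiple files per participant are joined in the manifest's row order
    after a lexicographic sort by file name.
    """
    manifest_path = Path(manifest_path)
    df = openface_io.read_manifest(manifest_path)
    samples = []
    for pid, rows in df.groupby("participant_id", sort=True):
        rows = rows.sort_values("file_path", kind="stable")
        severities = set(rows["severity"])
        if len(severities) != 1:
            raise ValueError(
                f"participant {pid!r} has conflicting severities: {severities}")
        paths = [manifest_path.parent / p for p in rows["file_path"]]
        series = openface_io.load_participant(paths, participant_id=str(pid))
        samples.append(CohortSample.from_severity(str(pid), rows["severity"].iloc[0],
                                                  series))
    return samples


@dataclass
class PreparedSplits:
    train: list[CohortSample]      # balanced, scaled, padded, smoothed
    validation: list[CohortSample]
    test: list[CohortSample]
    manifest: SplitManifest
    scaler: FeatureScaler
    horizon: int


def _auto_horizon(samples: list[CohortSample], window_len: int = 30) -> int:
    longest = max(len(s.series) for s in samples)
    return ((longest + window_len - 1) // window_len) * window_len


def prepare_splits(
    samples: list[CohortSample],
    seed: int = 42,
    horizon: int | None = None,
    alpha: float = 0.0,
    balance: bool = True,
) -> PreparedSplits:
    """Split, balance, scale, pad and smooth a loaded cohort.

    ``horizon=None`` pads to the longest series rounded up to a whole number
    of 30-frame windows; pass ``openface_io.DEFAULT_HORIZON`` for the full
    11-minute horizon.
    """
    manifest = stratified_split(samples, seed=seed)
    by_split = {
        name: [s for s in samples if manifest.assignment[s.participant_id] == name]
        for name in ("train", "validation", "test")
    }
    horizon = horizon or _auto_horizon(samples)
    scaler = FeatureScaler().fit([s.series for s in by_split["train"]])

    def transform(split):
        out = []
        for s in split:
            series = pad_to_horizon(scaler.transform(s.series), horizon)
            out.append(CohortSample(s.participant_id, s.severity, s.target, series))
        return out

    train = transform(by_split["train"])
    if balance:
        train = balance_by_duplication(train)
    if alpha:
        targets = smooth_labels([s.target for s in train], alpha)
        train = [
            CohortSample(s.participant_id, s.severity, t, s.series)
            for s, t in zip(train, targets)
        ]
    return PreparedSplits(
        train=train,
        validation=transform(by_split["validation"]),
        test=transform(by_split["test"]),
        manifest=manifest,
        scaler=scaler,
        horizon=horizon,
    )
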