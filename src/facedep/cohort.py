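"""Cohort construction: severity labels, binary targets, splits, balancing.

Severity has four clinician-rated levels.  The classification task is binary:
normal and mild count as non-depressed (0), moderate and severe as depressed
(1).  The cohort is split 80:10:10 per severity stratum; the depressed half
of the training split is duplicated once to balance classes; hard targets
may be softened with label smoothing ``y * (1 - alpha) + alpha / K``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from facedep.openface_io import FeatureSeries

N_CLASSES = 2
DEFAULT_RATIOS = (0.8, 0.1, 0.1)
SPLIT_NAMES = ("train", "validation", "test")

#: label-smoothing sweep grid: alpha = 0.0 .. 0.9 step 0.1 gives soft-label
#: pairs (0, 1), (0.05, 0.95), ... (0.45, 0.55)
DEFAULT_ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(10))


class Severity(str, enum.Enum):
    NORMAL = "normal"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    @classmethod
    def coerce(cls, value: "Severity | str") -> "Severity":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown severity level {value!r}; expected one of "
                f"{[s.value for s in cls]}"
            ) from None


#: severity level -> binary target (1 = depressed)
SEVERITY_TO_BINARY = {
    Severity.NORMAL: 0,
    Severity.MILD: 0,
    Severity.MODERATE: 1,
    Severity.SEVERE: 1,
}


@dataclass(frozen=True)
class BinaryTarget:
    """Hard binary label plus its (possibly smoothed) soft value."""

    y: int                  # hard label, 1 = depressed
    y_smooth: float         # smoothed target in [0, 1]
    alpha: float = 0.0      # smoothing coefficient used
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.y not in (0, 1):
            raise ValueError(f"hard label must be 0 or 1, got {self.y}")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")


def binarize(level: Severity | str) -> BinaryTarget:
    """Map a severity level to its hard binary target (no smoothing)."""
    y = SEVERITY_TO_BINARY[Severity.coerce(level)]
    return BinaryTarget(y=y, y_smooth=float(y), alpha=0.0)


def smooth_value(y: int, alpha: float, n_classes: int = N_CLASSES) -> float:
    """Label smoothing: ``y * (1 - alpha) + alpha / K``."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    return y * (1.0 - alpha) + alpha / n_classes


def smooth_labels(targets: list[BinaryTarget], alpha: float) -> list[BinaryTarget]:
    """Return targets with soft values ``y(1-alpha) + alpha/K`` (K = 2)."""
    return [
        BinaryTarget(y=t.y, y_smooth=smooth_value(t.y, alpha), alpha=alpha)
        for t in targets
    ]


@dataclass
class CohortSample:
    """One participant: feature series (optional until loaded) + labels."""

    participant_id: str
    severity: Severity
    target: BinaryTarget
    series: FeatureSeries | None = None

    @classmethod
    def from_severity(cls, participant_id: str, severity: Severity | str,
                      series: FeatureSeries | None = None) -> "CohortSample":
        sev = Severity.coerce(severity)
        return cls(participant_id=participant_id, severity=sev,
                   target=binarize(sev), series=series)


@dataclass
class SplitManifest:
    """Participant-to-split assignment plus per-stratum bookkeeping."""

    assignment: dict[str, str]                       # participant_id -> split
    counts: dict[str, dict[str, int]]                # split -> severity -> n
    seed: int
    ratios: tuple[float, float, float] = DEFAULT_RATIOS
    duplication: dict[str, int] = field(default_factory=dict)  # severity -> x

    def members(self, split: str) -> list[str]:
        return [pid for pid, s in self.assignment.items() if s == split]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": pid,
                "split": split,
                "duplicate_count": self.duplication.get(split, 1)
                if split == "train" else 1,
            }
            for pid, split in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)


def _largest_remainder(stratum_counts: dict[str, int], n_take: int) -> dict[str, int]:
    """Allocate ``n_take`` slots across strata proportionally.

    Floor of each proportional quota, then hand remaining slots to the
    largest fractional parts (ties broken by stratum size, then name).
    """
    total = sum(stratum_counts.values())
    if total == 0 or n_take <= 0:
        return {k: 0 for k in stratum_counts}
    quotas = {k: n * n_take / total for k, n in stratum_counts.items()}
    alloc = {k: math.floor(q) for k, q in quotas.items()}
    leftovers = n_take - sum(alloc.values())
    order = sorted(
        stratum_counts,
        key=lambda k: (-(quotas[k] - alloc[k]), -stratum_counts[k], k),
    )
    for k in order[:leftovers]:
        alloc[k] += 1
    # never allocate more than the stratum holds
    for k in alloc:
        alloc[k] = min(alloc[k], stratum_counts[k])
    return alloc


def stratified_split(
    samples: list[CohortSample],
    ratios: tuple[float, float, float] = DEFAULT_RATIOS,
    seed: int = 42,
) -> SplitManifest:
    """Split the cohort train/validation/test independently per severity.

    Test then validation receive ``ceil(ratio * N)`` participants each,
    spread across strata by largest-remainder proportional allocation;
    training keeps the rest.  The procedure sorts by participant id before
    shuffling, so the result depends only on the id set and the seed.
    Strata with fewer than 3 members go entirely to train with a warning.
    """
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    if len({s.participant_id for s in samples}) != len(samples):
        raise ValueError("duplicate participant_id in cohort")

    rng = np.random.default_rng(seed)
    by_level: dict[str, list[CohortSample]] = {}
    for s in sorted(samples, key=lambda s: s.participant_id):
        by_level.setdefault(s.severity.value, []).append(s)

    assignment: dict[str, str] = {}
    splittable: dict[str, list[CohortSample]] = {}
    for level in sorted(by_level):
        members = by_level[level]
        if len(members) < 3:
            warnings.warn(
                f"severity stratum {level!r} has only {len(members)} member(s); "
                "assigning all to train",
                stacklevel=2,
            )
            for s in members:
                assignment[s.participant_id] = "train"
        else:
            order = rng.permutation(len(members))
            splittable[level] = [members[i] for i in order]

    n_total = sum(len(v) for v in splittable.values())
    counts_now = {k: len(v) for k, v in splittable.items()}
    n_test = math.ceil(ratios[2] * n_total)
    test_alloc = _largest_remainder(counts_now, n_test)
    remaining = {k: counts_now[k] - test_alloc[k] for k in counts_now}
    n_val = math.ceil(ratios[1] * n_total)
    val_alloc = _largest_remainder(remaining, n_val)

    for level, members in splittable.items():
        nt, nv = test_alloc[level], val_alloc[level]
        for s in members[:nt]:
            assignment[s.participant_id] = "test"
        for s in members[nt:nt + nv]:
            assignment[s.participant_id] = "validation"
        for s in members[nt + nv:]:
            assignment[s.participant_id] = "train"

    by_id = {s.participant_id: s for s in samples}
    counts = {name: {} for name in SPLIT_NAMES}
    for pid, split in assignment.items():
        level = by_id[pid].severity.value
        counts[split][level] = counts[split].get(level, 0) + 1
    return SplitManifest(assignment=assignment, counts=counts,
                         seed=seed, ratios=ratios)


def balance_by_duplication(
    samples: list[CohortSample],
    split: str = "train",
    factor: int = 2,
) -> list[CohortSample]:
    """Duplicate every depressed training sample so it appears ``factor`` times.

    Only the training split may be balanced; validation and test keep their
    natural class ratio.  With no depressed samples the input is returned
    unchanged with a warning.
    """
    if split != "train":
        raise ValueError(
            f"duplication balancing applies to the train split only, got {split!r}"
        )
    if factor < 1:
        raise ValueError(f"duplication factor must be >= 1, got {factor}")
    minority = [s for s in samples if s.target.y == 1]
    if not minority:
        warnings.warn("no depressed samples in train split; nothing to balance",
                      stacklevel=2)
        return list(samples)
    out = list(samples)
    for _ in range(factor - 1):
        out.extend(replace(s) for s in minority)
    return out
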