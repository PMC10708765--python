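"""Synthetic OpenFace-like cohorts with planted, tunable depression signatures.

Real interview recordings are private, so every downstream stage is exercised
on generated 49-column per-frame tables.  The planted signatures follow the
qualitative picture the classifier is meant to recover:

* depressed participants turn their head (yaw excursion events) more often,
* their gaze wanders more widely but moves more slowly,
* "negative" action units (AU07 lid tightener, AU20 lip stretcher,
  AU26 jaw drop) are elevated,
* "social" action units (AU06 cheek raiser, AU12 lip corner puller,
  AU25 lips part) are suppressed.

Each signature is one tunable effect-size parameter; severity scales the
effect (normal < mild << moderate < severe), so the binary classes separate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from facedep import schema
from facedep.cohort import Severity
from facedep.openface_io import RawFeatureTable

#: how strongly each severity level expresses the depression signature
SEVERITY_FACTOR = {
    Severity.NORMAL: 0.0,
    Severity.MILD: 0.15,
    Severity.MODERATE: 0.85,
    Severity.SEVERE: 1.0,
}

AU_UP = ("AU07", "AU20", "AU26")     # elevated when depressed
AU_DOWN = ("AU06", "AU12", "AU25")   # suppressed when depressed

#: relative strength of the shift within each planted AU set (jaw drop is
#: the most prominent depressed signature; lip-corner pull the most social)
_AU_UP_WEIGHT = {"AU26": 1.0, "AU07": 0.7, "AU20": 0.6}
_AU_DOWN_WEIGHT = {"AU12": 1.0, "AU06": 0.8, "AU25": 0.6}

#: resting intensity (0-5 scale) per action unit; AU_DOWN members sit higher
#: so suppression does not clip at zero
_AU_BASELINE = {
    "AU01": 0.8, "AU02": 0.7, "AU04": 0.9, "AU05": 0.6, "AU06": 1.6,
    "AU07": 1.0, "AU09": 0.5, "AU10": 0.9, "AU12": 1.7, "AU14": 1.2,
    "AU15": 0.7, "AU17": 0.8, "AU20": 0.9, "AU23": 0.6, "AU25": 1.8,
    "AU26": 1.0, "AU28": 0.9, "AU45": 1.1,
}


@dataclass
class SignatureSpec:
    """Effect-size descriptors for the planted depression signatures."""

    fps: int = 30
    duration_s: float = 60.0
    # head pose: extra yaw-turn events per minute for a fully depressed profile
    yaw_turn_rate: float = 6.0
    base_turn_rate: float = 0.5
    yaw_turn_amplitude: float = 0.6          # radians at event peak
    # gaze: wander spread (stationary sd, radians) and movement slowness
    gaze_wander_sd: float = 0.20
    base_gaze_sd: float = 0.06
    eye_movement_speed_scale: float = 0.35   # < 1 slows depressed gaze
    # action units: intensity shifts (0-5 scale)
    au_up: float = 2.0
    au_down: float = 1.0
    # observation noise
    noise_sd: dict = field(default_factory=lambda: {
        "Pose": 0.03, "Gaze": 0.0, "AU_r": 0.30,
    })
    # between-participant variability (0 = every subject at the class mean)
    au_subject_sd: float = 0.0        # additive, per AU, intensity scale
    au_factor_sd: float = 0.0         # common-mode noise on the AU severity
                                      # factor (facial expressiveness varies)
    rate_subject_sd: float = 0.0      # log-normal sigma on yaw-event rate
    gaze_subject_sd: float = 0.0      # log-normal sigma on gaze wander sd

    def __post_init__(self) -> None:
        for name in ("yaw_turn_rate", "base_turn_rate", "yaw_turn_amplitude",
                     "gaze_wander_sd", "base_gaze_sd", "au_up", "au_down"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0 < self.eye_movement_speed_scale <= 1:
            raise ValueError("eye_movement_speed_scale must lie in (0, 1]")

    def scaled(self, effect_scale: float) -> "SignatureSpec":
        """Spec with all between-class effect sizes multiplied by a factor."""
        return replace(
            self,
            yaw_turn_rate=self.yaw_turn_rate * effect_scale,
            gaze_wander_sd=self.gaze_wander_sd * effect_scale,
            eye_movement_speed_scale=min(
                1.0, 1.0 - (1.0 - self.eye_movement_speed_scale) * effect_scale
            ) if effect_scale <= 1 else self.eye_movement_speed_scale,
            au_up=self.au_up * effect_scale,
            au_down=self.au_down * effect_scale,
        )

    def au_intensity_mean(self, au: str, level: Severity | str) -> float:
        """Closed-form expected intensity of one AU at one severity level
        (before between-participant jitter, which is zero-mean)."""
        f = SEVERITY_FACTOR[Severity.coerce(level)]
        mu = _AU_BASELINE[au]
        if au in AU_UP:
            mu += self.au_up * _AU_UP_WEIGHT[au] * f
        elif au in AU_DOWN:
            mu -= self.au_down * _AU_DOWN_WEIGHT[au] * f
        return float(np.clip(mu, 0.0, 5.0))


@dataclass
class SyntheticCohort:
    samples: list  # list[(RawFeatureTable, Severity)]
    participant_ids: list
    seed: int
    spec: SignatureSpec

    def __len__(self) -> int:
        return len(self.samples)


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average along axis 0 (edge-padded)."""
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, [(pad, w - 1 - pad)] + [(0, 0)] * (x.ndim - 1), mode="edge")
    out = np.empty_like(x)
    if x.ndim == 1:
        return np.convolve(xp, kernel, mode="valid")
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(xp[:, j], kernel, mode="valid")
    return out


def _ou_walk(rng: np.random.Generator, n: int, sd: float, theta: float,
             dt: float) -> np.ndarray:
    """Mean-reverting walk with stationary sd ``sd`` and reversion ``theta``."""
    a = np.exp(-theta * dt)
    innov_sd = sd * np.sqrt(max(1.0 - a * a, 1e-12))
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    for t in range(1, n):
        x[t] = a * x[t - 1] + innov_sd * eps[t]
    return x


def _yaw_events(rng: np.random.Generator, n: int, fps: int, rate_per_min: float,
                amplitude: float) -> np.ndarray:
    """Sum of raised-cosine head-turn excursions at Poisson times."""
    yaw = np.zeros(n)
    minutes = n / fps / 60.0
    n_events = rng.poisson(rate_per_min * minutes)
    for _ in range(n_events):
        center = rng.uniform(0, n)
        half = rng.uniform(0.4, 0.9) * fps          # 0.4-0.9 s half-width
        amp = amplitude * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
        lo = max(int(center - half), 0)
        hi = min(int(center + half), n)
        if hi <= lo:
            continue
        phase = (np.arange(lo, hi) - center) / half  # in (-1, 1)
        yaw[lo:hi] += amp * 0.5 * (1 + np.cos(np.pi * phase))
    return yaw


def _centered_gamma(rng: np.random.Generator, size, sd: float) -> np.ndarray:
    """Zero-mean, right-skewed noise with standard deviation ``sd``."""
    shape = 4.0
    scale = sd / np.sqrt(shape)
    return rng.gamma(shape, scale, size=size) - shape * scale


def generate_participant(
    level: Severity | str,
    spec: SignatureSpec | None = None,
    seed: int = 0,
) -> RawFeatureTable:
    """Generate one participant's 49-column per-frame table.

    ``T = fps * duration_s`` frames; the severity level scales every planted
    effect via :data:`SEVERITY_FACTOR`.  Identical (level, spec, seed) inputs
    regenerate identical tables.
    """
    spec = spec or SignatureSpec()
    level = Severity.coerce(level)
    if spec.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    f = SEVERITY_FACTOR[level]
    n = int(round(spec.fps * spec.duration_s))
    dt = 1.0 / spec.fps

    cols: dict[str, np.ndarray] = {}
    pose_sd = spec.noise_sd.get("Pose", 0.03)

    # subject-level idiosyncrasies, fixed within a recording
    rate_mult = float(np.exp(rng.normal(0.0, spec.rate_subject_sd))) \
        if spec.rate_subject_sd else 1.0
    gaze_mult = float(np.exp(rng.normal(0.0, spec.gaze_subject_sd))) \
        if spec.gaze_subject_sd else 1.0

    # head pose rotation: smoothed jitter; yaw carries turn events
    cols["pose_Rx"] = _smooth(rng.normal(0.05, pose_sd, n), 5)
    cols["pose_Rz"] = _smooth(rng.normal(0.0, pose_sd, n), 5)
    rate = (spec.base_turn_rate + spec.yaw_turn_rate * f) * rate_mult
    cols["pose_Ry"] = (
        _smooth(rng.normal(0.0, pose_sd, n), 5)
        + _yaw_events(rng, n, spec.fps, rate, spec.yaw_turn_amplitude)
    )

    # head pose location (mm): slow drift around a sitting position
    cols["pose_Tx"] = _smooth(rng.normal(0.0, 8.0, n), 15)
    cols["pose_Ty"] = _smooth(rng.normal(0.0, 8.0, n), 15)
    cols["pose_Tz"] = 600.0 + _smooth(rng.normal(0.0, 15.0, n), 15)

    # gaze angles: mean-reverting wander; depressed = wider and slower
    gaze_sd = (spec.base_gaze_sd + spec.gaze_wander_sd * f) * gaze_mult
    theta = 4.0 * (1.0 - f * (1.0 - spec.eye_movement_speed_scale))
    ax = np.clip(_ou_walk(rng, n, gaze_sd, theta, dt), -np.pi / 2, np.pi / 2)
    ay = np.clip(_ou_walk(rng, n, gaze_sd, theta, dt), -np.pi / 2, np.pi / 2)
    cols["gaze_angle_x"] = ax
    cols["gaze_angle_y"] = ay

    # per-eye gaze unit vectors derived from the shared angles + small jitter
    for eye in (0, 1):
        vx = np.sin(ax) + rng.normal(0.0, 0.01, n)
        vy = np.sin(ay) + rng.normal(0.0, 0.01, n)
        vz = -np.sqrt(np.clip(1.0 - vx**2 - vy**2, 1e-6, None))
        norm = np.sqrt(vx**2 + vy**2 + vz**2)
        cols[f"gaze_{eye}_x"] = vx / norm
        cols[f"gaze_{eye}_y"] = vy / norm
        cols[f"gaze_{eye}_z"] = vz / norm

    # action units: smoothed skew noise around the severity-shifted mean
    au_sd = spec.noise_sd.get("AU_r", 0.30)
    # one noisy expressiveness factor shared by every AU shift: it cannot be
    # averaged away across AUs, so AU evidence alone stays imperfect
    au_factor = f
    if spec.au_factor_sd:
        au_factor = float(np.clip(f + rng.normal(0.0, spec.au_factor_sd),
                                  0.0, 1.2))
    for au_id in schema.AU_PRESENCE_IDS:
        au = f"AU{au_id}"
        mu = _AU_BASELINE[au]
        if au in AU_UP:
            mu += spec.au_up * _AU_UP_WEIGHT[au] * au_factor
        elif au in AU_DOWN:
            mu -= spec.au_down * _AU_DOWN_WEIGHT[au] * au_factor
        mu = float(np.clip(mu, 0.0, 5.0))
        if spec.au_subject_sd:
            mu = float(np.clip(mu + rng.normal(0.0, spec.au_subject_sd),
                               0.0, 5.0))
        intensity = np.clip(
            mu + _smooth(_centered_gamma(rng, n, au_sd), 5), 0.0, 5.0
        )
        if au_id in schema.AU_INTENSITY_IDS:
            cols[f"{au}_r"] = intensity
        # presence: Bernoulli with rate increasing in the shifted intensity
        p = np.clip(intensity / 4.0, 0.02, 0.98)
        cols[f"{au}_c"] = (rng.random(n) < p).astype(float)

    values = np.column_stack([cols[c] for c in schema.ALL_FEATURES])
    return RawFeatureTable(
        frame_index=np.arange(n),
        timestamp=np.arange(n) * dt,
        values=values,
    )


def generate_cohort(
    n_per_level: dict[Severity | str, int] | tuple[int, int, int, int],
    spec: SignatureSpec | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a cohort with the requested per-severity composition.

    ``n_per_level`` is either a mapping level -> count or a 4-tuple in the
    order (normal, mild, moderate, severe).  Per-participant seeds derive
    deterministically from the master seed.
    """
    spec = spec or SignatureSpec()
    if not isinstance(n_per_level, dict):
        n_per_level = dict(zip(list(Severity), n_per_level))
    counts = {Severity.coerce(k): int(v) for k, v in n_per_level.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("per-level counts must be >= 0")

    levels: list[Severity] = []
    for level in Severity:  # fixed level order keeps ids stable
        levels.extend([level] * counts.get(level, 0))

    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(levels), 1))
    samples, ids = [], []
    for i, level in enumerate(levels):
        table = generate_participant(level, spec, seed=int(child_seeds[i]))
        samples.append((table, level))
        ids.append(f"P{i:04d}")
    return SyntheticCohort(samples=samples, participant_ids=ids,
                           seed=seed, spec=spec)


def write_cohort(cohort: SyntheticCohort, out_dir: str | os.PathLike,
                 segments: int = 1) -> Path:
    """Write OpenFace-dialect CSVs plus a participant manifest.

    Optionally splits each participant into ``segments`` consecutive files to
    exercise segment joining.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, (table, level) in zip(cohort.participant_ids, cohort.samples):
        df = table.to_frame()
        bounds = np.linspace(0, len(df), segments + 1, dtype=int)
        for k in range(segments):
            part = df.iloc[bounds[k]:bounds[k + 1]]
            if part.empty and segments > 1:
                continue
            fname = f"{pid}_q{k:02d}.csv"
            part.to_csv(out / fname, index=False)
            rows.append({
                "participant_id": pid,
                "file_path": fname,
                "severity": level.value,
            })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
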