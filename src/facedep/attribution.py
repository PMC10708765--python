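"""Integrated-gradient attribution for time-series inputs.

Attributions are taken on the depressed probability with respect to every
frame x feature cell, against an all-zero baseline, using a midpoint Riemann
approximation of the path integral.  Per-feature summaries aggregate over
time and samples: the signed mean gives direction (positive pushes toward
"depressed"), the absolute mean gives importance, and features are ranked
by descending absolute mean.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from facedep import schema
from facedep.nn import Tensor

#: bar colours: positive = toward depressed (blue), negative = away (red)
POSITIVE_COLOR = "#2b6cb0"
NEGATIVE_COLOR = "#c53030"


@dataclass
class AttributionMap:
    """Per-cell IG attributions for one sample (zero baseline)."""

    values: np.ndarray          # (T, F)
    n_steps: int
    prediction: float           # F(x), the attributed output
    baseline_output: float      # F(0)
    original_length: int = -1   # frames before padding

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.original_length < 0:
            self.original_length = self.values.shape[0]

    @property
    def completeness_error(self) -> float:
        """|sum(attributions) - (F(x) - F(baseline))|."""
        return abs(self.values.sum() - (self.prediction - self.baseline_output))


def integrated_gradients(model, x: np.ndarray, n_steps: int = 64,
                         original_length: int | None = None,
                         step_batch: int = 16) -> AttributionMap:
    """IG of the model's depressed probability w.r.t. a (T, F) input.

    ``IG_i = x_i * mean_k dF(a_k x)/dx_i`` with midpoints
    ``a_k = (k - 1/2)/n_steps`` — the straight path from the all-zero series.
    Path steps are evaluated ``step_batch`` at a time as one batch; each
    batch row's gradient flows only to its own scaled copy, so the chunking
    does not change the result.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a (T, F) input, got shape {x.shape}")
    alphas = (np.arange(1, n_steps + 1) - 0.5) / n_steps
    total = np.zeros_like(x)
    for lo in range(0, n_steps, step_batch):
        chunk = alphas[lo:lo + step_batch]
        xt = Tensor(chunk[:, None, None] * x[None], requires_grad=True)
        out = model.forward(xt)
        out.backward(np.ones(out.shape))
        if not np.all(np.isfinite(xt.grad)):
            raise FloatingPointError(
                f"non-finite gradient among path steps {lo + 1}..."
                f"{lo + len(chunk)} of {n_steps}"
            )
        total += xt.grad.sum(axis=0)
    attributions = x * total / n_steps
    pred = float(model.predict_proba(x[None])[0])
    base = float(model.predict_proba(np.zeros_like(x)[None])[0])
    return AttributionMap(values=attributions, n_steps=n_steps,
                          prediction=pred, baseline_output=base,
                          original_length=original_length
                          if original_length is not None else x.shape[0])


@dataclass
class AttributionSummary:
    """Per-feature signed/absolute mean attribution with importance ranking."""

    feature_names: list[str]
    signed_mean: np.ndarray     # (F,)
    abs_mean: np.ndarray        # (F,)
    group_slices: dict[str, slice] = field(
        default_factory=lambda: dict(schema.GROUP_SLICES))

    @property
    def ranking(self) -> np.ndarray:
        """Feature indices by descending absolute mean; ties by column order."""
        return np.lexsort((np.arange(len(self.abs_mean)), -self.abs_mean))

    def top_features(self, k: int) -> list[str]:
        return [self.feature_names[i] for i in self.ranking[:k]]

    def group_rollup(self) -> pd.DataFrame:
        rows = []
        for name, sl in self.group_slices.items():
            rows.append({
                "group": name,
                "signed_mean": float(self.signed_mean[sl].mean()),
                "abs_mean": float(self.abs_mean[sl].mean()),
            })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rank_of = np.empty(len(self.feature_names), dtype=int)
        rank_of[self.ranking] = np.arange(1, len(self.feature_names) + 1)
        return pd.DataFrame({
            "feature": self.feature_names,
            "group": [schema.group_of(f) for f in self.feature_names],
            "signed_mean": self.signed_mean,
            "abs_mean": self.abs_mean,
            "rank": rank_of,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AttributionSummary":
        return cls(
            feature_names=list(df["feature"]),
            signed_mean=df["signed_mean"].to_numpy(dtype=float),
            abs_mean=df["abs_mean"].to_numpy(dtype=float),
        )


def summarize(maps: list[AttributionMap],
              feature_names: list[str] | None = None) -> AttributionSummary:
    """Aggregate per-sample maps into the per-feature summary.

    The temporal mean divides by each sample's pre-padding length (padded
    rows attribute exactly zero, so longer padding must not dilute the
    importance of shorter recordings).
    """
    if not maps:
        raise ValueError("summarize() needs at least one attribution map")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise ValueError("attribution maps differ in shape")
    signed = np.mean(
        [m.values.sum(axis=0) / m.original_length for m in maps], axis=0)
    magnitude = np.mean(
        [np.abs(m.values).sum(axis=0) / m.original_length for m in maps], axis=0)
    names = feature_names or list(schema.SELECTED_FEATURES)
    if len(names) != shape[1]:
        raise ValueError("feature_names length does not match map width")
    return AttributionSummary(feature_names=names, signed_mean=signed,
                              abs_mean=magnitude)


def _bar_panel(ax, names, values, title, signed: bool) -> None:
    order = np.argsort(np.abs(values))[::-1]
    names = [names[i] for i in order]
    values = np.asarray(values)[order]
    colors = ([POSITIVE_COLOR if v >= 0 else NEGATIVE_COLOR for v in values]
              if signed else "#4a5568")
    ax.barh(range(len(values))[::-1], values, color=colors)
    ax.set_yticks(range(len(values))[::-1])
    ax.set_yticklabels(names, fontsize=7)
    ax.set_title(title, fontsize=9)
    ax.axvline(0.0, color="black", linewidth=0.5)


def render_impact_report(summary: AttributionSummary,
                         out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write per-group and overall impact figures plus the summary CSV.

    Produces 8 per-group panels (signed impact + magnitude for each of the
    four feature groups), a 2-panel all-features figure, and
    ``attribution_summary.csv``.  Returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fig, axes = plt.subplots(4, 2, figsize=(10, 16))
    for row, (group, sl) in enumerate(summary.group_slices.items()):
        names = summary.feature_names[sl]
        _bar_panel(axes[row][0], names, summary.signed_mean[sl],
                   f"{group}: impact on output", signed=True)
        _bar_panel(axes[row][1], names, summary.abs_mean[sl],
                   f"{group}: impact magnitude", signed=False)
    fig.tight_layout()
    paths["groups"] = out / "impact_by_group.png"
    fig.savefig(paths["groups"], dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(12, 10))
    _bar_panel(axes[0], summary.feature_names, summary.signed_mean,
               "All features: impact on output", signed=True)
    _bar_panel(axes[1], summary.feature_names, summary.abs_mean,
               "All features: impact magnitude", signed=False)
    fig.tight_layout()
    paths["overall"] = out / "impact_overall.png"
    fig.savefig(paths["overall"], dpi=120)
    plt.close(fig)

    paths["csv"] = out / "attribution_summary.csv"
    summary.to_frame().to_csv(paths["csv"], index=False)
    return paths
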