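"""Training loop and the metric table layout used throughout the reports.

Every evaluation row carries the confusion counts (positive class =
depressed) plus accuracy, macro-averaged and support-weighted
precision/recall/F1, all as percentages.  Note the support-weighted columns
are labelled "micro" in some published tables of this layout even though
they are weighted, not textbook-micro, averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from facedep.cohort import CohortSample, smooth_labels
from facedep.model_zoo import ModelConfig, Prediction, build_model
from facedep.nn import Adam, Tensor, no_grad

_EPS = 1e-12


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; the depressed class is positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def positive_support(self) -> int:
        return self.tp + self.fn

    @property
    def negative_support(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class EvalReport:
    """One metric row: counts + accuracy + macro and weighted P/R/F1 (%)."""

    counts: ConfusionCounts
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    _COLUMNS = ("TP", "FN", "TN", "FP", "Acc (%)",
                "Macro Precision (%)", "Macro Recall (%)", "Macro F1 (%)",
                "Weighted Precision (%)", "Weighted Recall (%)",
                "Weighted F1 (%)")

    def as_row(self) -> dict:
        c = self.counts
        vals = (c.tp, c.fn, c.tn, c.fp,
                round(self.accuracy, 2),
                round(self.macro_precision, 2), round(self.macro_recall, 2),
                round(self.macro_f1, 2),
                round(self.weighted_precision, 2),
                round(self.weighted_recall, 2), round(self.weighted_f1, 2))
        return dict(zip(self._COLUMNS, vals))


def _precision(hits: int, predicted: int, label: str) -> float:
    if predicted == 0:
        warnings.warn(
            f"no predicted members for the {label} class; precision set to 0",
            stacklevel=3,
        )
        return 0.0
    return hits / predicted


def report_from_counts(counts: ConfusionCounts) -> EvalReport:
    """Compute the full metric row from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot evaluate an empty confusion matrix")
    c = counts
    p_pos = _precision(c.tp, c.tp + c.fp, "depressed")
    p_neg = _precision(c.tn, c.tn + c.fn, "non-depressed")
    r_pos = c.tp / c.positive_support if c.positive_support else 0.0
    r_neg = c.tn / c.negative_support if c.negative_support else 0.0
    f_pos = 2 * p_pos * r_pos / (p_pos + r_pos + _EPS)
    f_neg = 2 * p_neg * r_neg / (p_neg + r_neg + _EPS)
    w_pos = c.positive_support / c.total
    w_neg = c.negative_support / c.total
    acc = (c.tp + c.tn) / c.total
    return EvalReport(
        counts=counts,
        accuracy=100.0 * acc,
        macro_precision=100.0 * (p_pos + p_neg) / 2,
        macro_recall=100.0 * (r_pos + r_neg) / 2,
        macro_f1=100.0 * (f_pos + f_neg) / 2,
        weighted_precision=100.0 * (w_pos * p_pos + w_neg * p_neg),
        weighted_recall=100.0 * (w_pos * r_pos + w_neg * r_neg),
        weighted_f1=100.0 * (w_pos * f_pos + w_neg * f_neg),
    )


def evaluate(predictions: list[Prediction], targets: list[int]) -> EvalReport:
    """Score thresholded predictions against hard labels."""
    if len(predictions) != len(targets):
        raise ValueError("predictions and targets differ in length")
    if not predictions:
        raise ValueError("cannot evaluate an empty prediction list")
    tp = fn = tn = fp = 0
    for pred, y in zip(predictions, targets):
        if y == 1:
            tp += pred.decision == 1
            fn += pred.decision == 0
        else:
            tn += pred.decision == 0
            fp += pred.decision == 1
    return report_from_counts(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))


def reports_to_frame(rows: dict[str, EvalReport]) -> pd.DataFrame:
    """Stack named metric rows into a table in the canonical column order."""
    return pd.DataFrame(
        [{"Model": name, **rep.as_row()} for name, rep in rows.items()]
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingRecipe:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    patience: int = 10           # early stopping on validation loss
    shuffle: bool = True
    threshold: float = 0.5


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_records(self) -> list[dict]:
        return [
            {"epoch": i, "train_loss": tl, "val_loss": vl, "val_accuracy": va}
            for i, (tl, vl, va) in enumerate(
                zip(self.train_loss, self.val_loss, self.val_accuracy))
        ]


def _stack(samples: list[CohortSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if any(s.series is None for s in samples):
        raise ValueError("all samples must carry a loaded feature series")
    x = np.stack([s.series.values for s in samples])
    y_soft = np.array([s.target.y_smooth for s in samples])
    y_hard = np.array([s.target.y for s in samples])
    return x, y_soft, y_hard


def _bce(p: Tensor, y: np.ndarray) -> Tensor:
    """Binary cross-entropy of probabilities against (soft) targets."""
    p = p * (1 - 2e-7) + 1e-7  # keep log() finite at saturated outputs
    yt = Tensor(y)
    loss = -(yt * p.log() + (1.0 - yt) * (1.0 - p).log())
    return loss.mean()


def predict(model, samples: list[CohortSample], batch_size: int = 8,
            threshold: float = 0.5) -> list[Prediction]:
    """Forward the model over samples (no gradients), thresholding at 0.5."""
    x, _, _ = _stack(samples)
    probs = []
    with no_grad():
        for lo in range(0, len(x), batch_size):
            probs.extend(model.forward(x[lo:lo + batch_size]).data)
    return [Prediction.from_prob(float(p), threshold) for p in probs]


def fit(model, train: list[CohortSample], val: list[CohortSample],
        recipe: TrainingRecipe | None = None, seed: int = 0):
    """Train with Adam on binary cross-entropy against the smoothed targets.

    Keeps the parameters from the best-validation-loss epoch; stops early
    when validation loss has not improved for ``recipe.patience`` epochs.
    Returns ``(model, history)``.
    """
    recipe = recipe or TrainingRecipe()
    rng = np.random.default_rng(seed)
    x_train, y_train, _ = _stack(train)
    x_val, y_val, y_val_hard = _stack(val)

    optimizer = Adam(model.parameters(), lr=recipe.learning_rate)
    history = TrainingHistory()
    best_state, best_loss, stale = None, np.inf, 0

    for epoch in range(recipe.epochs):
        order = (rng.permutation(len(x_train)) if recipe.shuffle
                 else np.arange(len(x_train)))
        losses = []
        for lo in range(0, len(order), recipe.batch_size):
            idx = order[lo:lo + recipe.batch_size]
            optimizer.zero_grad()
            p = model.forward(x_train[idx])
            loss = _bce(p, y_train[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting"
                )
            loss.backward()
            optimizer.step()
            losses.append(loss.item())

        with no_grad():
            val_probs = np.concatenate([
                model.forward(x_val[lo:lo + recipe.batch_size]).data
                for lo in range(0, len(x_val), recipe.batch_size)
            ])
        val_loss = float(np.mean(
            -(y_val * np.log(val_probs + 1e-7)
              + (1 - y_val) * np.log(1 - val_probs + 1e-7))
        ))
        val_acc = float(np.mean(
            (val_probs >= recipe.threshold).astype(int) == y_val_hard))
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)

        if val_loss < best_loss - 1e-9:
            best_loss, stale = val_loss, 0
            best_state = model.state_dict()
            history.best_epoch = epoch
        else:
            stale += 1
            if stale >= recipe.patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def sweep_label_smoothing(
    config: ModelConfig,
    train: list[CohortSample],
    val: list[CohortSample],
    test: list[CohortSample],
    alpha_grid: list[float],
    recipe: TrainingRecipe | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train one model per smoothing coefficient on identical splits.

    Every cell uses the same seed, splits and recipe; only the soft targets
    change.  Returns a table with one metric row per alpha, labelled by the
    soft-target pair ``(alpha/2, 1 - alpha/2)``.
    """
    rows = {}
    for alpha in alpha_grid:
        smoothed = [
            CohortSample(s.participant_id, s.severity, t, s.series)
            for s, t in zip(train, smooth_labels([s.target for s in train], alpha))
        ]
        model = build_model(config, seed=seed)
        model, _ = fit(model, smoothed, val, recipe, seed=seed)
        report = evaluate(predict(model, test), [s.target.y for s in test])
        pair = f"({round(alpha / 2, 3):g}, {round(1 - alpha / 2, 3):g})"
        rows[pair] = report
    table = reports_to_frame(rows).rename(columns={"Model": "Smoothing"})
    table.insert(0, "alpha", list(alpha_grid))
    return table


def select_best_row(table: pd.DataFrame) -> int:
    """Row index of the best model: max accuracy, macro F1 as tie-break."""
    order = table.sort_values(["Acc (%)", "Macro F1 (%)"],
                              ascending=False, kind="stable")
    return int(order.index[0])
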