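import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facedep import model_zoo, train_eval
from facedep.cohort import balance_by_duplication, smooth_labels, stratified_split
from facedep.model_zoo import Prediction, default_config
from facedep.nn import Parameter, Tensor
from facedep.openface_io import FeatureScaler
from facedep.train_eval import (
    ConfusionCounts,
    TrainingRecipe,
    evaluate,
    fit,
    predict,
    report_from_counts,
    reports_to_frame,
    select_best_row,
    sweep_label_smoothing,
)
from tests.conftest import make_samples


def sklearn_oracle(counts):
    """Independent metric computation via scikit-learn on expanded labels."""
    from sklearn.metrics import accuracy_score, precision_recall_fscore_support

    y_true = [1] * counts.tp + [1] * counts.fn + [0] * counts.tn + [0] * counts.fp
    y_pred = [1] * counts.tp + [0] * counts.fn + [0] * counts.tn + [1] * counts.fp
    out = {"accuracy": accuracy_score(y_true, y_pred)}
    for avg in ("macro", "weighted"):
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average=avg, zero_division=0)
        out[avg] = (p, r, f)
    return out


class TestMetrics:
    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(min_value=0, max_value=60)] * 4))
    def test_matches_sklearn_oracle(self, counts):
        tp, fn, tn, fp = counts
        if tp + fn == 0 or tn + fp == 0:
            return  # single-class targets: sklearn's support differs
        c = ConfusionCounts(tp, fn, tn, fp)
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = report_from_counts(c)
        oracle = sklearn_oracle(c)
        assert rep.accuracy / 100 == pytest.approx(oracle["accuracy"], abs=1e-9)
        for avg, (p, r, f) in (("macro", oracle["macro"]),
                               ("weighted", oracle["weighted"])):
            assert getattr(rep, f"{avg}_precision") / 100 == pytest.approx(p, abs=1e-6)
            assert getattr(rep, f"{avg}_recall") / 100 == pytest.approx(r, abs=1e-6)
            assert getattr(rep, f"{avg}_f1") / 100 == pytest.approx(f, abs=1e-6)
        # binary identity: support-weighted recall is accuracy
        assert rep.weighted_recall == pytest.approx(rep.accuracy, abs=1e-9)

    def test_all_correct_is_hundred(self):
        rep = report_from_counts(ConfusionCounts(5, 0, 7, 0))
        assert all(
            getattr(rep, k) == pytest.approx(100.0)
            for k in ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                      "weighted_precision", "weighted_recall", "weighted_f1")
        )

    def test_zero_predicted_positives_warns(self):
        with pytest.warns(UserWarning, match="precision set to 0"):
            rep = report_from_counts(ConfusionCounts(0, 5, 10, 0))
        assert rep.macro_precision == pytest.approx(100.0 * (0 + 10 / 15) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])
        with pytest.raises(ValueError):
            report_from_counts(ConfusionCounts(0, 0, 0, 0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([Prediction.from_prob(0.9)], [1, 0])

    def test_evaluate_counts_from_decisions(self):
        preds = [Prediction.from_prob(p) for p in (0.9, 0.2, 0.8, 0.1)]
        rep = evaluate(preds, [1, 1, 0, 0])
        assert (rep.counts.tp, rep.counts.fn, rep.counts.fp, rep.counts.tn) == \
            (1, 1, 1, 1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_rendered_table_round_trips(self):
        rep = report_from_counts(ConfusionCounts(10, 3, 34, 1))
        frame = reports_to_frame({"winner": rep})
        assert frame.loc[0, "Acc (%)"] == round(rep.accuracy, 2)
        assert frame.loc[0, "Macro F1 (%)"] == round(rep.macro_f1, 2)
        assert list(frame.columns[1:5]) == ["TP", "FN", "TN", "FP"]


def prepare(counts=(8, 8, 8, 8), duration_s=2.0, seed=0, spec=None, alpha=0.0):
    samples = make_samples(counts, duration_s=duration_s, seed=seed, spec=spec)
    manifest = stratified_split(samples, seed=seed)
    split = {
        name: [s for s in samples if manifest.assignment[s.participant_id] == name]
        for name in ("train", "validation", "test")
    }
    scaler = FeatureScaler().fit([s.series for s in split["train"]])
    for name in split:
        for s in split[name]:
            s.series = scaler.transform(s.series)
    split["train"] = balance_by_duplication(split["train"])
    if alpha:
        targets = smooth_labels([s.target for s in split["train"]], alpha)
        for s, t in zip(split["train"], targets):
            s.target = t
    return split


class TestFit:
    def test_separable_cohort_reaches_high_accuracy(self):
        split = prepare(seed=1)
        config = default_config("intermediate", "window_block_lstm", horizon=60)
        model = model_zoo.build_model(config, seed=1)
        model, history = fit(model, split["train"], split["validation"],
                             TrainingRecipe(epochs=30, batch_size=8, patience=8),
                             seed=1)
        assert max(history.val_accuracy) >= 0.9

        # independent oracle: per-feature means are linearly separable
        from sklearn.linear_model import LogisticRegression
        everything = split["train"] + split["validation"] + split["test"]
        X = np.stack([
            np.abs(s.series.values[:s.series.original_length]).mean(axis=0)
            for s in everything
        ])
        y = np.array([s.target.y for s in everything])
        assert LogisticRegression(max_iter=5000).fit(X, y).score(X, y) >= 0.95

    def test_zero_effect_cohort_learns_nothing(self):
        from facedep.synthetic import SignatureSpec
        from scipy.stats import binomtest
        split = prepare(seed=2, spec=SignatureSpec(duration_s=2.0).scaled(0.0))
        config = default_config("intermediate", "window_block_lstm", horizon=60)
        model = model_zoo.build_model(config, seed=2)
        model, history = fit(model, split["train"], split["validation"],
                             TrainingRecipe(epochs=5, batch_size=8), seed=2)
        preds = predict(model, split["test"])
        correct = sum(p.decision == s.target.y
                      for p, s in zip(preds, split["test"]))
        # indistinguishable from guessing the majority class
        majority = max(np.mean([s.target.y for s in split["test"]]), 0.5)
        assert binomtest(correct, len(preds), majority).pvalue > 0.01

    def test_fixed_seed_reproduces_history(self):
        split = prepare(seed=3)
        recipe = TrainingRecipe(epochs=2, batch_size=8)
        config = default_config("intermediate", "window_block_lstm", horizon=60)
        histories = []
        for _ in range(2):
            model = model_zoo.build_model(config, seed=3)
            _, history = fit(model, split["train"], split["validation"],
                             recipe, seed=3)
            histories.append(history)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].val_loss == histories[1].val_loss

    def test_nan_loss_aborts(self):
        from facedep.nn import Module

        class Diverges(Module):
            def __init__(self):
                self.w = Parameter(np.zeros(1))

            def forward(self, x):
                return Tensor(np.full(x.shape[0], np.nan)) + self.w[0]

        split = prepare(seed=4)
        with pytest.raises(RuntimeError, match="non-finite"):
            fit(Diverges(), split["train"], split["validation"],
                TrainingRecipe(epochs=1), seed=0)

    def test_missing_series_rejected(self):
        from tests.conftest import label_only_samples
        samples = label_only_samples((2, 2, 2, 2))
        with pytest.raises(ValueError, match="series"):
            fit(None, samples, samples, TrainingRecipe(epochs=1), seed=0)


class TestSweep:
    def test_grid_rows_and_alpha_zero_identity(self):
        split = prepare(seed=5)
        config = default_config("intermediate", "window_block_lstm", horizon=60)
        recipe = TrainingRecipe(epochs=2, batch_size=8)
        table = sweep_label_smoothing(
            config, split["train"], split["validation"], split["test"],
            alpha_grid=[0.0, 0.1, 0.3], recipe=recipe, seed=5)
        assert len(table) == 3
        # soft-target pairs are (alpha/2, 1 - alpha/2)
        assert list(table["Smoothing"]) == ["(0, 1)", "(0.05, 0.95)",
                                            "(0.15, 0.85)"]

        # the alpha = 0 row is bit-for-bit a no-smoothing run at the same seed
        model = model_zoo.build_model(config, seed=5)
        model, _ = fit(model, split["train"], split["validation"], recipe, seed=5)
        rep = evaluate(predict(model, split["test"]),
                       [s.target.y for s in split["test"]])
        row = table.iloc[0]
        assert (row["TP"], row["FN"], row["TN"], row["FP"]) == (
            rep.counts.tp, rep.counts.fn, rep.counts.tn, rep.counts.fp)
        assert row["Acc (%)"] == round(rep.accuracy, 2)

        best = select_best_row(table)
        # recompute the argmax independently of the selection rule's code path
        scores = list(zip(table["Acc (%)"], table["Macro F1 (%)"]))
        assert scores[best] == max(scores)
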