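# facedep

Explainable depression screening from facial-expression time series.

The package implements a complete pipeline over OpenFace-style per-frame
feature CSVs (head pose, gaze, facial action units):

1. **Ingestion** (`facedep.openface_io`) — parse OpenFace-dialect CSVs, join
   per-question segments per participant, select the 40 retained feature
   columns (3 pose rotation + 2 gaze angles + 17 AU intensities + 18 AU
   presences), z-scale with training-split statistics, and zero-pad to a
   fixed horizon (default 19,800 frames = 11 min at 30 fps).
2. **Cohort construction** (`facedep.cohort`) — 4-level severity labels
   (normal / mild / moderate / severe) mapped to a binary target (moderate
   and severe = depressed), stratified 80:10:10 splitting, duplication
   balancing of the depressed training class (×2), and label smoothing
   `y(1−α) + α/K`.
3. **Synthetic cohorts** (`facedep.synthetic`) — a generator of
   OpenFace-like 49-column tables with planted, effect-size-controlled
   depression signatures (yaw-turn events, wide-but-slow gaze wander,
   elevated AU07/AU20/AU26, suppressed AU06/AU12/AU25), so the whole
   pipeline is testable without clinical data.
4. **Model zoo** (`facedep.model_zoo`) — all nine fusion × backbone
   classifiers: {early, intermediate, late} × {Bi-LSTM, window-block LSTM,
   transformer}, including the (660, 30, 40) window reshape, additive
   attention pooling, and mean-pool-by-15 transformer branch. Models run on
   a small numpy reverse-mode autodiff engine (`facedep.nn`) — no deep
   learning framework required.
5. **Training & evaluation** (`facedep.train_eval`) — Adam + binary
   cross-entropy against smoothed targets with early stopping; metric rows
   with confusion counts, accuracy, macro and support-weighted
   precision/recall/F1; a label-smoothing sweep driver.
6. **Attribution** (`facedep.attribution`) — integrated gradients from an
   all-zero baseline (midpoint-rule path integral), per-feature signed-mean
   (direction) and absolute-mean (importance) summaries, ranked impact
   figures and CSVs.

## CLI

```sh
# generate a synthetic cohort of OpenFace-dialect CSVs + manifest
facedep simulate --out-dir data/ --seed 1 --n-per-level 25,25,25,25 --duration 60

# train one of the nine models (fusion x backbone)
facedep train --data-dir data/ --fusion intermediate --backbone window_block_lstm \
    --alpha 0.1 --seed 1 --epochs 30 --checkpoint model.npz --log train.jsonl

# metric row on the held-out test split
facedep evaluate --data-dir data/ --checkpoint model.npz --split test --seed 1

# integrated-gradient feature attribution report (figures + CSV)
facedep explain --data-dir data/ --checkpoint model.npz --seed 1 --out-dir report/
```

The training/evaluation split is derived deterministically from the manifest
and `--seed`, so `evaluate` and `explain` must be given the seed used for
`train`.

## Layout

```
src/facedep/
  schema.py        canonical 49-column OpenFace dialect + feature groups
  openface_io.py   CSV parsing, joining, selection, padding, scaling
  cohort.py        labels, splits, balancing, label smoothing
  synthetic.py     planted-signature cohort generator
  nn/              numpy autograd engine, layers, Adam
  model_zoo.py     the nine fusion x backbone classifiers
  train_eval.py    training loop, metric tables, smoothing sweep
  attribution.py   integrated gradients + impact summaries/figures
  pipeline.py      manifest -> prepared splits glue
  cli.py           simulate / train / evaluate / explain
```
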