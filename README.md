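# eegfusion

Two-stage classification of multichannel scalp EEG:

1. **Preprocess** — band-pass (0.1–70 Hz) + 50 Hz notch filtering, optional
   user-supplied ICA component exclusion, common-average reference over the
   16 scalp electrodes of the 10-20 montage (A1/A2 dropped), per-channel
   z-scoring, segmentation of each recording into 60-s segments of twenty
   3-s pieces, per-piece STFT, and concatenation into one
   **concatenated power-density (CPD) map** per channel per segment.
2. **Stage 1 (TTM)** — a small-data vision transformer over each channel's
   CPD map, using Shifted Patch Tokenization (diagonally shifted copies
   concatenated before patch embedding) and Locality Self-Attention
   (diagonal of the score matrix masked to −∞, learnable per-head softmax
   temperature).
3. **Stage 2 (SGCM)** — the frozen transformer supplies one feature vector
   per electrode; spectral graph convolutions
   `H' = σ(D̂^{-1/2}(A+I)D̂^{-1/2} H W)` over the electrode-adjacency graph
   fuse them, with mean-pool readout and a linear classifier.

Training uses Adam + cross-entropy in two stages (stage 2 never touches
stage-1 weights) and is evaluated with subject-exclusive 10-fold
cross-validation (all segments of a subject share a fold), reporting
accuracy, recall, precision, F1 (macro one-vs-rest for multiclass),
confusion matrices and one-vs-rest ROC AUC.

Because no public cohort exists for the target task, the package ships a
**synthetic EEG generator** (`eegfusion.synthetic_data`) producing labeled
cohorts whose three classes differ by spectral signature — posterior ~10 Hz
alpha ("control"), diffuse high-amplitude 2–4 Hz slowing ("viral"), and
delta activity with superimposed anterior beta bursts ("nmdar") — on pink
background noise, with per-subject gain/frequency variability. A
`separation` knob scales the class-specific components from fully separated
(1.0) down to identically distributed (0.0). These signatures are testing
stand-ins, not physiologically validated models.

The neural-network stack (reverse-mode autodiff, linear/layer-norm blocks,
Adam) is implemented in pure numpy (`eegfusion.nn`) and gradient-checked
against finite differences, so the package has no deep-learning framework
dependency. EDF export/import is a minimal built-in 16-bit EDF codec.

## CLI

All commands share one YAML config (see `eegfusion.cli.DEFAULT_CONFIG` for
keys and defaults); every run writes a JSON manifest with the config
snapshot, seed, package version and input hashes.

```bash
eegfusion simulate   --config config.yaml   # synthetic cohort -> EDF + manifest
eegfusion preprocess --config config.yaml   # EDF -> CPD-map store (npz)
eegfusion train      --config config.yaml [--pairwise]
eegfusion report     --config config.yaml   # print a stored report
eegfusion evaluate   --config config.yaml   # re-verify stored fold metrics
```

`train` runs the cross-validated three-class experiment (plus the three
pairwise experiments with `--pairwise`) and writes
`reports/metrics_*.json` / `confusion_*.csv`.

Minimal config example:

```yaml
seed: 7
outdir: runs/demo
cohort: {n_subjects_per_class: 12, duration_s: 60.0, fs: 200.0}
train: {stage1_epochs: 15, stage1_lr: 1e-3, stage2_epochs: 8, stage2_lr: 2e-2, batch_size: 32}
cv: {k: 10}
```

The paper-scale schedule (150/80 epochs at lr 1e-4) is the library default
(`TrainConfig()`); the shorter profile above is for CPU-bound runs.

## Layout

```
src/eegfusion/
  montage.py               10-20 names, coordinates, default graph edges
  edfio.py                 minimal EDF writer/reader
  synthetic_data.py        class signatures, cohort generator, EDF export
  preprocess.py            filters, ICA exclusion, referencing, CPD maps
  nn/                      numpy autodiff, layers, Adam
  temporal_transformer.py  SPT + LSA transformer (TTM)
  spatial_gcn.py           electrode graph + spectral GCN (SGCM)
  training_eval.py         two-stage training, subject-wise CV, metrics
  cli.py                   simulate / preprocess / train / evaluate / report
```
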