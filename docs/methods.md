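# Methods

## Problem setting

The package targets seizure detection in long multichannel scalp-EEG
recordings annotated with seizure events (onset in seconds, duration in
seconds, category). The canonical data layout is 500 Hz sampling over 19
channels; the classification unit is a 1-second epoch, i.e. a `C × T`
matrix with `T = 500`. Three tasks are supported: binary seizure vs
non-seizure (all seizure categories merged), three-class typing (normal /
complex partial / electrographic, with the scarce video-detected class
excluded), and four-class passthrough.

## Epoching

Annotations are mapped to half-open sample intervals with floor
arithmetic: `start = floor(onset·fs)`, `stop = floor((onset+duration)·fs)`.
Floor plus half-open windows means boundary samples are never counted
twice; a sub-sample duration still occupies one sample so an event's span
is never empty. Seizure segments are sliced per category; normal signal of
matching total length is taken greedily from the seizure-free runs of the
recording, guaranteeing disjointness from every event and between
segments. Segments are chopped into non-overlapping `T`-sample epochs with
the trailing remainder discarded (models need a fixed input length; a
padded partial epoch would mix real and fabricated samples). No epoch ever
straddles a segment boundary. The train/test split is a seeded uniform
shuffle at 90:10 by default — the per-class train fractions this produces
are not exactly stratified, which matches how a plain global shuffle
behaves; an exactly stratified option exists. Per-recording montage
differences are handled by an optional channel-selection list rather than
hard-coded per-patient rules.

## Normalization

Standardization is global and train-only: one grand mean and one
*population* standard deviation (denominator `N·C·T`, no Bessel
correction) over every element of the training tensor, applied elementwise
to every split. Test statistics are never consulted; the fitted pair is
persisted with the model so streaming inference applies the identical
transform. Near-constant training data (σ < 1e−12) is rejected rather than
silently producing huge z-scores. A per-channel mode exists but is
non-default, because a single scalar pair preserves between-channel
amplitude relations that spatial filters can exploit.

## Architectures

All neural models are built on an in-package NumPy layer framework
(explicit forward/backward per layer, Adam, seeded initialization, early
stopping with best-weight restore). Layer gradients are validated against
central finite differences in the test suite; determinism is exact for a
given seed.

**MDCBG** (multi-dimensional CNN + bidirectional GRU). The epoch is
reshaped to a 3-D volume `(depth 1, height C, width T)` with one input
feature channel, so the 3-D kernels see channel-space and time jointly.
Four blocks: Conv3D(32, 3×3×3, stride (1,2,2)) → BN → ReLU → MaxPool3D
(1,2,2); Conv3D(64) → BN → ReLU → pool; two Conv3D(128) → BN → ReLU →
pool; two Conv3D(128) → BN → ReLU → pool. The surviving `(F, D, H, W)`
maps are reshaped to a length-`W` sequence of `F·D·H` features and fed to
a bidirectional GRU, dropout, and a dense head (sigmoid for binary,
softmax for multiclass). Two choices deserve note:

* *Volume orientation.* `(1, C, T)` is used so the stated stride (1,2,2)
  downsamples channels and time while keeping the singleton depth intact;
  orienting the volume `(C, T, 1)` would stride a singleton axis.
* *Ceil-mode pooling.* With floor-mode (valid) pooling the 19-channel axis
  collapses to size 0 at block 3 (19 → 10 → 5 → 3 → 1 → 0), so the stated
  stride/pool cascade is only shape-safe with ceil semantics (windows
  right-padded with −inf). Convolutions use same padding throughout for
  the analogous reason.

**EEGNet.** Temporal convolution (F1 maps, kernel (1, 64)) → depthwise
spatial filters over all channels (D per map, valid padding collapses the
channel axis) → separable temporal convolution (depthwise (1,16) +
pointwise) with batch norm, ELU, average pooling (4 then 8), and dropout.

**CTNet.** An EEGNet-style convolutional tokenizer produces a token
sequence along time; post-LN transformer encoder blocks (multi-head
self-attention + position-wise feed-forward, residual connections, layer
norm) model global dependencies; a dense head classifies the flattened
encoding.

**Ablations and recurrent baselines.** CNN-only (conv trunk + dense head),
BiGRU-only (bidirectional GRU straight on the length-T channel-vector
sequence), no-dropout MDCBG, BiGRU with learned softmax-over-time
attention pooling, and BiLSTM→GRU stacking. Classical baselines (Extra
Trees, Random Forest, XGBoost) are thin adapters over sklearn/xgboost on
flattened `C·T` vectors.

Unstated hyperparameters default to: GRU width 128, dropout 0.5, Adam at
1e−3, batch size 32, validation fraction 0.1, early stopping on validation
loss with patience 10 and best-weight restore. All are overridable through
`ModelSpec.hyperparams`. Published total parameter counts for the ablation
trio are not recoverable from the architecture prose alone (hidden sizes
are unstated), so the package exposes `count_parameters` for calibration
and asserts only the qualitative ordering (the recurrent-only model is far
smaller than the convolutional one; dropout adds no parameters).

## Evaluation

Per-class precision, recall, and F1 are computed one-vs-rest from the
confusion matrix; overall accuracy is the trace over the total; macro
averages are unweighted, weighted averages are support-weighted. A class
that is never predicted receives precision 0 with a warning rather than an
exception. Macro ROC-AUC is the unweighted mean of one-vs-rest AUCs, each
computed by the Mann–Whitney rank statistic with tied scores contributing
½; classes absent from the true labels are excluded with a warning and the
divisor adjusted.

Cross-validation is stratified 5-fold: folds preserve class proportions to
within one sample; in each fold the normalization statistics are fitted on
the four training folds only, the model is rebuilt from scratch (fresh
seeded initialization), trained with early stopping on a validation subset
carved from the training partition, and scored on the held-out fold. Fold
summaries are aggregated as mean ± *population* SD (divide by k). The
population convention is deliberate: it is the convention that exactly
reproduces the published fold tables this package's worked examples check
against, and the test suite contains the negative control showing the
sample convention does not.

## Channel attribution

Attributions are computed per class, sample, and flattened feature
(channel-major layout: feature `f` ↔ channel `f // T`, timepoint
`f % T`), then collapsed to channel level: mean of absolute values over
timepoints, then over samples, then unweighted over classes. Absolute
values are taken because signed contributions of opposite-phase timepoints
cancel; a signed mode is exposed. Backends:

* *tree_shap* — for xgboost models, the booster's built-in additive
  contributions; for sklearn tree ensembles, exact Shapley values by
  exhaustive coalition enumeration over the features each tree actually
  uses, with conditional expectations weighted by node sample counts.
  Exhaustive enumeration is exponential in the per-tree feature count and
  is therefore restricted to trees using ≤ 14 distinct features — ample
  for the shallow ensembles it is meant for, and exact where it applies
  (verified against full-feature enumeration and the efficiency axiom
  `base + Σφ = prediction`).
* *permutation* — for any model exposing probabilities, each channel is
  scored by the drop in accuracy when that channel's rows are permuted
  across samples (whole channels move together, preserving within-channel
  temporal structure). This is the supported channel-level path for the
  neural models, whose explanations would otherwise attach to internal
  features rather than raw channels.

## Alerting

Streaming inference standardizes each incoming `C × T` epoch with the
stored training statistics and classifies it; malformed epochs yield error
records and the stream continues. The trigger fires when at least k of the
trailing m predictions are seizure-positive (default (1,1): every positive
prediction), then disarms until the window drops below k positives, so a
sustained seizure produces one alert rather than one per epoch. Dispatch
is exactly-once per alert: a dry-run notifier appends a structured JSON
record, an SMTP notifier composes a message for an injectable mail client
(credentials referenced by environment-variable name, never stored), and
every configured actuator is switched ON idempotently. Notifier failures
are logged but never block actuation (fail-open, on the view that a missed
e-mail must not prevent environmental response). Actuators are an abstract
name→switch interface with a file-backed simulator; no hardware code.

## Synthetic data

The generator emulates the statistical skeleton of an annotated seizure
corpus: 500 Hz, 19 channels, 1-second epochs, four class archetypes
realised as band-limited Gaussian noise synthesized in the frequency
domain (exact band edges, no filter transients), plus optional amplitude
modulation, broadband noise floor, and linear trend:

| class | band (Hz) | amplitude (µV) | extras |
|---|---|---|---|
| 0 normal | 8–12 | 10 | — |
| 1 CPS | 3–8 | 100 | amplitude jitter 0.5 |
| 2 electrographic | 1–4 | 120 | trend 60 µV/s |
| 3 video-detected | 40–100 | 35 | noise floor 1.0 |

Amplitudes were calibrated once so that a depth-2 stochastic
gradient-boosted classifier on flattened raw epochs separates classes 0
and 1 with held-out accuracy above 0.9 at 50 epochs per class — the
weakest learner any downstream test relies on; milder contrasts leave
variance-scale differences invisible to single-feature splits. The
qualitative ordering of the class descriptions (low < bursty-moderate <
prominent) is preserved. Seizure events can be embedded in longer normal
background, and a planted-channel mode restricts class structure to one
channel for attribution validation. All randomness flows from a single
seeded generator; identical configuration and seed give bit-identical
output.

What the generator does *not* emulate: volume-conduction correlation
between channels, nonstationary background, artifacts (blinks, EMG, line
noise), inter-patient variability, or realistic seizure morphology.
Passing tests therefore demonstrate that the pipeline's machinery —
epoching arithmetic, leakage control, optimization, attribution,
alerting — behaves correctly, not that the models would reach comparable
accuracy on clinical EEG.

## Problem sizes

The test suite and acceptance script run everything at reduced scale,
chosen as the smallest sizes at which each check is meaningful: the
learning check trains a reduced-width MDCBG (filters 8/16/32/32, GRU 32)
on 200 epochs per class of the canonical 19×500 shape; attribution
recovery uses 20 seeded runs of 100+100 epochs with a 50-tree xgboost
model; the alert simulation uses 4-channel, 50 Hz recordings. Architecture
shape-safety is always checked at the full 19×500 input.

## Known limitations

* The NumPy training loop is single-threaded and unoptimized; full-width
  MDCBG training on a large corpus is out of scope (the full-width model
  builds and runs forward passes, and reduced-width variants train).
* Exact tree-Shapley enumeration is limited to shallow trees; deep
  ensembles should use xgboost contributions or permutation importance.
* EDF export is not implemented (reading is, via mne); synthetic
  recordings persist as `.npy` plus an events CSV.
* The three-class task assumes the video-detected class is too scarce to
  model, mirroring its exclusion in the data layout this package targets.
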