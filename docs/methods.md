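# Methods

## Problem and pipeline

`eegemo` implements an emotion-classification pipeline for multichannel EEG
in which the class signal is read from *functional-connectivity images*:
per-frequency-band 2D feature matrices built from short overlapping signal
windows, classified by a three-stage network. The stages are trained
separately:

1. **Convolutional extractor.** Two convolutional layers with
   one-dimensional (k x 1, k = 3) kernels slid over the image height,
   dropout after each, and one 3 x 3 max-pooling layer. The extractor is
   trained with a single temporary fully connected output layer
   (sigmoid + binary crossentropy for 2 classes, softmax + categorical
   crossentropy for 3), then the head is discarded.
2. **Sparse autoencoder (SAE).** The pooled maps are flattened, min-max
   scaled to [0, 1], and autoencoded through 512 -> 128 -> 512 -> input-dim
   layers. The reconstruction layer is sigmoid and scored with binary
   crossentropy; the hidden layer carries a sparsity penalty
   `beta * sum_j KL(rho || rho_hat_j)` where `rho_hat_j` is the batch-mean
   activation of hidden unit j and KL is the Bernoulli
   Kullback-Leibler divergence. The 512-unit decode layer's activations
   are the exported representation.
3. **Classifier (DNN).** Fully connected 512 -> 256 -> output layers on
   the SAE export, trained on a random 80/20 split. The canonical metric
   is the mean test accuracy over the final 10 epochs; the "convergence
   epoch" is the first epoch reaching 95% of that plateau.

A *baseline CNN* with the identical convolutional and dense layer sizes is
trained end-to-end on the same split for comparison.

Optimizers are Adadelta (lr 0.01, rho 0.95, eps 1e-7) for binary tasks and
the SAE, and Adam (lr 0.01, conventional betas) for the 3-class head, with
learning rate 0.01 and the batch sizes 128 (conv stages), 64 (SAE),
128 (classifier).

## Modelling conventions and numerical choices

- **Rectifier naming.** Parts of the literature this pipeline follows
  print the softplus formula ln(1 + e^x) under the name "ReLU". The
  default activation is the standard rectifier max(0, x); softplus is
  selectable everywhere (`activation="softplus"`), and both are covered by
  the gradient checks.
- **Convolution contract.** Valid (no padding), stride 1; a kernel spans
  all input channels (the four band images enter as channels). Pooling
  stride equals the pool size and partial blocks are truncated, so a
  32 x 32 input pools to 10 columns and, after two valid 3 x 1
  convolutions (height 32 -> 28), 9 rows: the flattened extractor output
  is 64 x 9 x 10 = 5760 features (16 x 19 x 20 = 6080 for the 62-channel
  montage).
- **Two-unit binary head.** The binary task uses a 2-unit sigmoid output
  with one-hot targets under binary crossentropy, matching the configured
  layer sizes; a 1-unit head is supported as an alternative.
- **Crossentropy conventions.** Predictions are clipped to
  [1e-7, 1 - 1e-7]; binary crossentropy averages over all elements,
  categorical over samples. The Bernoulli KL uses the standard two-term
  form; the per-unit mean activation is clipped into (1e-7, 1 - 1e-7)
  before the KL, and clipped units receive no penalty gradient (rectified
  hidden activations can exceed 1, where the Bernoulli divergence is
  undefined).
- **Sparsity defaults.** rho = 0.05, beta = 3 — classic sparse-autoencoder
  practice; beta = 0 recovers a plain autoencoder and is tested as such.
- **Dropout** 0.25 after each convolutional layer (rate not dictated by
  the protocol; exposed in `ConvSpec`).
- **Initialisation.** Fan-in-scaled uniform weights (limit
  sqrt(6/fan_in), the standard rectifier scaling — fan-average scaling
  lets activations decay through stacked ReLU layers and starves the later
  stages) from a seeded generator; all randomness (weights, dropout,
  shuffling, splits, data) flows from explicit integer seeds, so
  identically configured runs are bit-identical on one thread.
- **Filtering.** 4th-order Butterworth band-passes applied
  forward-backward (zero phase) — phase distortion would corrupt the
  correlation images. The four analysis bands are used verbatim as
  numeric ranges (1-7, 8-13, 14-30, 30-45 Hz); the conventional
  Greek-letter names attached to those ranges are inconsistent in parts of
  the source literature, so band labels are treated as opaque.
- **Resampling** uses polyphase filtering; for a rate change up/down in
  lowest terms the output length is ceil(n * up / down).
- **Windowing.** Windows align to the trial start; a trailing partial
  window is dropped: count = floor((duration - window)/step) + 1. Every
  segment inherits its trial's label.
- **PCA feature reading.** The per-segment PCA treats channels as
  observations and time points as variables, projecting onto the top
  n_channels components; this is the only reading that reproduces the
  square channels x channels feature shape without extra assumptions. The
  fit is per segment — no information crosses segments. Component signs
  follow a deterministic convention (largest-magnitude loading positive).
- **Degenerate channels.** A zero-variance channel makes correlation and
  higher moments undefined; its correlation row/column (and its
  skewness/kurtosis) are set to 0 and the sample is flagged.
- **Feature scaling.** Stacked tensors are min-max scaled to [0, 1] with
  stored constants (invertible) because the SAE's reconstruction loss is
  binary crossentropy, which needs [0, 1] targets.

## Training-protocol fidelity

The protocol's `paper` mode trains the extractor and the autoencoder on
*all* samples before the 80/20 split, so representation learning sees the
eventual test samples. This is reproduced deliberately because it is the
protocol being implemented; a `strict` mode (split first, fit every stage
on the training portion only) is provided, and every report labels its
mode. The null-calibration experiments show that at effect size 0 the
leak does not manufacture accuracy — both modes sit at chance.

## The synthetic-data generator

Real emotion-EEG corpora (32 subjects x 40 trials x 32 channels at 128 Hz
with 63-s trials; 15 x 15 x 62 channels at 200 Hz with 80-s segments) are
access-restricted, so the package ships a generator that emulates their
geometry and places a controllable class signal where the features look
for it. Per trial and band, `n_latent_sources` (default 6) white-noise
sources are passed through the same zero-phase band-pass the analysis
uses, scaled to unit variance, and mixed into channels by
`M[class, band] = M0[band] + effect_size * D[class, band]`, with `M0` and
`D` standard-normal (scaled by 1/sqrt(n_sources)) and drawn once per seed.
Bands are summed and white sensor noise (sd 1.0) is added. Classes are
balanced within subject by construction.

What this emulates: band-limited rhythms shared across channels with
class-dependent inter-channel correlation, the premise of
correlation-image classification. What it does not emulate: ocular/muscle
artifacts, volume conduction and electrode geometry, nonstationarity,
inter-subject variability of the class signal (the mixing matrices are
shared across subjects), or heavy-tailed noise. Passing tests therefore
demonstrate that the pipeline recovers correlation-coded class structure
and is correctly calibrated under the null — not that it attains any
particular accuracy on real recordings.

Unit-variance sources with 1/sqrt(L)-scaled mixing keep per-band channel
power comparable across bands and an O(1) signal-to-noise ratio; the
marginal channel variances are class-independent, so the discriminative
information is confined to correlation structure and the
statistical-characteristics feature is only indirectly informative.

## Study conditions and problem sizes

Two canonical conditions drive the benchmark experiments and the
acceptance script:

- **Signal condition:** 4 subjects x 10 trials of the 32-channel geometry
  (63-s trials, first 3 s trimmed, 8-s windows stepping 4 s -> 560
  segments), effect size 1, correlation features, stage schedules
  20/30/30 epochs (baseline 30). Expected behaviour: near-ceiling test
  accuracy.
- **Null condition:** the same generator with effect size 0, scaled to
  2 subjects x 8 trials with schedules 5/8/15 — chance-level behaviour
  does not depend on training length, and the shorter schedule keeps the
  default test run fast.

At these scales all stages use batch size 32 (the full-scale presets keep
128/64/128): with 560 samples the full-scale batches would give only ~5
optimizer steps per epoch, an order of magnitude below the regime the
epoch counts were chosen for, which distorts Adadelta's per-epoch
progress. Batch size scales with the study; epochs do not.

Both conditions are evaluated over three seeds with the composite model
and the baseline CNN fitted on identical data and splits.

## Known limitations

- The convolutional cores are pure NumPy; they are exact (gradient-checked
  against central finite differences) but not fast. The desk-scale
  conditions above run in minutes on one CPU; the full-geometry presets
  (17,920 segments, 100-epoch schedules) are supported but take hours.
- Printed parameter counts in the source literature (~7.5 x 10^5) cannot
  be reconciled with the printed layer sizes under any padding convention;
  the package reports its own exact counts (`Network.n_parameters`) and
  asserts nothing about the published figures.
- With strongly separable synthetic data both models can saturate within a
  few epochs, compressing the contrast between their convergence speeds;
  the convergence comparison is therefore most informative at moderate
  effect sizes.
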