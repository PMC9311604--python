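# Methods

## Problem setting

Four-class motor-imagery (MI) decoding from multichannel EEG: each trial is
a fixed-length matrix of `electrodes x samples` (22 x 1125 for a
BCI-IV2a-style montage at 250 Hz, 44 x 1125 for a high-gamma-style montage
after downsampling from 500 Hz), labeled left hand / right hand / feet /
tongue.  Evaluation is within-subject: the model is trained on one or more
recording sessions of a subject and tested on that subject's held-out
session(s).

## Architecture

### EEGNet branch

Each branch is a compact EEGNet-style feature extractor:

1. **Temporal convolution** — `F1` filters of size `1 x K` applied along
   time with same padding and no bias, followed by batch normalization.
   The three branches use `F1 = 4, 8, 16` with `K = 16, 32, 64` samples
   (64, 128 and 256 ms at 250 Hz), so each branch sees a different
   temporal scale.
2. **Depthwise spatial convolution** — one `E x 1` filter per temporal
   filter with depth multiplier `D = 2`, collapsing the electrode axis and
   producing `F2 = F1 * D` channels; batch norm, ELU (alpha = 1), average
   pooling `1 x 8`, dropout.
3. **Separable convolution** — depthwise `1 x 16` temporal convolution
   followed by a `1 x 1` pointwise mix to `F2` channels; batch norm, ELU,
   average pooling `1 x 8`, dropout.

Dropout rates are 0 / 0.1 / 0.2 for branches 1-3.  All convolutions are
biasless with same padding (even kernels pad the extra cell on the trailing
side); average pooling floors the time axis, so a 1125-sample trial ends as
an `F2 x 1 x 17` map.  Because the depthwise stage absorbs the electrode
axis, the output shape is independent of the electrode count — the same
architecture serves both montages.

The depth multiplier, pool sizes and separable kernel are not uniquely
determined by the branch table alone; they are pinned by the parameter
accounting of the fusion variant (below), which requires the per-branch
flattened widths 8x17 + 16x17 + 32x17 = 952.  Batch-norm uses eps = 1e-3 and
running-statistics momentum 0.99; no max-norm weight constraints are
applied.

### CBAM attention

Each branch output passes through a convolutional block attention module:

- **Channel attention**: global average- and max-pooling per feature channel
  produce two C-vectors; both pass through one *shared* bias-free MLP
  (hidden width `max(1, C / r)`, ReLU hidden activation, linear output);
  the two outputs are summed elementwise and squashed with a sigmoid, and
  the resulting per-channel weights rescale the map.  The output layer is
  linear before the sum — with a sigmoid applied per path the standard
  sum-then-sigmoid composition would be impossible.
- **Spatial attention**: the channel-wise mean and max maps are stacked and
  convolved with a single `k x k` kernel (2 input channels, 1 output, one
  bias, same padding); a sigmoid gives a per-position weight map.  On the
  height-1 maps produced here the module degenerates gracefully to temporal
  attention.

Reduction ratios are 2 / 8 / 8 and spatial kernels 2 x 2 / 4 x 4 / 2 x 2
for branches 1-3 (the best cells of a ratio x kernel grid search, which the
`grid` module can reproduce on any dataset).  Both gates lie strictly in
(0, 1), so attention can only attenuate — an invariant the tests assert.

### Multi-branch assembly and fusion

`build_mbeegcbam` flattens and concatenates the three attended maps
(952 features) into a single shared dense softmax classifier.  The "one
shared classifier" reading matters: per-branch dense layers cannot
reproduce the fusion variant's parameter accounting below, so that variant
is excluded by arithmetic.

`build_fmbeegcbam` taps the same branch layers twice — once after the
EEGNet blocks, once after the CBAM blocks — and concatenates both flattened
taps (1904 features) before the classifier.  Because every convolutional
and attention parameter is shared by construction between the two taps, the
fusion model has exactly `n_classes x 952 = 3808` more trainable parameters
than the base model: the widened classifier is the only difference.  This
identity holds for any input length that survives the pooling cascade and
is asserted analytically over several lengths.

`build_eegcbam` exposes the single-branch ablation used by the grid search.

## Training

Adam with fixed global hyperparameters for every subject: learning rate
0.0009, beta1 0.9, beta2 0.999, epsilon 1e-7, batch size 64, categorical
cross-entropy, 1000 epochs by default (tests and examples use far fewer).
No early stopping, learning-rate schedule or validation split.  Per-epoch
shuffling and dropout draws are reseeded from `(seed, epoch)`, so a run is
bit-reproducible on a fixed platform.  Weight initialization is
variance-scaling (He) for convolutions and fan-based uniform (Glorot) for
dense and attention-MLP weights, all from one seeded generator.

The layers are implemented directly in NumPy with hand-derived backward
passes (verified against central finite differences in the test suite to
1e-6 relative error in float64).  The temporal convolution runs in the
frequency domain via cached real FFTs; a few memory-bound elementwise and
reduction kernels (batch-norm statistics and gradients, the depthwise
spatial convolution) are JIT-compiled with numba.  Cross-entropy clips
probabilities at 1e-12.  Softmax ties in `predict` resolve to the lowest
class index.

## Evaluation

Confusion matrix (rows = true), accuracy, Cohen's kappa
`(p_o - p_e) / (1 - p_e)`, per-class precision/recall and unweighted macro
averages.  The headline F1 is the harmonic mean of macro precision and
macro recall; per-class F1 and its macro average are also exposed (the two
conventions agree to the precision reported in typical MI tables, so the
choice is documented rather than observable).  For a balanced 4-class test
set with uniform predicted marginals, kappa reduces to
`(accuracy - 1/4) / (3/4)` — the identity used in the worked examples.
Degenerate cases (a class never predicted, chance agreement 1) contribute 0
with a warning instead of NaN.

Paired model comparison uses the two-sided Wilcoxon signed-rank test on
per-subject scores: zero differences dropped, average ranks for tied
magnitudes, the exact null distribution for n <= 25 (computed by a
generating-function convolution over doubled ranks, algebraically identical
to enumerating all 2^n sign assignments), and a normal approximation with
continuity and tie corrections beyond.

## Synthetic data generator

`generate_trialset` emulates the *structure* of a 4-class MI dataset: per
class, a deterministic template (a Hann-windowed sinusoid at a
class-specific center frequency, peak amplitude 1, on a class-specific
electrode subset) plus white Gaussian noise scaled so the template/noise
power ratio equals `snr_db` in expectation (powers averaged over the whole
trial matrix).  Defaults: 22 channels, 1125 samples, 250 Hz, 100 trials per
class, 6 dB SNR, center frequencies 8/12/20/28 Hz on four disjoint
electrode blocks — mu/beta-range tones with distinct spatial footprints, a
deliberately idealized stand-in for lateralized sensorimotor rhythm
changes.  A pink-noise option (1/f-shaped spectrum, renormalized to unit
variance) exists for extra realism but is off by default.

The generator does **not** model event-related desynchronization dynamics,
volume conduction, electrode covariance, artifacts, non-stationarity or
inter-subject variability.  Consequently, passing learning tests show that
the architecture, gradients and training loop work end to end on separable
band-limited signals; they say nothing about decoding accuracy on real EEG.

## Data pipeline conventions

- Epochs are half-open, 0-based windows `[cue - 0.5 s, cue + 4.0 s)` —
  4.5 s, i.e. 1125 samples at 250 Hz.  The 0.5 s pre-cue anchor is
  configurable.
- Downsampling (e.g. 500 to 250 Hz) is integer-factor polyphase decimation
  with a zero-phase FIR anti-alias filter (`scipy.signal.resample_poly`);
  upsampling and non-integer ratios are rejected.
- Motor-cortex channel selection keeps channels whose name contains a
  pattern (default "C"), preserving order; EOG channels are dropped at
  load time by the optional GDF/EDF reader (mne).
- No band-pass filtering and no normalization by default; a per-channel
  z-score helper exists but is opt-in.
- The within-subject split holds out the *last* `n_test_sessions` sessions.

## Problem sizes used in the checks

The parameter-delta and shape identities are exact and instantaneous.  The
full-scale learning check trains the three-branch model for 50 epochs on
400 synthetic trials of 22 x 1125 at 10 dB SNR (a separability level at
which a matched-filter classifier is already near-perfect, so the check
isolates optimization correctness rather than statistical difficulty) and
evaluates 200 held-out trials; most other tests use a miniature 4-electrode,
64-sample configuration of the same architecture.

## Known limitations

- CPU-only NumPy training: throughput is adequate for the synthetic study
  sizes, not for 1000-epoch runs on full datasets.
- Exact bit-reproducibility holds per platform/BLAS build, not across them.
- The GDF/EDF adapter maps annotation descriptions to labels by first
  appearance; competition-specific event codes may need remapping.
- Checkpoints store parameters positionally with a JSON sidecar describing
  the build; they are not portable across architecture changes.
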