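# Methods

`pcgkit` implements an automatic screening pipeline for heart-sound (PCG)
recordings: is a recording *normal* or *abnormal*?  The pipeline follows the
canonical order — noise reduction, spike removal, segmentation, feature
extraction, classification, evaluation — and is built so that every stage is
testable offline against a seeded synthetic generator.

## Synthetic data generator

Real heart-sound corpora (thousands of 5–120 s bedside recordings with
binary labels) cannot ship with a library, so `pcgkit.simulate` generates
recordings that reproduce the *statistical structure* the pipeline depends
on:

- **Heart cycle.** Each cycle is S1 → systole → S2 → diastole.  Default mean
  state durations are S1 = 0.122 s, systole = 0.30 s, S2 = 0.092 s, with
  diastole absorbing the remainder of the cycle (cycle length from a heart
  rate drawn per recording, mean 75 bpm, SD 8).  Per-state durations vary
  with a 5% coefficient of variation.  Annotations record the generating
  state of every sample exactly, which is what makes beat segmentation and
  the per-state engineered features testable against ground truth.
- **Waveform.** S1/S2 are Gaussian-windowed band-limited noise bursts
  (50–150 Hz and 80–200 Hz).  This is a deliberate choice over recorded
  templates: the generator stays dependency-free and every spectral property
  asserted in tests is controlled by a config field.
- **Abnormality.** The default abnormal class adds a band-limited
  (150–400 Hz) systolic murmur.  `abnormality="timing"` instead inflates
  cycle-length variability (an irregular-rhythm pathology with no murmur),
  and `"mixed"` draws each abnormal record as one or the other — used to
  build tasks where different envelope channels carry complementary signal.
  A config switch adds diastolic murmurs.
- **Noise levels.** White background noise sits 20 dB below the heart-sound
  component (`noise_snr_db=20`, a moderately clean bedside recording); the
  murmur sits 10 dB above the background noise by default
  (`murmur_snr_db=10`, a clearly audible but not dominant murmur).  Tests
  that require a near-separable task raise the murmur to +20 dB explicitly.
- **ECG.** The transfer-learning source domain is deliberately minimal:
  P/QRS/T Gaussian bumps per beat, where the atrial-fibrillation class has
  no P bump and a six-fold larger beat-interval coefficient of variation.
  Transfer learning needs a learnable source task with shared
  temporal-burst structure, not clinical fidelity.
- **Spikes.** `inject_spikes` adds 10 ms half-sine transients (≥ 500 ms
  apart) scaled by a multiple of the recording's maximum absolute amplitude,
  as fixtures for spike removal.

All randomness flows from one `numpy` generator seeded per call; identical
`(config, seed)` give bit-identical datasets.

What the generator does **not** emulate: realistic murmur morphology
(crescendo/decrescendo shapes, radiation), respiration and friction noise,
sensor transfer functions, split S2, ectopic beats, or the pathology mix of
real screening corpora.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its learning components can exploit
the kinds of contrast they target — not that real-world accuracy figures
carry over.

## Preprocessing

Recordings above 1 kHz are polyphase-resampled down to 1 kHz.  A 4th-order
Butterworth band-pass keeps 25–400 Hz, where heart-sound energy lives; it is
applied forward–backward (zero phase) so S1/S2 timing survives for
segmentation.  Upsampling is refused by default.

Spike removal is the windowed maximum-absolute-amplitude (MAA) procedure:
split into consecutive 500 ms windows (final partial window kept); while any
window MAA exceeds 3× the median of all window MAAs, take the worst window,
call its MAA sample the spike top, zero from the last zero crossing strictly
before the top to the first strictly after (window edges when no crossing
exists), and recompute.  A zero crossing is a sign change between
consecutive samples, with a literal zero sample counting as a crossing.  The
loop recomputes MAAs after every zeroing and is capped at 100 iterations.
The procedure is the identity on spike-free inputs and idempotent.

## Segmentation

Sliding windows (default stride 1 s, window 2 s — the configuration that
performs best in our reference experiments) with trailing remainders
discarded; recordings shorter than one window yield a single right-padded
segment so no record is dropped.  Fixed segmentation is the stride = window
degenerate case; a 10 s window is available as a preset.  Beat segmentation
cuts S1-onset-to-S1-onset cycles from the annotation and linearly resamples
each to a common length (the annotation is supplied externally — e.g. from
simultaneously recorded ECG — rather than estimated, so no hidden
semi-Markov segmenter is involved).  Record-level decisions average the
segment abnormal-probabilities by default (`mean_prob`); majority voting is
available but coarser when a record has few segments.

## Features

**Envelope stack (neural input).**  Four channels at a common 50 Hz channel
rate, each standardized to zero mean/unit variance (constant channels map to
zeros): the preprocessed waveform, the homomorphic envelope
(`exp(lowpass(log |analytic(x)|))` with a first-order zero-phase 8 Hz
low-pass — the log turns the multiplicative envelope/carrier structure
additive), the Hilbert envelope (analytic-signal magnitude via the
−j·sgn(ω) multiplier), and an autocorrelation-method PSD band envelope
(biased autocorrelation per 50 ms frame at 50% overlap, transformed at full
lag and averaged over 40–60 Hz, then interpolated back to the signal grid).
At full lag the AC-method PSD equals the periodogram (Wiener–Khinchin),
which the tests assert against an independently coded periodogram to 1e-6
relative error.

**Engineered vector (classical input).**  124 named features:

- 36 time-domain: mean+SD of cycle and per-state durations (10), of
  per-state duty ratios and systole/diastole (10), of per-state mean
  absolute amplitudes and S1/systole, S2/diastole amplitude ratios (12),
  plus whole-signal skewness, kurtosis, zero-crossing rate, RMS (4).
- 36 frequency-domain: per state, the median over occurrences of
  Hamming-windowed DFT mean band power in 9 bands tiling 25–400 Hz.
- 52 MFCC: 13 coefficients (25 ms frames, 10 ms hop, 26 mel filters,
  orthonormal DCT-II) × 4 moments (mean, SD, skewness, kurtosis) over
  frames.

The 36+36 enumeration and the 13×4 MFCC summary are declared conventions of
this library (exposed through `FEATURE_NAMES` so alternatives can be
swapped); only the group sizes and the ingredient transforms are fixed by
the design.

## LKNet

A residual 1-D CNN whose convolutions use a deliberately large kernel
(default 15 taps; tested at 9/15/31) — wide receptive fields suit smooth
50 Hz envelope sequences better than the conventional 3-tap kernels.
Architecture: a learned per-timestep input projection (so 1-channel ECG and
4-channel PCG inputs meet identically shaped residual blocks), `n_blocks`
blocks of [conv–BN–ReLU–conv–BN] + identity/projected skip, channel doubling
with stride-2 temporal downsampling every 2 blocks from a base width of 32,
global average pooling, and a 2-class softmax head.  Block internals
(BatchNorm, ReLU, the doubling schedule) are config-pinned conventions.

The network, its backpropagation and its Adam optimizer are implemented
directly on numpy arrays (im2col convolutions; float32).  Training uses
cross-entropy, optional class weighting, an internal stratified validation
split, early stopping on validation MAcc with best-epoch restoration, and —
for boosting — weighted mini-batch sampling.  After each epoch the
batch-norm inference statistics are re-estimated exactly from one pass over
(up to 512 of) the training samples: exponential running averages lag the
final weights badly in small-data regimes, and the exact pass removes the
train/eval distribution gap.  All randomness comes from the config seed;
fixed seed + fixed data order reproduce final weights bit-for-bit on one
platform.

## Transfer learning (ECG → PCG)

1. Train an 8-block LKNet on the two-class ECG rhythm task; a stratified
   hold-out measures source validation accuracy, and hand-off is refused
   below 90% (overridable).
2. Drop the last 4 source blocks; copy the first 4 and mark them frozen.
3. Append 8 freshly initialized blocks continuing the source width/stride
   schedule, plus a fresh 4-channel input adapter and head.
4. Fine-tune on PCG segments.

Frozen applies to learned parameters: frozen blocks are excluded from
optimizer updates and their BatchNorm layers never use batch statistics
during training, so their convolution weights and BN affine parameters stay
bit-identical through fine-tuning.  Their BatchNorm *buffers* (running
mean/variance) are deliberately re-estimated on the target data during the
calibration pass: normalization statistics are properties of the data
domain, not learned knowledge, and keeping the source-domain statistics
makes the frozen blocks mis-normalize every target activation (in our
experiments that turned transfer from neutral-to-helpful into consistently
harmful).  This is the standard batch-norm domain-adaptation reading of a
"fixed" block.  The per-modality input adapter is what makes the surgery
well-typed across 1-channel and 4-channel inputs.

What the desk-scale transfer experiment shows, and its honest limits: with
a rhythm-linked source/target pair (AF-vs-normal ECG source, irregular-
rhythm PCG target) the fine-tuned model matches or slightly exceeds an
identically budgeted from-scratch model of the same 12-block architecture.
The effect at this scale is small and seed-sensitive — both models fit the
~300 training segments within a few epochs, so the comparison measures
generalization from a small sample, where the transferred features provide
at best a modest prior.  A murmur-contrast target shares nothing with the
ECG rhythm task and showed no transfer benefit; the rhythm-linked pairing
is therefore the study condition.

## MFS-LKNet boosting

Rounds train one reduced LKNet (default 4 blocks — weak enough for
re-weighting to matter) per feature set, cycling through
full-stack/homomorphic/Hilbert/PSD channels.  Record weights start uniform;
after each round the weighted record-level training error ε (clamped to
(1e-6, 0.5−1e-6)) gives the member weight α = ½·ln((1−ε)/ε), and weights are
multiplied by e^{+α} (misclassified) / e^{−α} (correct) and renormalized —
the classical AdaBoost update, which places exactly half the mass on errors
whenever ε is unclamped.  ε is computed on record-level decisions because
records, not segments, are the diagnostic unit.  Fusion is deliberately
light: the default combines members by the weighted log-odds score
Σ α_m(2p_m−1) through a logistic squash; a logistic head calibrated on a
held-out 20% record split is available instead.  Members can optionally be
initialized by the ECG transfer surgery.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), MAcc = (Se+Sp)/2 — MAcc is
the community-standard screening metric because it is insensitive to class
imbalance.  Cross-validation is stratified at the record level (a record's
segments never straddle a fold); k = 10 by default with k = 6 available as a
preset, since both protocols appear in the literature this pipeline follows.
Fold assignment, model initialization and batch order all derive from
explicit seeds, so a run is reproducible end to end.

## Problem sizes used in tests and the acceptance script

The shipped experiments run on desk-scale synthetic datasets chosen as the
smallest sizes at which the studied effects are stable: 400 + 100 recordings
(5–15 s) for the high-murmur learning check, 300–600 ECG recordings for the
source task, 100–140 recordings for the transfer comparison, and ~120
recordings for the boosting comparisons, with reduced network widths
(base 8 channels, kernel 9) for speed.  Stochastic learning checks run three
seeds and require a majority.  These sizes are the package's own test
design; headline accuracies from full-scale public-corpus experiments are
not reproduced here.

## Known limitations

- The numpy implementation is single-device, CPU-only and unoptimized for
  large corpora.
- BatchNorm calibration caps at 512 samples; gigantic training sets would
  estimate inference statistics from a subset.
- The WFDB binary format is not read; datasets enter as WAV + CSV manifests.
- Beat segmentation requires externally supplied annotations.
- The synthetic abnormality model (murmur/timing) is a stand-in; it makes no
  claim about the pathology mix of any real corpus.
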