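# Methods

This note documents the models, conventions and design choices behind the
package, in the order data flows through it.

## Synthetic snore model

A snore event is a harmonic stack: partials at `h·f0` (h = 1..H) with
amplitudes `rolloff^(h-1)`, random phases, a shared envelope of 2–8 Hz
sinusoidal amplitude modulation (depth 0.5) and 50 ms raised-cosine
onset/offset ramps, over a pink-noise floor 30 dB below the harmonic
power. Requesting a harmonic above Nyquist is rejected rather than
silently aliased.

The **low-frequency energy ratio** (LFER) — the fraction of Welch-PSD
energy below 650 Hz — is imposed exactly by splitting the signal at the
band edge (partials split exactly by frequency; the noise floor via an
order-8 Butterworth low/high pair) and rescaling the low side so the
energy fraction hits the target. The target is reachable only when both
sides carry energy; with all partials on one side of the edge the measured
ratio saturates near 0 or 1, which the tests cover explicitly. Generated
events are unit-RMS; segments assembled for WAV export are peak-scaled to
0.9.

Non-snore segments are a three-way mixture mirroring common ward sounds:
200–2000 Hz band-filtered noise (breathing), sparse exponentially decaying
impulses (footsteps), and 300–3400 Hz band noise (conversation). Noise
generators (`white`, `pink`, `speech_band`, `transient_train`) are pure
functions of (spec, seed) and return unit-RMS waveforms; the pink
generator's PSD slope is −3 dB/octave by spectral shaping.

### Cohort distributions

Per-patient LFER, nightly event count (events per 8 h) and median event
duration are log-normal around the group medians — positive, right-skewed
clinical variables — with LFER clipped into (0, 1). Defaults encode the
published clinical group medians: LFER 0.52 (stenotic) vs 0.69
(non-stenotic), 835.5 vs 649 events/8 h, 1.60 vs 1.51 s.

The dispersions are free parameters of the generator. They are set to
log-space sigmas of 0.18 (LFER), 0.22 (event count) and 0.15 (duration),
chosen once by a normal-theory power analysis so that at the clinical
sample sizes (16 vs 15) the Mann-Whitney test rejects for LFER and event
frequency in well over 80% of cohort replicates while the small duration
contrast stays non-significant in the majority — i.e. the generator
reproduces the reported significance *pattern*, not any particular
p-value. The printed clinical IQRs would imply a larger event-count
dispersion (sigma ≈ 0.5) under which that pattern is not reproducible at
n = 31; the dispersion here is therefore a deliberate generator
calibration, not an estimate of the clinical population.

What the generator does **not** emulate: room acoustics and reverberation,
physiological airway dynamics, night-scale nonstationarity, apnea/hypopnea
structure, and recording-chain artifacts. Tests passing on this cohort
show the pipeline's statistical and learning machinery is correct, not
that clinical-scale accuracy figures transfer.

## Preprocessing

Audio is averaged to mono, polyphase band-limited resampled to 22.05 kHz,
and zero-meaned. Endpoint detection is a classical double-threshold
short-time-energy VAD: the noise floor is the median 20 ms frame energy;
regions must exceed 8× the floor somewhere and extend while above 2× (or
while the zero-crossing rate exceeds 3× its median at above-floor energy);
regions closer than 100 ms merge; regions shorter than 50 ms drop. All
thresholds are configurable. Optional denoising is deliberately absent
from the default path so results are exactly reproducible.

Labeled events are cut into exactly 3-s clips (66 150 samples): shorter
events are zero-padded at the tail (the pad length is recorded), longer
events are tiled non-overlapping into ⌈L/3⌉ clips with the last padded.
Non-overlapping tiling is a documented choice; overlap is not implemented.

Dataset partitioning is patient-level everywhere: `patient_split`
(default 8:2 by patient count, so 31 patients split 25/6) and
`make_cv_folds` (k = 5) guarantee disjoint patient-ID sets, asserted by
tests on every split.

## Features

All four representations share the 20 ms / 10 ms Hamming frame grid and
the framed DFT, except chroma analysis, which uses ~93 ms frames because
pitch-class resolution needs ~11 Hz bins.

- **Mel**: 128 unit-peak triangular filters equally spaced on the HTK Mel
  scale over 0–11 025 Hz; log energies with floor 1e-10.
- **MFCC**: type-II cosine transform of the log Mel energies over the M
  filters, first 13 coefficients. A constant log-energy vector maps to
  exactly zero coefficients (cosine orthogonality), which the tests use as
  an oracle.
- **CQT**: implemented as a constant-Q filter bank on the linear DFT grid
  (triangular filters at centers `f_k = f1·2^((k−1)/B)`, bandwidths
  `f_k·(2^(1/B)−1)`, so Q is constant by construction). Defaults: f1 =
  32.7 Hz, 12 bins/octave, 84 bins. This frame-based formulation keeps all
  four features on the same "filter bank over the power spectrum"
  substrate, which is what the enhancement step operates on.
- **CENS**: 12 pitch classes by nearest equal-tempered pitch, per-frame L1
  normalization with a silence convention (uniform 1/12), the standard
  4-level quantization staircase (0.4/0.2/0.1/0.05 →
  1/0.75/0.5/0.25), 41-frame Hann smoothing, downsampling by 10, L2
  normalization.

**Enhancement** operates on linear filter-bank energies before any log
compression, for all four kinds (for MFCC it precedes the log and the
cosine transform). Per frame, the threshold is the sorted
linear-interpolation 80th percentile of that frame's filter energies; the
comparison is strict, so a uniform frame passes through unchanged and at
most ~20% of filters are scaled. A single-filter bank is a degenerate case
and passes through. β defaults to 1.5; `grid_search_beta` scans
{1.1, …, 2.0} and breaks ties toward the smaller β.

Feature maps are rendered as images by optional log compression,
per-image min-max normalization (a constant map renders as zeros; the
output is invariant to positive affine rescaling of the input), bilinear
resize (align-corners) to 224×224 by default, and replication to three
channels. Channel replication rather than a colormap is a documented
choice.

## Classifier

The backbone is the standard ConvNeXt-Tiny; the baseline 2-class build
has exactly 27,821,666 parameters, which matches the analytic per-layer
inventory also shipped in `nn.zoo` (the zoo additionally accounts
ResNet50, Swin-T and MobileNetV3-Large, whose 1000-class totals reproduce
the canonical ImageNet counts).

Modifications, with placements chosen where the block descriptions leave
them open:

- **AKConv** replaces the 7×7 depthwise convolution inside *every*
  Stage-2 block (a minimal, resolution-preserving intervention; stride is
  fixed at 1). The initial sampling layout fills a regular grid of
  `floor(sqrt(n))` columns row by row and appends the remainder on the
  next row, anchored at (0, 0); n = 3 therefore gives a 3×1 column. A 3×3
  convolution with zero-initialized weights predicts 2N per-position
  offsets and its parameters carry a 0.1 learning-rate multiplier;
  resampling is bilinear with zero padding outside the map; the N sampled
  values are mixed by a pointwise convolution, channel-LayerNormed, and
  passed through SiLU.
- **CBAM** is inserted once, on the Stage-3 output. The shared channel
  MLP uses reduction 16 with a ReLU between the two (bias-free) layers —
  the standard CBAM construction — and the spatial stage is a bias-free
  7×7 convolution on the channel-wise average/max maps. With all weights
  zero both gates are σ(0) = 0.5 and the block is exactly a 0.25×
  passthrough, which is frozen as a test.
- **ConvMod** is appended once after Stage 4 at dim 768: LayerNorm, a
  1×1 → GELU → 11×11 depthwise (padding 5) attention branch multiplying a
  1×1 value branch, a 1×1 projection, and a residual connection. Zeroing
  the value branch reduces the block to the identity.

These placements put the improved model at 30.04 M parameters, above the
27.82 M baseline; the exact insertion points trade off against the
parameter budget and are the main architectural degrees of freedom left
open by the block descriptions.

The `nn` package is a self-contained float64 numpy autograd engine
(broadcast arithmetic, grouped conv2d via sliding windows, differentiable
bilinear grid sampling, LayerNorm, SiLU/GELU/ReLU/sigmoid, fused
softmax-cross-entropy, AdamW with decoupled weight decay and
per-parameter learning-rate scaling). Backward passes are verified against
central differences, and each block against a brute-force transcription
oracle on ≤8×8×8 tensors at 1e-6 relative tolerance.

## Evaluation harness

Metrics are the standard confusion-matrix formulas in percent; a
denominator-free metric is reported as `None`, never silently zero. The
95% CI resamples *patients* with replacement (B = 1000, seed 42 by
default) and takes 2.5/97.5 percentiles of the patient-mean accuracy —
bootstrapping the patient mean rather than pooled segments is a documented
choice. Majority voting resolves exact ties toward the positive class.
SNR mixing scales the (looped-if-short, seeded offset) noise so the
post-mix SNR matches the target exactly; silent inputs are rejected
because the ratio is undefined. Cross-validation folds are patient-level;
variant comparison uses the two-sided Wilcoxon signed-rank test with the
classical drop-zeros convention (all-tied inputs return p = 1 rather than
an error).

Training defaults mirror the reference protocol (batch 32, AdamW, lr
2e-4, weight decay 0.05, cross-entropy); the `experiments` module runs the
full pipeline at reduced scale — 12 patients, 6+6 segments each, 32×32 Mel
images, a (8, 16, 32, 64) × (1, 1, 1, 1) improved model, 10 epochs — which
reaches 100% held-out patient-level accuracy on the spectrally separable
synthetic cohort in ~20 s of CPU time. Problem sizes here were chosen as
the smallest at which the classification task and all three added blocks
are meaningfully exercised.

## Statistics

LFER integrates a Welch PSD (Hamming, 2048-sample segments, 50% overlap,
trapezoidal rule) over [0, 650) Hz against [0, Nyquist]; it is
scale-invariant and undefined (raises) for silent segments. Patient
summaries are medians over that patient's snore segments/events only,
with event counts normalized to an 8-h night.

The Mann-Whitney implementation reports U of the stenotic group, a
Z statistic with mid-rank tie correction and continuity correction (so
Z is signed: negative when the stenotic group ranks lower), and a
two-sided p: exact, by dynamic-programming enumeration of the rank-sum
distribution, when min(n) ≤ 8 and there are no ties; otherwise the normal
approximation. The exact and approximate routes agree within 0.02 at
n = 8 vs 8, and the implementation is cross-checked against
`scipy.stats.mannwhitneyu` in tests (scipy is the oracle, never the
implementation). The sensitivity analysis re-runs the identical pipeline
on the cohort minus flagged patients and errors if a group empties.
t-test and χ²/Fisher utilities for demographic tables are thin scipy
wrappers.

## Known limitations

- The numpy engine is for correctness and desk-scale experiments; it is
  orders of magnitude slower than a GPU framework, so full-resolution
  (224×224, 27.8 M-parameter) *training* is out of scope — only
  construction, forward passes and parameter accounting run at full size.
- The CQT is a frame-based filter-bank approximation; it preserves the
  constant-Q geometry but not the per-bin adaptive window lengths of a
  true multi-rate CQT.
- Endpoint detection is energy-based and untuned for heavily non-stationary
  noise floors.
- Synthetic cohorts encode group contrasts by construction; rejection
  rates measured on them validate the statistical machinery, not clinical
  effect sizes.
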