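# Methods

## EEG differential-entropy features

A trial is a 63-s, 32-channel recording at 128 Hz: 3 s of preparation
followed by a 60-s task span. Each channel is band-passed into theta
(4–7 Hz), alpha (8–13 Hz), beta (14–30 Hz) and gamma (31–45 Hz); the gamma
upper edge is capped at 45 Hz because the recordings this pipeline targets
are band-limited to 4–45 Hz by the acquisition preprocessing. The filter
is a zero-phase Butterworth band-pass of order 8 (`scipy.signal.sosfiltfilt`).
Order 8 was chosen over lower orders because the package asserts that each
band's captured power tracks a rectangular periodogram integral to within
10%; at order 4 the transition bands of the 3-Hz-wide theta band leak
~12% of its nominal power.

Differential entropy per non-overlapping 0.5-s window uses the Gaussian
closed form `h = ½ ln(2πeσ̂²)` in natural log (the only base for which
that closed form holds; the base is exposed as a parameter). `σ̂²` is the
unbiased (n−1) sample variance. A zero-variance window would have
`h = −∞`; it returns a configurable floor (−20 nats) with a warning.

The six 0.5-s windows of the preparation span give a per-channel,
per-band baseline DE (their mean), subtracted from every task window to
remove resting-state bias. Corrected DE vectors are scattered onto an 8×9
scalp grid (bundled 32-channel layout; 40 of 72 cells carry no electrode
and stay exactly zero), bands are stacked, and six consecutive windows
(3 s) are grouped without overlap into one `(6, 4, 8, 9)` sample — 20
samples per 60-s task span, 1728 values each. Windowing is a strict
ordered partition; the whole pipeline is deterministic.

## Face branch (MSDAC)

Input: grayscale crops in [0, 1], 48×48 by default (any size ≥ 24 whose
side is divisible by 8 works; a center-crop preprocessor handles larger
frames). Architecture: two conv blocks (3×3 conv + batch-norm + ReLU +
2×2 max-pool) → a three-branch multi-scale dilated convolution module
(3×3 kernels at dilations 1, 2, 3 with padding = dilation, concatenated
along channels) → a dual-branch attention module → one more conv block →
a two-layer classifier with dropout 0.2 after its first layer.

The three dilations give receptive spans 3, 5 and 7 at identical
parameter cost (span = 2d+1 for a 3×3 kernel), matching the spatial
statistics of facial action units: compact cues (lip corners) versus
widely separated ones (brow + mouth coactivation). The attention module
runs channel attention (global average pool → two FC layers → sigmoid
gate) and spatial attention (channel-mean map → 1×1 conv → sigmoid gate)
in parallel and fuses their outputs element-wise; sum is the default,
average is available. The channel gate ends in a sigmoid as well — a
multiplicative gate must be bounded. The composition of a "conv block"
and the parallel (rather than sequential) reading of the two attention
branches were open design points; both choices are the simplest
consistent ones and are isolated behind the `MSDACConfig` surface.

Stem and branch widths default to 32→64 stem, 64 per branch. These widths
are a declared default, not derived from any published parameter total.
Ablations: `MSAC` replaces the dilated branches by receptive-field-matched
standard 3×3/5×5/7×7 kernels (per-branch weight ratio 49:9 for the span-7
branch, hence strictly more parameters at equal widths); `WO_DBA` removes
the attention module; `WO_DBA_MSDC` also collapses the branches to one
standard convolution.

## EEG branch classifier

Input `(6, 4, 8, 9)`. A band-preserving 3×3 convolution is applied per
time step, then two single-layer, 4-head transformer encoders with
embedding width 72: *spectral* attention treats the 4 band maps of a step
as tokens (each the flattened 72-dim grid), *spatial* attention treats
the 72 grid cells as tokens (their 4-dim band profiles linearly embedded
to 72 and projected back). They run sequentially, spectral first. No
positional encoding is added; spatial identity is carried by token order.
Temporal attention assigns each step a non-negative scalar (linear
projection → ReLU), normalised to sum to one; a zero-weight step
contributes a zero block. The weighted steps are kept and flattened —
not summed — so the classifier input stays 1728-dimensional, which is the
deliberate resolution of describing the temporal stage both as a
"weighted summation" and as feeding a 1728-dim fully-connected layer:
per-step weighting honours both the weighting and the printed dimension.
Dropout 0.5 precedes the final FC + softmax.

## Self-learning decision fusion

Inputs are the per-sample probability rows of the two branches,
concatenated to width 2D (EEG columns first). Four affine+GELU layers
expand 2D → 16 → 32 → 64 → 64; the widths are architecture constants (a
description of them as N-dependent is treated as a typo), with L = 8
tokens of E = 8 dims, n = 4 heads, d_k = 2, all exposed in
`FusionConfig`. The token sequence passes scaled dot-product multi-head
self-attention (per-head V, i.e. V_h), is flattened, and a final affine +
softmax returns fused class probabilities. Baselines: the convex
combination `k·X_E + (1−k)·X_F` with k grid-searched over {0, 0.1, …, 1}
on labelled validation decisions, and a feature-level head (two FC layers
over concatenated penultimate branch features).

**Modality dropout.** During fusion training each sample may have one
modality's row replaced by the uniform distribution (uniform, not zeros,
so the simplex invariant survives). The contract is: each modality is
dropped with probability exactly p and never both for one sample. Those
two requirements are only jointly satisfiable for p ≤ 0.5 (expected drops
per sample is 2p), so drops are drawn mutually exclusively from one
uniform variable per sample; p > 0.5 is rejected. An
independent-then-redraw scheme would bias the marginal rate to p/(1+p)
(0.0909 at p = 0.1) and was rejected for that reason.

## Training protocol

Adam + cross-entropy throughout. Branch learning rate 5e-4; fusion 1e-4,
batch 32, 20 epochs with modality dropout p = 0.1. Batch sizes: 128
(face), 32 (EEG). Branch epoch count is not externally fixed; default 30,
always overridable. Evaluation is subject-dependent: stratified five-fold
cross-validation within each subject (stratification prevents
single-class training splits on small runs), per-subject mean/std
accuracy, unweighted mean across subjects. The paired t-test on per-fold
accuracies is two-sided; zero-variance differences return p = 1 with a
warning rather than an undefined statistic. For fusion, each 3-s EEG
sample is paired with the face frame at its final 0.5-s step (a center
pairing is available).

## Numpy autodiff core

`msdafuse.nn` is a small tape-based reverse-mode engine (broadcasting
arithmetic, batched matmul, dilated conv2d via explicit tap gathering,
max-pool, batch-norm, layer-norm, softmax/log-softmax, GELU in the tanh
approximation, Adam). Every operator's gradient is checked against
central finite differences in `tests/test_nn_core.py`. Float64 is used
throughout; models at the scales in this package train in seconds to
minutes on one CPU.

## Synthetic data: what it emulates, what it does not

The generators reproduce the acquisition *protocol* (trial structure,
sampling rates, frame cadence: 8064 time points per trial, 120 frames per
trial, 4800 per subject, 105,600 across 22 subjects) and a controllable
class structure:

* **EEG** — pink (1/f) background noise, so band-pass filtering is
  consequential, plus a band-limited oscillation on every channel; class 1
  multiplies the oscillation amplitude on four designated channels by 2.5
  during the task span only (the preparation span never carries the class
  effect, keeping baseline correction class-neutral). The oscillation is
  synthesised 2 Hz inside the nominal band edges so its power does not
  straddle the boundary shared with neighbouring bands; the class effect
  is statistically invisible outside the designated band.
* **Faces** — class 0 is one compact bright Gaussian blob (σ = 3 px), a
  local-scale cue; class 1 is two dimmer blobs ≥ 24 px apart, a long-range
  cue that small receptive fields cannot relate; pixel noise sd 0.08,
  clipped to [0, 1].
* **Decisions** — per sample one modality is "reliable" (confident,
  correct with probability 0.98) and the other weakly informative, with
  the weak accuracy set so each modality's marginal accuracy is 0.85; a
  modality reliable on a zero fraction emits uniform rows. An oracle that
  trusts the reliable modality attains 0.98 — the complementary regime
  learned fusion is designed for.

None of this emulates real EEG morphology (no 1/f slope variation,
artifacts, inter-subject variability) or real face appearance. Passing
tests therefore demonstrate that the *mechanisms* work — that the DE
pipeline recovers injected band-power structure, that multi-scale
branches exploit scale cues, that learned fusion recovers complementary
reliability — not that published benchmark accuracies transfer.

## Problem sizes and determinism

Tests and the acceptance script run scaled-down experiments chosen for
single-CPU execution: the fusion benchmark uses 1200 training / 800 test
decision pairs; the face training check uses 600 48×48 frames for 25
epochs; the EEG training check uses 240 samples (24 trials at a 30-s task
span) for 8 epochs; the end-to-end pipeline smoke uses 2 subjects × 6
short trials. Every random draw flows from an explicit seed; identical
seeds give bit-identical datasets and training histories.

## Known limitations

* Layer widths of the face stem are declared, not derived; absolute
  parameter totals are therefore not comparable to any published totals —
  only the dilated-vs-standard direction is asserted.
* The fusion benchmark's fixed-weight baseline is strong by construction
  (confidence averaging nearly implements the oracle), so self-learning
  fusion typically ties rather than beats it there; its advantage is the
  learned per-sample weighting, which the graceful-degradation test
  (one modality uniform) exercises.
* Subject-dependent evaluation only; leave-one-subject-out is out of scope.
* No calibration of fused probabilities.
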