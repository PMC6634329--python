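# Methods

This note records the models, conventions and numerical choices behind
`pupiltag`, in the order the data flow through the pipeline.

## Experimental design being analyzed

Dichoptic presentation of two images whose luminance is modulated
sinusoidally at *f* = 1.7 Hz between half and full image luminance
(`L(t) = 0.5 + 0.25·(sin(2πft + φ) + 1)`), with the right eye's modulation
shifted by Δφ ∈ {0°, 90°, 180°} relative to the left (left eye leading).
One presentation cycle is 1/f = 588 ms — 50 frames at the 85 Hz display
refresh this frequency was chosen to divide. Displayed pixel values are
the luminance fraction raised to 1/γ (γ = 2.26) so the modulation is
sinusoidal in physical luminance rather than in pixel value
(`gamma_corrected_multiplier`). Observers hold one button per image while
that image is exclusively dominant, both buttons during mixed percepts.

Blocks are 300 s sampled at 1000 Hz. The canonical seven-block session
(`SESSION_CONDITION_ORDER`) is: static, 180° naive, 90° naive, 0° control,
180° attention-instruction, 90° attention-instruction, static, with the
image-to-eye assignment alternating every block.

## Synthetic sessions

The generator produces exactly the statistical structure the analysis
assumes, nothing more:

- **Dominance durations** are gamma distributed — the standard
  description of rivalry phase durations — with shape 3.5 and scale set so
  the median is 2.7 s (the order observed for face/house rivalry). The
  shape is a modelling choice; only the median is treated as calibrated.
- **Mixed-percept interludes** between exclusive periods are exponential,
  with mean chosen so MIXED occupies 29% of the block in expectation.
  Unreported ("none") periods, ~3.5% of time in practice, are not
  simulated separately; the reported stream begins with a NONE stretch of
  one report lag.
- **Reports** are the ground-truth timeline shifted by a constant 400 ms
  button lag. Real report latencies are variable; a constant lag is the
  simplest model that exercises the (deliberate) absence of latency
  correction in the analysis.
- **Pupil**: `pupil(t) = baseline − gain·[w_L(t)·L_left(t−δ) +
  w_R(t)·L_right(t−δ)] + drift(t) + ε(t)` with the dominant eye at weight
  `w_dom` (default 0.9), the suppressed at `1 − w_dom`, both 0.5 during
  mixed/none. The response is inverted (dimmer stimulus → larger pupil)
  and delayed by δ = 400 ms. No physiological low-pass filtering or
  amplitude adaptation is modelled: the analysis relies only on phase
  consistency, so a linear fixed-delay response is sufficient and keeps
  the noise-free oscillation amplitude exactly equal to the analytic
  mixture model `|w + (1−w)e^{iΔφ}|` (shared closed form, tested).
  The 400 ms delay is a modelling choice of the same order as the button
  lag; no empirical latency estimate is assumed.
- **Noise**: drift is a Gaussian random walk low-pass filtered at 0.2 Hz
  and scaled to SD 100 raw units; measurement noise is white with SD 20.
  With `baseline = 2000` and `gain = 150` (single-source oscillation
  amplitude 37.5), the induced oscillation is clearly visible in the
  z-scored trace — as it is in real recordings of this paradigm — and
  white noise sits near 1% of pupil size, typical of video-based
  eye trackers at 1000 Hz. The defaults were set on these realism grounds.
- **Blinks** arrive as a Poisson process (0.25 Hz), produce gaps of
  exponentially distributed duration (mean 150 ms, floor 50 ms) with
  missing samples, and are flanked by 60 ms spike artifacts of ±10
  trace-SD whose sign alternates sample to sample. The alternation
  matters: the artifact being emulated is a *rapid apparent change* in
  pupil size, and a change-rate detector can only see artifacts that
  actually change fast. These spikes guarantee the 5-SD rule has true
  positives to find.

What the generator does **not** emulate: neural rivalry dynamics
(adaptation, mutual inhibition, return transitions), gaze-dependent pupil
foreshortening, saccades, variable report latency, pupil low-pass
dynamics, image rendering. Passing tests therefore show that the pipeline
recovers what it assumes from data with realistic nuisance structure —
not that those assumptions hold in any particular real dataset.

## Preprocessing

Order: change-rate rejection → blink padding → interpolation →
z-standardization. No samples are deleted; cleaning only toggles the
validity mask and fills values, so output length always equals input
length.

- **Change-rate rule**: first differences `d_i = x_{i+1} − x_i` over
  consecutive valid pairs; sample *i* is invalidated when `|d_i|` exceeds
  5 SD of the block's change rate. Single pass with the threshold fixed
  up front (deterministic); the earlier member of an offending pair is
  rejected, and the later member too when it begins an offending pair of
  its own. The SD is estimated excluding pairs within 50 ms of a
  blink-flagged sample: that neighborhood is known-contaminated (the
  padding rule discards it anyway), and letting flanking artifacts into
  the estimate inflates the very threshold meant to catch them — with
  dense blinks the rule can otherwise fail entirely, since N alternating
  spikes contribute ≈ √f·(spike step) to the SD at spike fraction f.
- **Padding**: every invalid run touching a blink flag is extended by
  50 ms on each side (clipped at block edges). Rate-rejection runs of at
  least 10 ms are padded too (residual artifacts of that size behave like
  blinks); isolated single-sample rejections are not.
- **Interpolation** is cubic and gap-local: each interior gap is bridged
  by a spline through up to four anchor samples per side, spaced a
  quarter of the gap length apart. A spline forced through *every* raw
  sample is exact on clean data but catastrophically noise-amplifying
  across gaps of a few hundred ms (its edge slope is set by adjacent
  noisy samples; measured amplification ~100×), so the local scheme is
  used: it reproduces cubic polynomials exactly, reconstructs a 100 ms
  gap in a noise-free modulation cycle to <0.1% of amplitude, and stays
  bounded by the scale of the surrounding data under noise. Leading and
  trailing invalid runs are filled by nearest-valid constant extension.
  The validity mask is preserved so each cycle's interpolated fraction is
  known downstream.
- **Z-standardization** is over all samples of the block (mean 0, SD 1,
  population SD), after interpolation. A zero-variance block is a hard
  error. Z-scoring is idempotent and affine-invariant.

## Cycle segmentation and the F1 component

The cycle length in samples is fractional (1000/1.7 = 588.235). Windows
are realized as fixed N = round(1000/1.7) = 588 samples, with the onset of
cycle *k* re-anchored at `round(k·1000/1.7)` — alignment error never
exceeds half a sample and does not accumulate. The trailing partial cycle
is dropped; a 300 s block yields 510 cycles. Windows are aligned so each
contains one period of the left-eye modulation sinusoid starting at −90°
(its minimum).

A cycle is labelled LEFT_EYE/RIGHT_EYE only when reported exclusive
dominance of that eye covers the entire window (equivalently: every
sample in the window carries that label); anything else — switches, mixed
percepts, unreported stretches — is EXCLUDED and never enters statistics.
No latency correction is applied to windows or labels: pupil delay and
button lag are of the same order and partially cancel. Cycles dominated
by interpolation are flagged via `frac_interpolated` but not excluded by
default.

The F1 component is the exact sine/cosine projection at one cycle per
window, computed through the FFT bin-1 fast path:
`Z = (2/N)·conj(FFT(x)[1])`, fixed by two convention-defining identities
— a unit reference-phase sine maps to Z = +i, a unit cosine to Z = +1 —
so Im(Z) > 0 means "in phase with the left-eye reference sinusoid". Under
this convention a forward time shift of the signal by Δt rotates Z by
−2πfΔt (exact at the realized analysis frequency 1000/588 Hz).
`|Z| ≤ √(2·mean(x²))` for any input.

## Decoding

- **Group phase statistic**: per subject and condition, the complex mean
  of Z over left-eye-reported and over right-eye-reported cycles; the
  imaginary parts are compared with a two-sided paired t-test. Averaging
  precedes the test (cycle-level pooling is available but not default).
- **Effect sizes**: `d_s` divides the mean difference by the pooled SD of
  the two observation sets — the convention this pipeline reproduces for
  paired designs — and the standard paired `d_z = t/√n` is reported
  alongside.
- **ROC/AUC**: per-cycle scores (default Im(Z)), positive class
  RIGHT_EYE, threshold sweep over all distinct scores, trapezoidal area,
  ties at half weight — identical to the Mann–Whitney U statistic scaled
  to [0, 1] (oracle-tested). Per-cycle rather than per-mean scores feed
  the ROC, since classification is defined cycle by cycle.
- **Optimal rotation**: scores `Im(Z·e^(−iθ))` for θ ∈ [0°, 180°) in 1°
  steps, with orientation folding `max(AUC, 1 − AUC)` per angle — because
  AUC(θ+180°) = 1 − AUC(θ), the half-circle search with folding equals
  scanning all rotations and keeping the maximum. Ties break to the
  smallest θ. This is a selective (optimistic) estimate by construction:
  even the in-phase control's folded optimum sits visibly above 0.5.
- **Group vs chance**: two-sided one-sample t of per-subject AUCs
  against 0.5, per condition. Subjects lacking a percept class in a
  condition are reported as missing, never as zero, and skipped in group
  tests.

## Behavioral statistics

Exclusive-dominance intervals are mapped from eye to stimulus type
(face/house) through each block's eye assignment. Summaries are per
subject × condition × stimulus type: median exclusive duration (empty
cells propagate as missing, not zero) and time proportions
(exclusive/mixed/none, which sum to 1 per block).

The 2 × 7 repeated-measures ANOVA uses the classical fully-within
decomposition, each effect tested against its own interaction-with-
subjects error term, uncorrected df (no sphericity correction; a future
flag may add Greenhouse–Geisser). Generalized eta-squared follows
Olejnik–Algina for a fully within design:
`η²_G = SS_effect / (SS_effect + SS_subjects + SS_A×S + SS_B×S +
SS_A×B×S)`. The decomposition is implemented directly (the total-SS
identity is property-tested) because common library implementations of
two-way within ng² omit the subject SS from the denominator; an
independent implementation serves as the F/p oracle in the test suite.
Degenerate all-equal tables report F = 0, p = 1.

Attention-instruction blocks are scored by the fraction of instructed
time the target image was *part of* the percept (its eye exclusive, or
MIXED) — the instructed image need not be exclusively dominant. This is
one reading of "not necessarily exclusive perception"; counting MIXED
fully toward both images is the corresponding simplification.

**Sensitivity analysis**: the smallest d with
`P(|T_{df=n−1, ncp=d√n}| > t_crit(α, n−1)) ≥ power`, solved with Brent's
method on the noncentral-t power function to a tolerance of 1e-6.
For n = 12, α = .05: d = 0.8887 at power
.80 and d = 1.1460 at power .95. scipy's noncentral-t CDF underflows to
NaN deep in the negligible lower rejection tail; the power function
treats non-finite tail values as 0/1.

## Numerical and interface conventions

- Time is integer milliseconds from block onset; intervals are half-open
  `[onset, offset)` — no double-counted boundary samples.
- Simultaneous button events: releases before presses, so a clean switch
  never creates a zero-length MIXED interval. Zero-length report
  intervals are dropped.
- Missing samples: empty cells and NaN accepted on read, written as empty
  cells; blink and validity flags travel as explicit columns so disk
  round-trips preserve every field at the printed precision (6 decimals).
- All randomness flows from `numpy.random.Generator` seeds; identical
  seed and parameters give byte-identical sessions. Multi-subject runs
  use substreams keyed by (seed, subject, condition).
- Test and demonstration runs use scaled-down problem sizes (60–120 s
  blocks, 4–6 subjects) chosen to keep the suite quick; the full-scale
  parameter-recovery checks in `tests/test_acceptance.py` use the
  study-sized design (12 subjects, 300 s blocks).

## Known limitations

- The generator's percept weight `w_dom` is constant within a session;
  real percept-to-pupil coupling fluctuates, so real-data AUCs are far
  lower than synthetic ones at these defaults.
- The constant report lag makes label misalignment systematic rather
  than jittered; decoding on real data degrades differently (more
  EXCLUDED cycles near switches).
- The attention-instruction model (duration scaling of the attended
  image) captures the direction of attentional dominance effects, not
  their mechanism.
- Edge gaps are filled by constant extension; the first/last cycles of a
  heavily blink-contaminated block are accordingly conservative.
- `optimal_rotation` is selection-biased upward by design (it is an upper
  bound, not an unbiased estimate); cross-validation is out of scope.
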