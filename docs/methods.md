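# Methods

## Problem setting

`painfnirs` implements a complete analysis chain for recognising four
thermal-pain conditions — Low-Cold (1), Low-Heat (2), High-Cold (3),
High-Heat (4), i.e. modality x intensity — from multi-channel fNIRS
oxyhaemoglobin (HbO) recordings sampled at 10 Hz. Because no public
recordings accompany the protocol, the package ships a synthetic-data
generator that reproduces the statistical structure the analysis assumes,
and the whole chain is validated on that generator plus analytic fixtures.

The task-relevant haemodynamics live in two low-frequency bands: VLFO
(0.01–0.08 Hz) and LFO (0.08–0.15 Hz). Everything downstream — the filter
cutoff, the two feature-grid designs, the band summaries — is organised
around this band structure.

## Synthetic-data generator

Each subject's recording is a 60-s rest baseline followed by 12 randomised
trials (3 per class), each a 90-s stimulation window plus 30 s rest.  Every
channel is a sum of:

* **Systemic physiology**, shared across channels with per-channel gains
  ~N(1, 0.2): cardiac (1.25 Hz), respiratory (0.3 Hz) and Mayer-wave
  (0.1 Hz) sinusoids with random phases, plus a linear drift.
* **Event-locked activation**: a double-gamma-difference kernel (initial
  dip ≈ −0.15 of the peak at a third of the peak latency; single maximum at
  the class's latency; decay to baseline).  The per-trial amplitude is
  `class amplitude x subject gain x lognormal(σ=0.1)` trial jitter, with the
  subject gain `exp(N(0, subject_effect_sigma))` shared by all of a
  subject's trials.
* **Class-dependent narrowband oscillations**: cold classes carry extra
  VLFO-band power, heat classes extra LFO-band power; high-pain classes
  carry roughly double the low-pain band power, an upward-shifted
  within-band peak frequency, and a shorter HRF latency (stronger stimuli
  evoke faster, larger responses).  Latency and peak frequency are
  gain-invariant, so the intensity contrast survives between-subject gain
  variability that scales all amplitudes of a held-out subject.  A Tukey
  taper (α = 0.2) confines the oscillation to the stimulation window
  without step edges.
* **Noise**: white Gaussian noise (σ = 0.1) and Poisson-placed motion
  artifacts (sharp 1-s spike plus a 20-s decaying step, amplitude ≫
  signal), per channel.

Activation (HRF and oscillation) gains are **spatially localized**: a random
half of the channels are responsive (gain ≈ 1.2), the rest nearly silent
(≈ 0.15).  This mirrors localized cortical pain processing under a
whole-head montage and is what makes rest-referenced PCA meaningful — the
systemic pattern (all channels ≈ 1) and the activation pattern span
different directions of channel space.

Class effect sizes are free parameters of the generator (nothing in the
source protocol quantifies them).  The defaults encode intensity both in
amplitude (gain-sensitive) and in within-band peak position and latency
(gain-invariant), so that subject-level gain variability does not erase the
intensity contrast.  Determinism: each subject's stream is seeded by
`SeedSequence([master_seed, subject_index])`, so any output is a pure
function of the configuration.

What the generator does **not** emulate: optical physics (no Beer–Lambert
or photon-transport model), HbR, spatially smooth channel covariance from
shared optodes, non-stationary vigilance drifts, or serially correlated
physiological noise.  Passing tests on this generator therefore demonstrate
correctness of the pipeline's computations and protocol, not expected
accuracy on real cortical data.

## Preprocessing

Fixed order: FIR low-pass → wavelet de-noising → rest-referenced PCA.

* **FIR low-pass, 0.16 Hz cutoff.**  Two modes.  `nominal` uses
  `fir_order + 1 = 5` taps, honouring the minimal fourth-order description
  this chain descends from; at fs = 10 Hz such a short window filter cannot
  meaningfully attenuate the 1.25 Hz cardiac line (its response is nearly
  flat), so the pipeline driver defaults to `effective` mode: a Hamming
  window design with ~`3 fs / cutoff` (189) taps, giving < 2·10⁻⁵ residual
  gain at 1.25 Hz while passing 0.05 Hz at ≈ 0.999.  Both modes are
  linear-phase and applied with group-delay compensation over
  reflection-padded edges, so epoch-locked features are not time-shifted.
  Whether the original description meant a 5-tap FIR or a loosely-described
  4th-order IIR is unresolved; both readings stay available and neither is
  asserted.
* **Wavelet de-noising** (motion artifacts): 5-level `sym8` DWT; within
  each detail level, coefficients farther than 1.5 x IQR from the level
  median are zeroed; the approximation band is untouched.  On a 0.05 Hz
  sinusoid with a 10-σ spike this removes ≳ 95 % of the spike while
  changing the sinusoid RMS by < 0.1 %.
* **PCA systemic removal**: principal axes are fitted on the pre-stimulus
  rest segment (channels as variables, mean-centred); the smallest leading
  set of components reaching 80 % cumulative rest variance is projected out
  of the whole recording (channel means restored).  The component count is
  data-driven and logged per subject; a threshold > 1 switches the stage
  off.  Fitting is per subject (rest data are per subject); a cross-subject
  fit would be an alternative reading.  Note the failure mode when the
  channel count is small: isotropic noise flattens the rest eigenspectrum
  and the cumulative threshold can consume a large fraction of channel
  space.  With 12–24 channels the stage removes 2–4 components.

## Feature extraction (69 features)

Per (trial, channel) epoch of 900 samples (90 s at 10 Hz):

* **Time (9)**: mean, variance (N−1), skewness and kurtosis (1/(N−1)
  normalisation, sample σ; kurtosis raw, not excess; both 0 by convention
  on a zero-variance epoch), peak, least-squares slope (units/s, fitted
  with an intercept so a baseline offset cannot bias it), trapezoidal AUC,
  RMS, time-to-first-peak (s).
* **Frequency (23)**: magnitudes of the DFT of the mean-removed epoch at
  bins 1..15 of the Δf = 1/90 Hz grid.  The 90-s epoch is chosen exactly so
  that this grid lands on the reference per-bin frequencies (bin 11 →
  0.122 Hz); bins 1–8 form the VLFO group and 9–15 the LFO group (bin 8,
  0.0889 Hz, is nominally above the 0.08 Hz edge but stays in VLFO to keep
  the fixed 8 + 7 split).  Per band: mean |F|, variance of |F| (the
  "variance of the energy spectrum" prose reading — variance of |F|² — was
  rejected in favour of the coefficient-variance table reading), maximum
  energy |F|², and its frequency.  Mean removal prevents DC leakage into
  bin 1.  Ties in argmax go to the lowest frequency.
* **Wavelet (37)**: complex Morlet (ω₀ = 6) CWT at 30 scales on a
  10-voice-per-octave geometric grid from f_top = 0.1492 Hz downwards — the
  unique geometric grid consistent with all five reference per-scale
  frequencies (0.113, 0.0746, 0.0373, 0.0283, 0.0214 Hz).  Scales 1–9 form
  the LFO group, 10–30 the VLFO group.  Per scale, the feature is the
  time-mean of |W| (the collapse along time is unspecified upstream; the
  mean is the stable choice).  Per band: mean of the per-scale means,
  variance of all |coefficients|, summed power Σ|W|², and the absolute
  difference of the two band means (AMR).  Edge effects of the finite epoch
  are accepted (no padding); at the deepest scales the kernel exceeds the
  epoch and the response is attenuated equally for all classes.

The CWT is computed by FFT convolution of the sampled Morlet kernel
(truncated at |u| ≤ 4 envelope widths), batched over epochs and streamed
scale-by-scale; it is cross-checked in the tests against PyWavelets' `cmor`
implementation (proportional profiles over the upper half of the scale
grid, where pywt's fixed-resolution integrated-wavelet table is accurate).

## Feature ranking

Continuous features are discretized equal-frequency into 10 bins (edges at
empirical quantiles, duplicates merged); the bin count and strategy are
package choices — nothing upstream specifies them.  Mutual information is
the plug-in estimator in bits.

* **IG**: I(feature; label), descending.
* **χ²**: Pearson statistic of the bins x classes table, no correction.
* **JMI**: greedy forward; first pick maximises I(f; Y), later picks
  maximise Σ_{s ∈ selected} I((f, s); Y) with jointly-coded pairs.  This
  accumulation-sum form is the standard formulation of the criterion.

All rankings are deterministic and row-permutation invariant; ties break by
canonical feature order.  During evaluation, discretization and ranking are
fitted on training subjects only (leakage-safe).  Whether the original
analysis ranked on the full dataset or on training folds is unknown; the
leakage-safe choice is the defensible one but can shift curves relative to
a full-data ranking.

## Evaluation protocol

Subjects are split 13 train / 5 validation uniformly at random (seeded).
Hyperparameters are selected by leave-one-subject-out CV across the 13
training subjects — 13 folds, one per subject (an upstream description
says "repeated 12 times", which is inconsistent with its own 12-of-13
fold arithmetic; 13 folds is the consistent reading).  Features are
z-scored with fold-train statistics; grids: K = 1..20 for K-NN, C in
{0.1, 1, 10, 100} for all SVMs, gamma in {0.001, 0.01, 0.1, 1} for RBF;
polynomial kernel degree fixed at 3 with variance-scaled gamma; all SVMs
one-vs-one.  Ties go to the simplest model.  The selected model is refit
on all training rows and scored per validation subject (correct/total over
that subject's trial x channel rows), reporting the mean across subjects.
Accuracy-vs-top-m curves rerun this whole procedure per m.

## Problem sizes used in tests and the acceptance script

The protocol-level checks run the generator at its default conditions (18
subjects, 3 trials/class, default effect sizes and noise) but simulate 12
of the 24 montage channels; channels are statistical replicates, so this
halves compute without changing the per-row signal structure.  The
accuracy-vs-m curve is evaluated at m ∈ {5, 13, 25, 40, 55, 69} rather
than all 69 sizes.  End-to-end determinism is checked on a miniature
configuration (6 subjects, 1 trial/class, 3 channels) since bit-identity
does not depend on scale.

## Known limitations

* Synthetic effect sizes are free parameters; absolute accuracies on this
  generator say nothing about accuracies attainable on real recordings.
* The plug-in MI estimator is biased upward at small n; fine for ranking
  (shared bias), unsuitable for absolute information estimates.
* The JMI greedy loop is O(m² · pairs) per dataset and becomes slow beyond
  a few hundred features.
* PCA removal deletes whole directions of channel space; with few channels
  it can remove substantial signal (see above).
* The biomarker preset is a named column subset; nothing in this package
  can confirm its clinical validity.
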