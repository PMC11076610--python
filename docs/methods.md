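# Methods

## The analysis this package implements

During a sustained static contraction, the surface-EMG power spectrum
compresses toward lower frequencies while the amplitude of the signal holds
or grows — the joint amplitude/spectrum (JASA) signature that distinguishes
muscle motor fatigue from a simple reduction in effort. The pipeline
quantifies this with the mean frequency (MNF) of the one-sided power
spectrum,

    MNF = Σᵢ fᵢ Pᵢ / Σᵢ Pᵢ,

computed from a single full-interval FFT (no window, no overlap), restricted
to the 20–400 Hz passband of the preprocessing filter. Each 90 s trial is
trimmed by 2 s at both ends and the remaining 86 s split into ten equal
intervals (37,582 samples at 4370 Hz), giving a ten-point MNF trajectory per
muscle. Fatigue is operationalized as a negative OLS slope of MNF against
time with a two-sided slope test p < 0.05.

Knee wobble is the Euclidean norm of the three accelerometer axes
("resultant acceleration") after a 4th-order, 10 Hz Butterworth lowpass.
Four per-interval summaries are taken: the maximum, the trapezoidal area
under the rectified curve (AUC), the sum of squared samples, and the
zero-cross rate — reported, following the protocol's definition, as the
*average time in seconds between successive zero crossings* of the demeaned
resultant (the raw resultant is non-negative and never crosses zero; the
demeaned reading is the only non-degenerate one).

All ten measures are normalized to the within-group maximum before
regression. "Inter-trial maximum" is ambiguous between within-trial,
within-subject and cohort-wide scopes; the default is per subject per
measure across all of that subject's trials and intervals (configurable via
`FeatureConfig.grouping`), which preserves between-trial growth within a
subject while removing between-subject scale.

## Statistical machinery

* **Interval regressions**: OLS of each normalized measure on interval index
  (1..10); slopes are also reported per second (×1/8.6) and, for MNF, as a
  relative slope in %/s computed from the raw MNF against the interval
  midpoint time (slope/intercept × 100), the unit in which fatigue slopes
  are conventionally compared.
* **First-vs-last comparisons**: paired two-tailed t-tests across trials.
  Identical paired vectors return t = 0, p = 1 by convention; zero-variance
  non-zero differences raise a degenerate-input error.
* **Slope ANOVAs**: one-way ANOVA across muscles and across activities, with
  unadjusted pairwise t-tests as the follow-up (a Tukey HSD option exists
  but is off by default, matching the bare pairwise p-values the analysis
  reports). Numerically identical group means can produce a tiny negative F
  by cancellation; F is clamped to 0 and p computed from the F survival
  function.
* **Multivariate regression**: per trial, OLS of the summed (normalized, by
  default) three-muscle MNF on the four wobble measures; the per-trial R² is
  then summarized by the number of fatigue-responder muscles (0–3).
* **Stepwise selection**: forward selection with backward pruning,
  p-to-enter 0.05 and p-to-remove 0.10 (the common default of commercial
  stepwise implementations; the protocol states only the 0.05 significance
  level). The default orientation regresses *time on the four wobble
  measures* and calls a trial a wobble responder when at least one retained
  term has p < 0.05; the mirror orientation (each measure on time) is
  available via `stepwise_orientation`.

## The classifier

A 27-neighbor KNN with Chebyshev distance predicts "one or more fatigued
muscles" from the 40 acceleration features (4 measures × 10 intervals).
Within each stratified fold: NaNs (intervals with fewer than two zero
crossings) are imputed with training-fold medians; features are z-scored on
the training fold (the four measures have incommensurate scales, and the
Chebyshev metric otherwise reduces to whichever feature has the largest
spread); Kruskal–Wallis H ranks features and the 10 smallest-p features are
kept (the selection count is not dictated by the protocol; 10 of 40 is the
default and configurable). The asymmetric misclassification costs — 1 for a
false negative, 4 for a false positive — enter through the decision rule:
predict positive iff the positive vote fraction exceeds
c_fp/(c_fp+c_fn) = 0.8, ties to negative. When every selected training
feature is constant the neighbor set is an arbitrary tie, so the vote
fraction is defined as the training-class prior. Pooled confusion counts
over the five folds give the PPV and NPV.

## The synthetic-data generator

Raw recordings from the study are not deposited, so the pipeline runs on
synthetic cohorts with known ground truth.

**sEMG model.** Unit-RMS Gaussian noise lowpassed at `bandwidth/2` is
amplitude-modulated by the envelope `amp0·(1 + rel_amp_slope·t)` and mixed
up to a chirp carrier whose instantaneous frequency is
`center_freq0·(1 + rel_mnf_slope·t)`; broadband noise at `noise_floor` is
added. Because the modulated spectrum is symmetric about the carrier, the
programmed MNF *equals* the carrier frequency analytically — the drift is
exactly linear and exactly recoverable in expectation, which is what makes
parameter-recovery tests sharp. Defaults: 90 s at 4370 Hz, initial center
110 Hz, bandwidth 60 Hz, RMS 0.1 mV (a typical surface-EMG scale), envelope
growth +0.2 %/s (effort not decreasing, per the JASA requirement), noise
floor 2 µV. Responder slopes are drawn from −0.5 to −0.15 %/s, the range
reported for comparable static-exercise protocols.

**Accelerometer model.** Gravity (9.81 m/s²) on the z axis plus a circular
(quadrature) x–y tremor at 4 Hz — below the 10 Hz lowpass — whose amplitude
`tremor_amp0·(1 + rel_tremor_slope·t)` grows through the trial, plus
0.05 m/s² white noise per axis. The quadrature construction makes the
noise-free, constant-amplitude resultant exactly constant, so interval
measures respond only to programmed growth and noise. Default initial
tremor amplitude 0.8 m/s² is of the order of visible knee oscillation
during a strenuous static hold.

**Cohort structure.** 24 subjects × 5 activities = 120 trials. Each muscle
of each trial is independently a fatigue responder with probability 0.5
(non-responders get slope exactly 0). Wobble growth is coupled to fatigue:
the trial's tremor growth rate is the template rate scaled by
`0.2 + n_fatigued/3`, so trials with more fatigued muscles wobble more —
the structure behind the rising R²-by-responder-count pattern and the
high-PPV/low-NPV relationship between wobble and fatigue responders. All
per-trial, per-channel seeds derive from the master seed by counter
(`SeedSequence(master_seed, spawn_key=(trial, channel))`), so cohorts are
bit-reproducible.

**What the generator does not emulate**: motor-unit physiology (recruitment,
firing statistics, crosstalk between muscles), nonstationary effort
strategies (e.g. posture drift that reduces load), movement artifacts and
electrode noise spectra, multi-component tremor, or any force/torque
biomechanics. Passing recovery tests therefore demonstrates that the
*analysis chain* is correct and unbiased for signals obeying its model
assumptions — not that real recordings meet those assumptions.

## Numerical choices and degenerate inputs

* Filters are applied zero-phase (`sosfiltfilt`) to avoid phase distortion
  at interval boundaries; the stated orders (8th-order bandpass, 4th-order
  lowpass, −3 dB at the cutoffs) describe the single-pass design, on which
  the magnitude contract is tested. "8th order" is read as 8 poles, i.e. a
  4th-order prototype mapped to a bandpass.
* Axes are filtered first, then the resultant is taken: lowpassing the
  non-negative magnitude would bias its mean.
* `trim` rounds `head_s·fs` to the nearest integer sample;
  `segment` uses floor division and drops the remainder from the tail so
  intervals stay equal-length, as the single-FFT-per-interval procedure
  requires.
* AUC uses trapezoidal integration with dt = 1/fs.
* An interval with fewer than two zero crossings yields a missing (NaN) ZCR
  for that interval, not an exception; regressions drop missing rows and
  the classifier imputes them.
* Ten intervals is the default (86 s/8.6 s); the protocol text also
  mentions nine in places, and `n_intervals` is configurable.

## Problem sizes

Analysis drivers run the full study geometry (120 trials at 4370/370 Hz,
90 s; about 20 s of compute). The test suite exercises the same code mostly
on 30 s/1 kHz cohorts of 12–20 trials, with one full-scale 50-trial
recovery experiment (programmed slope −0.3 %/s, all-responder, low noise)
verifying that the mean fitted relative MNF slope lands within 15 % of the
programmed value and that trial-level responder sensitivity exceeds 95 %.

## Known limitations

* The trial-pooled regressions and ANOVAs treat trials as independent,
  ignoring the repeated-measures structure across a subject's five
  activities (no mixed-effects model).
* With the default low-noise accelerometer model, nearly every synthetic
  trial is detectable as a wobble responder, so the stepwise NPV is
  estimated from very few predicted negatives.
* The stepwise-selection p-values are post-selection and not corrected; the
  responder definition inherits this.
* MNF restricted to 20–400 Hz is mildly biased toward the band center when
  the broadband noise floor is large relative to the signal.
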