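# Methods

## Signal model and pipeline

The package estimates emotional valence from the prefrontal asymmetry of
EEG: the working hypothesis is that the left-vs-right imbalance between
the Fp1 and Fp2 sites carries valence information, and that a band-limited
variance/power feature of the difference signal `d = Fp1 − Fp2` is enough
to separate high- from low-valence trials within a subject.

The canonical trial geometry mirrors the common preprocessed benchmark
release: 40 trials per subject, 63 s at 128 Hz including a 3 s pre-trial
baseline, ratings on a continuous 1–9 scale. The baseline is discarded
outright (no baseline-statistic subtraction — a deliberate choice; some
pipelines subtract baseline means instead). Units are assumed microvolts
and never rescaled: every feature is scale-covariant and classification
z-scores per fold, so absolute calibration only affects reporting.

Differencing precedes band filtering. The two operations commute exactly
for linear filters, and differencing first halves the filtering cost;
the order is recorded in the band-signal provenance.

## Filters

Band separation uses 3rd-order Butterworth band-pass designs with −3 dB
points at the printed band edges (delta starts at 2 Hz, not 0.5 Hz).
Filters are applied forward–backward (zero phase), the standard choice
for offline EEG analysis: timing is preserved at the cost of squaring
the magnitude response. Coefficients are realized as cascaded
second-order sections; the narrow 2–4 Hz band at fs = 128 Hz is the
numerically worst case and remains stable in this form. Edge transients
are suppressed with scipy's default odd-reflection padding
(3·(2·n_sections+1) samples per side), which on 20 s slots is negligible
relative to the window length.

Two caveats are inherent to the band definitions and not compensated:
the gamma band's 60 Hz upper edge leaves almost no guard band before the
64 Hz Nyquist frequency of 128 Hz recordings, and adjacent bands share
their −3 dB edge, so a small fraction of narrow-band power appears in the
neighbouring band.

## Features

Per band and trial, five scalars:

* activity = population variance (1/N, not 1/(N−1) — this makes the
  Parseval identity with the power feature exact; at N = 7680 the
  distinction is immaterial);
* mobility = `sqrt(var(Δy)/var(y))` with Δ the unscaled first
  difference. The textbook definition uses a time derivative; the fs
  factor cancels in complexity and rescales mobility by a dataset-wide
  constant that fold-wise standardization removes, so the unscaled form
  is used and stated here so cross-implementation numbers match.
  Closed form for a sinusoid of frequency f: `2 sin(π f / fs)`.
* complexity = mobility of Δy over mobility of y (= 1 for a pure
  sinusoid). The Hjorth ratios are implemented with their square roots
  (the canonical definitions);
* zero-crossings = strict sign reversals, where a zero sample inherits
  the most recent nonzero sign (deterministic when sinusoids hit exact
  grid zeros; an all-zero signal has none);
* total power = `(1/N²) Σ|DFT|²` without windowing or mean removal —
  band-passed signals are zero-mean by construction, so the DC bin is
  negligible and the value equals the activity to float precision.

Constant signals report activity 0 and NaN mobility/complexity (a
distinguished missing value rather than an exception).

## Labels

Binary: high iff rating > threshold (default 5; the boundary convention
is fixed but configurable, and matters only for synthetic data since
real ratings are continuous). Three-class: low iff ≤ 3, high iff ≥ 6,
neutral otherwise. Strongest-emotion screening takes the eight lowest-
and eight highest-rated trials per subject, labelled by selection side;
ties are broken by ascending trial index with the low side claiming
first, and the two sides are always disjoint.

## Classification

Everything is subject-dependent: one model per subject, leave-one-out
cross-validation, and the cohort figure is the unweighted mean of
per-subject accuracies, reported to two decimals with half-up rounding
(the rounding convention is visible in the bundled reference table,
whose printed averages include an exact .xx5 tie).

kNN uses k = 5 and Euclidean distance with fully deterministic ties:
distance ties resolve to the lower training index, vote ties to the
label of the nearest neighbor among the tied classes.

The RBF-SVM's (C, γ) are searched per fold over log2 ranges
([−5, 15] for C, [−15, 3] for γ) using inner stratified k-fold accuracy
on the training trials only — nested tuning. Tuning once on all of a
subject's data and then cross-validating would leak the held-out trial
into the hyperparameters; the nested form is slower but honest. Two
tuners are provided: a deterministic near-square grid, and a Bayesian
search (Gaussian-process surrogate with a fixed Matern kernel and
expected-improvement acquisition over random candidate pools). Search
ranges and budgets are conventional rather than prescribed, so reported
SVM numbers can shift a point or two under other budgets. Objective ties
prefer smaller C, then smaller γ (the smoother model). All randomness
derives from `tuner_seed` and the fold index, so runs are bit-identical
and a fold's tuning cannot depend on its held-out trial — the
`fold_details` of every evaluation expose the per-fold scaler statistics
and chosen hyperparameters precisely so this is testable.

Feature standardization (z-score, training-fold statistics) is applied
inside every fold by default. Variance/power features span orders of
magnitude and both classifiers are scale-sensitive, so some normalization
is required; fold-wise fitting is the leakage-free way to get it. An
optional log10 transform for power-type features is available but off by
default.

## Synthetic cohorts

The generator emulates exactly what the pipeline measures. Each channel
is a sum of band-limited Gaussian noise (white noise through the band
filters): a per-band common component (cancels in the difference), an
antisymmetric component added with opposite signs (survives differencing
unchanged), and independent white sensor noise. For high-valence trials
the effect band's antisymmetric amplitude is scaled by
`sqrt(effect_ratio)`, planting a variance ratio of `effect_ratio`
between classes in the difference signal's effect band — the class
effect lives in the *difference*, mirroring the asymmetry hypothesis,
not in each channel's absolute power.

Band noise is calibrated through the filter's white-noise power gain
(mean |H|⁴ over frequency) rather than per-realization RMS
normalization, so the natural trial-to-trial sampling variability of
band power (relative SD ≈ `1/sqrt(B·T)` for bandwidth B and duration T)
is preserved; without it, classes at any ratio > 1 would be trivially
separable.

Defaults, chosen once as plausible for resting-style EEG in microvolts:
band RMS amplitudes δ 8, θ 6, α 10, β 5, γ 3 µV; antisymmetric fraction
0.5 of the band amplitude; 1 µV white sensor noise per channel; effect
band alpha with ratio 2; ratings from class-conditional truncated
normals (means 3 and 7, SD 1) so threshold-5 labels agree with the
planted classes up to ~2% tail mislabelings; per-subject log-normal
amplitude multipliers with σ = 0.15. Classes are exactly balanced
(20/20) per subject and shuffled. Subject seeds derive from
`(cohort seed, subject index)` via a SeedSequence; no global RNG state.

What the generator does **not** model: 1/f background spectra, ocular
and muscular artifacts, nonstationarity, volume conduction, rating
idiosyncrasies. Passing tests therefore demonstrate that the pipeline
recovers planted band-variance asymmetries at realistic noise levels —
not that real EEG carries such asymmetries.

## Numerical and statistical behaviour worth knowing

* With the default planted ratio of 2, per-trial alpha variance has a
  relative SD of roughly 6% over 60 s (≈480 degrees of freedom), so the
  classes are nearly separable and cohort accuracies of 97–98% are
  expected; residual errors are dominated by rating-label tail flips.
* Under a null cohort (ratio 1) the LOOCV kNN accuracy sits slightly
  *below* 50% (typically 44–49% over a 32-subject cohort): removing the
  held-out trial depletes its own class among the neighbors, the
  well-known pessimistic bias of leave-one-out with balanced classes.
  This is expected behaviour, not a defect.
* The measured high/low variance ratio recovered from the difference
  signal is slightly below the planted value (≈1.93 for 2.0) because
  sensor noise and neighbouring-band leakage add class-independent
  variance to the band estimate.
* Full-size runs (32 subjects × 40 trials) were used for the end-to-end
  recovery checks; screening-style unit tests use 3–8 subjects with
  16–20 trials, which keeps the full suite under a minute while leaving
  every statistical assertion inside comfortable bands.

## EDF support

EDF/EDF+ recordings are read through mne as one-trial archives with
empty ratings (feature-extraction-only mode). The EDF header is scanned
first so that files with heterogeneous per-channel sampling rates are
rejected explicitly rather than silently resampled. A minimal EDF writer
(16-bit samples, 1 s records, per-channel physical scaling) is included
for round-trip tests and for exporting synthetic recordings; it does not
produce EDF+ annotations.

## Known limitations

* The SVM search budget strongly affects runtime (folds × iterations ×
  inner folds fits); the defaults are sized for 40-trial subjects.
* Three-class evaluation keeps all trials including neutrals; with
  truncated-normal ratings the neutral class can be small for extreme
  class-mean settings.
* Timeslot analysis assumes trials of at least 60 s post-baseline when
  the named 20 s slots are used; shorter recordings must use custom
  slots (or the full-duration default).
* The fast-gamma band of 128 Hz recordings abuts Nyquist; any prior
  low-pass in the acquisition chain (common in preprocessed releases)
  attenuates it in ways the package does not model.
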