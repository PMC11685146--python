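# Methods

`mifeatlab` implements a complete motor-imagery (MI) EEG analysis pipeline:
synthetic generation of epoched 22-channel trials, a 1,364-column
four-domain feature battery, mass-univariate significance screening with
channel x feature-type distribution maps, and a nine-family classifier
benchmark under stratified 5-fold cross-validation. This note records the
model assumptions, the numerical conventions, and the design choices made
where the problem was genuinely open.

## The epoched-trial model

The unit of analysis is a cue-based MI trial: a 3-s segment of 22-channel
EEG sampled at 250 Hz (750 samples), with one of K = 4 imagery classes
(left hand, right hand, feet, tongue in the reference montage) and a
subject ID. A dataset stacks 288 trials per subject — exactly 72 per class
— and pools subjects row-wise, so the default 9-subject layout yields a
2,592 x 1,364 pooled feature matrix, or 1,296 rows after restriction to a
class pair. Per-subject views remain available by filtering on the subject
column; pooled analysis is the default.

## Synthetic data: what it emulates and what it does not

Each channel-trial is synthesized in the frequency domain as
1/f^γ-amplitude Gaussian noise (γ = 1, i.e. pink noise — the canonical
broadband EEG background) restricted to the 0.5–100 Hz acquisition
passband, with the 50 Hz mains bin zeroed to emulate the notch filter.
The per-bin amplitude envelope is deterministic, so the expected
time-domain variance is analytic and the output is scaled to a typical
per-channel RMS of 10 (microvolt-like arbitrary units).

Class structure enters through `EffectSpec`: for trials of the stated
class, the spectral coefficients of the stated band on the stated channels
are multiplied by `sqrt(power_ratio)`, so the in-band power is scaled by
exactly `power_ratio` in expectation. Ratios below 1 emulate event-related
desynchronization (ERD), above 1 synchronization (ERS). Scaling was chosen
over adding a band-limited component because an additive component cannot
*reduce* band power, and because the multiplicative form keeps the
effect-to-measurable-power relation exact for any ratio. Per-subject
variability is a log-normal jitter of the ratio (`jitter` = sd of
log power_ratio). All randomness flows from one integer seed; identical
seed and parameters give bit-identical datasets.

The generator reproduces the *structural and spectral* conditions of a
real MI recording — trial geometry, balanced design, passband, ERD/ERS-like
band-power contrasts — but not EEG morphology: no volume-conduction
correlation between channels, no eye-blink or electrode artifacts, no
non-stationarity within a trial, no event-locked time course. Tests passing
on this generator therefore validate the *pipeline* (feature definitions,
calibration of the screen, recovery of injected contrasts), not
classification performance on real recordings, which depends on exactly
the structure the generator omits.

## The feature battery

All features are computed per channel per trial; sample statistics use the
n−1 denominator throughout.

**Time domain (T1–T24).** Amplitude/statistics descriptors listed in
`features/timedomain.py`. Conventions chosen where names underdetermine
definitions: kurtosis is non-excess (normal = 3); Hjorth mobility is
`sqrt(var(diff x)/var x)` and complexity is `mobility(diff x)/mobility(x)`;
zero crossings count strict sign changes with a configurable dead-band
(default 0); slope changes count strict sign changes of consecutive first
differences; quartiles interpolate linearly between order statistics. The
mode of continuous data is ill-posed, so T22 is the center of the most
populated of 100 equal-width bins over [min, max] — deterministic and
scale-aware. A constant series leaves mobility/complexity (and
skewness/kurtosis) undefined; those entries are NaN with a logged warning.

**Frequency domain (F1–F15).** The one-sided FFT of the raw segment is
partitioned by half-open intervals into delta 0.5–4, theta 4–8, alpha 8–13,
beta 13–30, gamma 30–100 Hz (conventional edges consistent with the
acquisition passband; configurable). Per band: energy `sum |y(k)|^2`;
variance of the coefficient magnitudes `|y(k)|` (the band spectrum is
complex, so the magnitude is the natural variate for a dispersion);
normalized spectral entropy `1/log M * sum P log P` with
`P = |y|^2 / sum|y|^2`. The entropy is kept with its natural (non-positive)
sign rather than flipped to the usual Shannon convention; its magnitude is
bounded by 1 and equals 1 for a uniform in-band distribution, 0 when one
bin carries all power. A zero-power band has entropy 0 by convention. The
log base cancels under the `1/log M` normalization.

**Time-frequency domain (W1–W15).** A full wavelet-packet tree to depth 7
with Haar filters, chosen so that at 250 Hz the 128 terminal nodes tile
[0, 125] Hz at 0.9765625 Hz resolution. Two numerical choices matter here:

* *Boundary handling* is periodization after zero-padding to the next
  power of two (750 → 1024), which preserves exact coefficient counts and
  the Parseval identity; the pad region's coefficients are retained.
* *Node ordering*: the packet tree's natural order is not frequency order;
  terminal nodes are reordered by the binary-reflected Gray code before
  band mapping. Skipping this step silently assigns most bands the wrong
  coefficients. The implementation is a vectorized butterfly recursion
  kept coefficient-exact against PyWavelets
  (`wavelet='haar', mode='periodization', order='freq'`), which the test
  suite uses as the independent oracle.

A node belongs to the band whose interval contains the node's midpoint
frequency (nodes almost never align with band edges; the midpoint rule is
deterministic, and the full node→band table is logged). Per band, the
coefficients of its nodes are pooled: energy `sum c^2`; variance
`1/(N−1) sum (c − mean)^2`; entropy `sum c^2 log(c^2)` with `0·log 0 := 0`.
This entropy is deliberately unnormalized and without the conventional
minus sign — it is the log-energy form used as-is in the source feature
battery; it is monotone-comparable across columns, which is all the
downstream screen requires.

**Non-linear domain (P1–P8).** Lagged Poincaré plots at m = 1 and m = 9
samples: with `x_i = (x_0..x_{N−m})`, `x_lag = (x_m..x_N)` and the ±45°
rotation `x_a = (x_lag − x_i)/√2`, `x_b = (x_lag + x_i)/√2`, the features
are SD1 = sd(x_a), SD2 = sd(x_b), their product and their ratio, per lag.
The rotation gives the exact identity
`SD1² + SD2² = var(x_i) + var(x_lag)`, used as a standing test invariant;
for i.i.d. data SD1/SD2 → 1. SD2 = 0 (constant series) leaves the ratio
NaN with a warning.

## Feature screening and distribution maps

Screening is mass-univariate: per column, a two-sided equal-variance
independent t-test for two classes (Welch available by flag) or a one-way
ANOVA F-test for more, with a strict `p < alpha` mask at alpha = 0.05.
Two caveats are intentional properties of the procedure being studied, not
oversights, and both are preserved faithfully:

* **No multiple-testing correction** — raw p-values are thresholded, so
  under the null about alpha of the columns are selected (the test suite
  checks this calibration against a binomial band and a permutation
  oracle).
* **Selection precedes cross-validation** on the full pooled matrix, so
  label information leaks into the column choice; accuracies on selected
  columns are optimistically biased relative to nested selection.

Zero-variance columns get p := 1 with a warning. The per-domain
`DistributionMap` is the boolean feature-type x channel grid of surviving
columns with row/column/grand totals, rendered as a check-mark text table
and as CSV; grand totals over the four domains sum to the mask size by
construction.

## Classifier benchmark

Nine families, each a set of standard toolbox presets: decision trees
(max-leaf 100/20/4), linear/quadratic discriminant analysis, logistic
regression, Gaussian/kernel naive Bayes, SVMs (linear/quadratic/cubic and
three RBF widths around gamma = 1/P), kNN (k = 1/10/100, Minkowski-3,
cosine, distance-weighted), ensembles (bagged trees, boosted trees,
random-subspace discriminant, random-subspace kNN), MLPs (one to three
hidden layers, 10–100 units), and kernel approximation (Nystroem features
into a linear SVM or logistic regression). Scale-sensitive estimators are
standardized inside their pipelines. Kernel naive Bayes (a toolbox preset
without a scikit-learn counterpart) is implemented in-package as a
per-feature Gaussian-KDE naive Bayes with Silverman bandwidth; it is
quadratic in the training-set size and intended for moderate sample
counts. A RUS-boosted tree preset is not included: it targets class
imbalance, which the balanced design never produces.

Folds are stratified (protecting chance-level baselines with four classes)
and seeded; all variants share the same folds, and each sample is tested
exactly once. A family reports its best variant by mean fold accuracy —
the way benchmark tables print one number per family — with per-variant
details retained. A variant that cannot fit (e.g. singular class
covariance in quadratic discriminant analysis on wide matrices) is
recorded as failed rather than aborting. Accuracy is
`ACC = (TP+TN)/(TP+FN+TN+FP)`; for K > 2 the confusion counts are
aggregated one-vs-rest (totalling n·K) while the headline accuracy is the
fraction of correctly labeled test samples.

## Problem sizes and tolerances

Exact identities (oracle equivalence of every feature, Parseval sums, the
Poincaré rotation identity) are asserted at 1e-9 relative tolerance on
100 seeded 750-sample trials. Statistical checks use sizes at which their
bands are meaningful and quick to compute: null calibration of the screen
on 200 i.i.d. columns (binomial band [0.01, 0.12] at alpha = 0.05) and on
full generated datasets; permutation-oracle spot checks with 10,000
shuffles at |Δp| < 0.025; channel recovery over 5 seeds of a
72-trial-per-class dataset with a 4x alpha-band effect on channels 8 and
12 (sensitivity ≥ 0.8 required; observed 1.0); classifier null-safety on
400 shuffled-label samples (chance band [0.15, 0.35] for K = 4). The
acceptance script runs the full 2,592-trial extraction; everything else is
sized to keep a complete run in a few minutes on one core.

## Known limitations

* The generator's channels are independent; spatial filters or
  connectivity features would find no realistic structure to exploit.
* The wavelet entropy convention (unnormalized, sign as computed) differs
  from Shannon entropy; compare only within this package.
* Accuracies on selected features inherit the selection-before-CV
  optimism noted above.
* MATLAB toolbox presets are followed in spirit (variant structure and
  key hyperparameters), not bit-for-bit; exact replication of another
  toolbox's internals is a non-goal.
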