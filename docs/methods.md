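# Methods

This note documents the generating models, estimators, defaults and known
limitations of the `electrome` package — what is being computed, why these
definitions were chosen where several are in circulation, and what passing
the test suite does and does not establish about real recordings.

## Signal model

An electrophytogram is modelled as

    dV(t) = b(t) + sum_k  s_k * A_k * w(t - t_k)  [+ slow waves]

with three components:

**Colored-noise baseline** `b(t)`: spectrally synthesized noise with
amplitude spectrum proportional to f^(-beta/2) and i.i.d. uniform phases,
rescaled to an exact target standard deviation sigma and exact zero mean.
This reproduces the 1/f^beta power spectra characteristic of resting
plant electromes. Spectral synthesis (rather than, e.g., an AR cascade)
gives direct, unbiased control of the generating exponent, which the
recovery tests depend on.

**Spike train**: event times t_k follow a homogeneous Poisson process
(piecewise-constant rate inside an optional burst window), absolute
amplitudes A_k follow a truncated power law p(A) ~ A^-mu on
[A_min, A_max] (drawn by inverse CDF), and the sign s_k is positive with
probability 0.5 by default. Two unit-peak templates `w` are provided:
`ap_like`, a Hann-windowed single sine cycle (biphasic
depolarization/repolarization, default 4 s), and `vp_like`, a raised
cosine (slow monophasic wave, default 45–60 s). The power-law amplitude
model encodes the observed "the larger the peak, the rarer" behaviour;
the Poisson placement is the simplest process consistent with the
described phenomenology.

**Slow waves** (salt profile only): a configured number of single-cycle
Hann-windowed sine waves (default period 600 s, amplitude 1.5 mV) at
uniformly random onsets, emulating the long-period waves with embedded
spikes that distinguish salt stimulation.

### Treatment profiles

Shipped defaults (`electrome/data/default_profiles.yaml`), one per
treatment, all at 62.5 Hz for 7200 s (450,000 samples):

| treatment | beta (pre -> post) | sigma mV (pre -> post) | spikes/h (pre -> post) | extras |
|-----------|--------------------|------------------------|------------------------|--------|
| water     | 1.76               | 0.02                   | 6 -> 8                 | —      |
| nutrient  | 1.75               | 0.02                   | 6 -> 12                | —      |
| peg       | 1.65 -> 2.12       | 0.02 -> 0.05           | 6 -> 60 (VP-like, to 8 mV) | —  |
| nacl      | 1.90               | 0.02 -> 0.04           | 6 -> 80 (to 10 mV)     | burst ×4 in first 25 min; 4 slow waves |

Baseline exponents and their post-stimulus shifts follow the reported
phase-dependent spectral exponents; resting sigma 0.02 mV keeps ~98% of
resting samples within ±0.05 mV with rare spikes below ±0.5 mV, and
post-osmotic amplitudes reach the ±5–10 mV range. **Spike rates are
order-of-magnitude choices**: no quantitative event rates are published
for this design, so the defaults were fixed once at values that give
clearly visible but not wall-to-wall spiking, and are not calibration
targets. The profiles are tuned only so the qualitative orderings hold
(post-PEG/NaCl entropy below pre-stimulus, chance-level separability for
water); no real per-treatment statistic is a fitting target.

For recordings shorter than the canonical 2 h,
`fit_profile_to_duration` rescales burst windows and slow-wave periods
proportionally so the same phenomenology occupies the same fraction of
the recording; event rates per hour are untouched.

### Acquisition-filter emulation

The emulated acquisition front end is a 2nd-order zero-phase Butterworth
high-pass at 0.5 Hz (`signal_io.apply_acquisition_filter`). The hardware
chain's 100 Hz low-pass and 60 Hz notch act above the 31.25 Hz Nyquist
frequency of the 62.5 Hz stream and are therefore not modelled
digitally; the instrument tones they leave behind (2.5 / 5 / 7.5 Hz) can
instead be injected explicitly (`instrument_tones=True`).

`synthesize_electrome` does **not** apply the high-pass by default.
Recorded electromes demonstrably retain strong sub-0.5 Hz power (spectra
concentrated between 0 and 1 Hz; minutes-long salt waves), so an ideal
zero-phase digital 0.5 Hz high-pass would erase exactly the structure
the generator exists to produce — the 1/f^beta tail inside the 0.05–10 Hz
fit band and the slow waves. The filter is one call away for users who
want the strict front-end emulation; applying it attenuates everything
below 0.5 Hz by design.

## Estimators

**Mean voltage variation** is the mean of |dV| by default. A high-passed
recording is near-zero-mean, so the signed mean is uninformatively close
to zero while the reported per-series values are small and positive;
mean |dV| is the definition consistent with both. `signed=True` restores
the plain mean.

**Skewness / kurtosis**: standardized third moment and *excess* (Fisher)
kurtosis. At the kurtosis magnitudes relevant here (hundreds to
thousands) the ±3 convention offset is immaterial.

**PDF exponent mu**: |dV| is binned into 40 log-spaced bins over the fit
range (default: above the 90th percentile of |dV|, i.e. the tail), and
log10 density is regressed on log10 |dV| by ordinary least squares;
mu is the negative slope, reported with r² and the number of tail
points. Regression on log-spaced histograms matches the practice of the
plant-electrome literature this pipeline follows; the estimator recovers
generating exponents 1.5 and 2.5 within ±0.2 on 10^5 truncated-Pareto
samples (tested). A fit with too few tail points is flagged, not raised.

**Autocorrelation decay**: smallest lag at which the sample ACF
(FFT-based) first drops below 1/e, reported in samples and seconds. The
1/e first-crossing is a documented stand-in: published "autocorrelation"
summary values for this kind of data come with no stated units or
definition, so this package fixes one and names it. An ACF still above
threshold at the maximum lag is reported as right-censored.

**PSD exponent beta**: Welch averaged periodogram (Hann window, 8
segments, 50% overlap), log10 power regressed on log10 frequency over
0.05–10 Hz; beta is the negative slope. The band avoids the high-pass
shoulder and the instrument-tone region while retaining ≥ 3 decades.
The log-periodogram's chi-square distribution offsets the intercept, not
the slope, so the estimator is slope-unbiased; it recovers generating
beta in {0, 1, 2} within ±0.15 (mean over 20 series, tested). Note that
on *composite* signals (baseline + spikes) the fitted beta reflects
total signal content, not the baseline parameter alone.

**FFT spectrum**: one-sided magnitude spectrum to Nyquist, scaled so a
unit sinusoid at a bin frequency has magnitude ≈ 1.

**Approximate entropy**: the Pincus definition with self-matches,

    ApEn(m, r) = Phi^m(r) - Phi^(m+1)(r),
    Phi^m(r)   = mean_i ln( C_i^m(r) ),

where C_i^m is the fraction of length-m pattern vectors within Chebyshev
distance r of vector i. Defaults m = 2, r = 0.2 × SD — the field
standard in the multiscale-entropy literature; the source analyses state
no parameters. The implementation is a block-chunked O(N²) kernel whose
equality with a direct transcription of the definition is enforced to
1e-9 on random series (tested). A constant series returns exactly 0.
Because O(N²) on 450,000 points is infeasible at desk scale, the ledger
decimates to at most 10,000 points (every 45th sample at canonical
length) before ApEn; correctness is guarded by the small-N equivalence
test, and the cap is configurable.

**Multiscale ApEn**: scale-s series are non-overlapping means of s
consecutive samples (floor(N/s) points); ApEn is computed per scale with
r *fixed from the original series*, so the curve reflects structure, not
per-scale renormalization. Scale 1 is exactly the plain ApEn. For white
noise the expected curve decreases with scale (tested on seed-averaged
curves, allowing 5% of transitions to invert due to estimator noise at
deep scales).

## Interval-arithmetic reduction and classification

Windows are consecutive and non-overlapping (default 30,000 samples;
1,000 / 5,000 / 15,000 supported via config), a trailing partial window
is dropped, and each window contributes [min, center, max]. The center
is the **arithmetic mean** by default: the defining descriptions state
the triplet both as "[min, med, max]" and explicitly as minimum /
average / maximum; the average is the majority reading, and
`center="median"` is available. A 450,000-point series reduces to 15
windows = 45 scalars ("reduced to 15" counts windows, not scalars).

Classifier defaults (hyperparameters are unstated upstream, so these are
fixed and documented): KNN k = 5 Euclidean (k shrinks to the training
size on very small splits); decision tree unlimited depth, seeded;
random forest 100 trees; Gaussian naive Bayes; RBF-SVM (C = 1) on
standardized features; MLP with one hidden layer of 32 units on
standardized features, trained with lbfgs — the quasi-Newton solver is
the reliable choice at the tens-of-samples training sizes this design
produces, where stochastic optimizers underfit sporadically.

Splits are stratified by class (unstratified splits at fraction 0.1 can
drop a class outright); each split's seed derives deterministically from
(master seed, classifier index, fraction index, repetition index), so
every repetition is reconstructible. A split missing a class is redrawn
and logged. Confusion matrices are row-normalized (entry (i, j) =
fraction of class-i items predicted j) — captions phrased as "recognized
X% of class i" imply row normalization — and are pooled over the 20
repetitions at a chosen fraction (default: the classifier's best mean
accuracy). Classifier pairs are compared with the two-sided Wilcoxon
signed-rank test on paired per-repetition accuracies; identical arrays
are reported as "no difference detectable" rather than a p-value.

Per-plant grouping (keeping one plant's before/after in the same fold)
is not enforced: the split unit is the series.

## Paired before/after statistics

Paired differences are screened with Shapiro–Wilk at alpha = 0.05 (the
routing rule names no specific normality test; Shapiro–Wilk is the
default of the statistical package used upstream and is configurable);
normal-looking differences go to the paired t-test, others to the
Wilcoxon signed-rank test, both two-sided. All-zero differences are
degenerate and reported as such. Type-I error of the routed procedure
stays within [0.03, 0.07] at alpha = 0.05 over 2,000 null replicates for
both normal and heavy-tailed data (tested). No multiple-testing
correction is applied across ledger variables, matching upstream
practice.

## Problem sizes in tests and calibration

The test suite and the calibration script run on deliberately desk-scale
problems, chosen as the smallest sizes at which each property is
statistically decisive: exponent recovery on 65,536-sample series (20
seeds); chance-level calibration on 200 (two-class) and 400 (four-class)
interval-reduced series of 45,000 samples with window 3,000 — the same
15-window/45-scalar geometry as the canonical design, since chance level
under shuffled labels does not depend on series length; ApEn equivalence
on 50 series of ≤ 500 points; type-I calibration on 2,000 replicates of
20 pairs. The chance-level report averages over 10 independent label
draws because a single balanced labelling of n series carries an
irreducible binomial floor of about sqrt(p(1-p)/n) on the pooled cell
estimate.

## What the synthetic data do and do not show

The generator reproduces the *statistical* structure described for real
electromes: amplitude scale and spike rarity at rest, power-law spike
amplitudes, 1/f^beta baselines with phase-dependent exponents, the salt
burst and slow waves, and the complexity collapse under severe osmotic
stress. It does not reproduce: individual-plant idiosyncrasy (each real
electrome is "unique"; synthetic series differ only by seed within a
profile), electrode-contact and drift artifacts, circadian or
environmental nonstationarity, true AP/VP waveform physiology (templates
are stylized), or any real-data feature values. Passing tests therefore
establishes that the *estimators and harness are correct and calibrated*
— that exponents are recovered, entropy implements its definition,
chance is chance, separable data separate — not that real recordings
would yield any particular accuracy. Real-data classifier accuracies
cannot be reproduced here because the underlying recordings were never
deposited; the separable-case ceiling (every classifier reaching 100% on
a constructed tonic-depolarization contrast) is the end-to-end surrogate
for the reported perfect salt-stress detection.

## Numerical choices and degenerate inputs

- Colored noise: DC bin zeroed, Nyquist bin made real for even N; exact
  zero mean and exact target SD by rescaling.
- Exponent fits return flagged results (`ok=False` with a message)
  rather than raising when the tail or band is too thin; ledger
  assembly records per-statistic failures and never aborts.
- Constant series: mean |dV| 0, ApEn 0, moments/ACF flagged as
  degenerate, CV of a zero-mean sample is NaN ("undefined" signal).
- ApEn tolerance r derived from a zero-variance series is treated as
  perfect regularity (0), but an explicitly passed r ≤ 0 is an error.
- Multiscale entropy refuses scales for which the coarse series would
  be shorter than m + 2, naming the maximal feasible scale.
- All generators and the harness are deterministic given a seed; derived
  seeds use `numpy` SeedSequence spawning and stay below 2^31.
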