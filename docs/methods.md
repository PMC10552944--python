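# Methods

This note records the models, conventions, and numerical choices behind
the package, including the decisions taken where the procedure left room
for interpretation, and what the synthetic-data tests do and do not
establish about real recordings.

## Conventions

Time is measured in milliseconds relative to speech-chunk onset; sample
index 0 is onset and all windows are half-open `[start, end)`.  Channels
are keyed by montage label, never by position in an array, so channel
subsetting is explicit.  Artifact samples are NaN and are *excluded*
from every downstream average (never zero-filled), so missing data
shrink the effective sample rather than bias it.

## Envelope extraction

The envelope is `|hilbert(audio)|`, decimated to 1000 Hz with a
polyphase anti-aliasing resampler, then low-pass filtered at 40 Hz.
"Zero-phase 4th-order Butterworth" is realized as forward–backward
(`filtfilt`) application of a 4th-order design — effective order 8 with
exactly zero net phase, which the test suite verifies by
cross-correlation.  Filter ringing below zero is clipped, preserving the
envelope's nonnegativity invariant.  Spectral peaks are detected on the
one-sided FFT power spectrum with DC removed; since only a
minimum-distance criterion is given for syllable-rate peaks (150 ms),
the height criterion is this package's choice: peaks must exceed the
chunk median (time domain) or 5% of the largest non-DC component
(spectrum).  Chunks shorter than 300 ms yield a rate estimate flagged
`reliable = False` rather than being dropped.

## EEG preprocessing

The pipeline order is fixed and logged: band-pass (0.1–70 Hz, zero-phase
4th-order Butterworth) + 50 Hz notch (Q = 30), spatial smoothing, common
average reference, epoching.  The spatial filter takes, per channel and
sample, the 6 nearest neighbors plus the channel itself (self weight 1,
neighbors weighted by inverse distance), sorts the 7 values, drops the
minimum and maximum, and averages the remaining 5 with their weights.
Neighbor distances use 3-D sensor positions when available; ties are
broken by channel-label order.  Operator-interactive cleaning (ICA
component rejection, spline interpolation) is out of scope — the
pipeline accepts pre-cleaned input with artifact spans marked.

Electrode adjacency for cluster statistics comes from a Delaunay
triangulation of the 2-D projected montage with edges longer than 1.5×
the median edge length pruned; the montage itself (when synthesized) is
a sunflower layout on a spherical cap, which yields a connected,
roughly uniform neighbor graph at 110 channels.

## Time–frequency power

Morlet wavelets with 5 cycles (MNE's L2/energy normalization), computed
on the padded epoch and cropped to −1000…+1000 ms.  Trials are averaged
*before* the dB conversion `10·log10(P / P̄_baseline)`; the order is
locked because the two orders differ for heterogeneous trials.  NaN
artifact spans are zero-filled before the convolution and the output is
re-masked with the mask dilated by half the wavelet support per
frequency, so no artifact leaks into the averages.  Band power is the
mean dB over the band × 0–1000 ms rectangle.

## Neural tracking

Band amplitude is `|hilbert|` of the zero-phase band-passed epoch.
Because the per-epoch filter and analytic signal have onset/offset
transients of roughly a quarter second, the reconstruction uses the
interior of each speech window (default margin 300 ms) with the
pre-onset padding absorbing the left transient.  The design matrix has
one column per (channel × lag); positive lag means the EEG sample
follows the envelope sample it predicts.  Folds are 10 consecutive,
contiguous, equal-length segments of the concatenated speech windows
(remainder to the last fold); the fit is plain OLS (minimum-norm on
rank deficiency, with a logged warning), correlation is Pearson, and
pooling is the inverse Fisher transform of the mean z.  Single-channel
maps fit one model per channel.

## Phase–amplitude coupling

Phase bands are `f_p ± 1 Hz`; amplitude bands follow the variable-
bandwidth rule `f_a ± f_p`.  Phase bins are 18 equal left-closed bins on
[−π, π); empty bins contribute 0 to the KL divergence (the 0·log 0
limit) and more than 2 empty bins triggers a warning.  MI is computed
per trial and averaged; surrogates pair each trial's amplitude with the
phase of a random *different* trial (200 draws), giving
`z = (MI_obs − mean_surr) / sd_surr`.  The visual peak/trough screening
of the modulating-band spectrum is automated as a local-extremum test on
the trial-averaged Welch spectrum within ±1 Hz of each candidate `f_p`;
failing frequencies are flagged, never dropped.  For an electrode
cluster, signals are averaged across the cluster's electrodes before
phase/amplitude extraction, so each cluster contributes one
representative time course.

**Resolution of the comodulogram.**  With the variable-bandwidth rule,
an amplitude-modulated component at `(f_p, f_a)` places its sidebands at
`f_a ± f_p` — exactly on the −3 dB edges of every candidate amplitude
band whose center lies within `f_a ± f_p`.  All such cells therefore
carry nearly the same coupling information, and the raw grid argmax
jitters across this blob (about ±f_p in the amplitude dimension) while
the phase coordinate is recovered exactly.  Bands that capture a single
sideband with a partially attenuated carrier additionally show a
deepened beat (an overmodulation artifact familiar from narrowband PAC
filtering).  The package therefore exposes
`Comodulogram.coupling_centroid()` — the z-weighted centroid of the
cells above a z threshold, snapped to the grid — as its coupling-location
estimator; on synthetic data it recovers a planted (6 Hz, 36 Hz)
coupling essentially always, whereas the literal argmax lands anywhere
inside the 30–42 Hz blob.

## Gaze divergence

Densities are adaptive-bandwidth Gaussian KDEs: a Silverman pilot
bandwidth (floored at one grid cell) gives per-point Abramson factors
`λ_i = (g / f_pilot(x_i))^{1/2}`.  Maps live on a down-sampled grid of
the 1920 × 1200 px screen (default 96 × 60) and integrate to unit mass.
The EMD is solved exactly as the discrete transport linear program
(HiGHS) on the density support, truncated to the cells carrying all but
a 10⁻⁴ mass fraction, at most 400 cells, and nothing below 10⁻⁶ relative
weight (the LP solver's feasibility tolerance); the truncation error is
bounded by the dropped mass times the grid diameter, far below a pixel.
The permutation test shuffles participant labels and deems the observed
distance significant when it ranks in the top 5% of the null (rank > 195
of 200 by default).  The Proximity Index uses the same metric: the
per-frame EMD of an individual's density to the norm group's pooled
density, min–max normalized across the cohort per frame and inverted
(1 = most norm-like), averaged over frames per excerpt.  The choice of
EMD as the PI distance and of the per-frame cohort min–max as the 0–1
normalization are this package's decisions; the underlying procedure
names only "distance" and "normalized to 0–1".

## Group statistics

Psychometric comparisons use Student's pooled two-sample t with
pairwise-complete deletion per variable (df = n₁ + n₂ − 2 after
exclusion) and η² = t²/(t² + df); age distributions are compared by the
asymptotic two-sample KS test.  The electrode cluster test thresholds
per-electrode |t| at the two-sided 5% point, forms clusters of ≥2
adjacent suprathreshold electrodes, carries the maximum |t| forward, and
compares it to the permutation null of the largest cluster statistic
(1000 draws; p = (1 + #{null ≥ obs})/(n + 1)).  Covariate adjustment is
a Freedman–Lane scheme: values and group indicator are residualized
against [1, covariate], permutations shuffle the residualized data and
re-residualize before computing t (this re-residualization is what keeps
the permuted statistic's degrees of freedom equal to the observed one's
— omitting it measurably inflates the family-wise error).  A literal
covariate-label shuffle is available via
`covariate_scheme="shuffle-covariate"` for sensitivity analysis.
Comodulogram-cell clusters use paired t, 4-neighbor grid adjacency,
sign-flip permutations, and allow single-cell clusters (the ≥2 rule is
an electrode-space constraint).

## Prediction

Severity classification uses a linear discriminant with a shared
diagonal covariance; the shrinkage grid {0, 0.1, …, 1} blends the
per-feature pooled variances toward their mean.  Outer folds are
stratified 10-fold (shrunk when a class is too small), inner grid search
is 5-fold, and the reported accuracy pools all held-out participants.
Chance levels come from the exact upper-tail binomial at p = 1/n_classes.
Score regression is Lasso inside a standardization pipeline; the 30
log-spaced penalties are anchored at the training fold's null-model
penalty `max|Xᵀy|/n` and span three decades.  The displayed final model
is a whole-data refit after the cross-validated assessment, with
coefficients mapped back to the original feature scale.  Held-out R² is
computed against the test fold's own mean; with small test folds this
estimator is noticeably downward-biased, which is why the known-R²
calibration uses n = 200 (test folds of 20).

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
with defaults mirroring the study conditions: 31 + 33 participants,
50 trials of ~2.4 s at 1000 Hz, 110 channels, cohort score means/SDs
equal to the published group summary, ADOS-derived severity grades, and
a (6 Hz, 36 Hz, depth 0.8) coupling on a 6-electrode cluster.  The
background is 1/f (pink) noise, amplitude-equalized per channel.  The
envelope is a sum of cosines at configurable modulation peaks (default
1.2, 3.3, 4.7 Hz) over a unit pedestal plus a small pink-noise
component.  The tracking embedding amplitude-modulates a carrier at the
embed-band center with the *low-passed* envelope (cutoff = band
half-width): a band of half-width w cannot physically carry amplitude
modulation faster than w, so this is the strongest embedding the decoder
could ever recover; with the default multi-peak envelope the recoverable
ceiling is therefore well below 1 even at infinite SNR, which is the
realistic regime.  The PAC component adds a narrowband stochastic slow
oscillation (filtered noise at f_p ± 1 Hz, so phase estimation is
nontrivial) and a fast component `fast_amp · (1 + depth·cos φ_p) ·
cos(2π f_a t)` from onset onward; the pre-onset baseline contains
background only.  Gaze streams draw each participant's fixations from
per-group Gaussian mixtures, clipped to the screen.  Cohort scores share
a per-participant latent factor (default correlation 0.5).  All
generators are pure functions of (spec, seed).

What passing these tests shows: the estimators recover known parameters
at realistic SNR, the permutation machinery holds its nominal error
rates, and the identities (Fisher pooling, MI bounds, dB scale
invariance, EMD metric axioms) are exact.  What they do not show: the
generators contain no eye blinks, line-noise harmonics, inter-channel
correlation structure beyond the planted components, or nonstationary
artifacts, so performance on real recordings will be bounded by data
quality in ways these tests cannot certify.

## Problem sizes

The test and acceptance runs scale the simulations to desk size as the
package's own choice of study conditions for automated verification:
tracking recovery uses 10 × 3 s trials at 1000 Hz; comodulograms use
40 × 2 s trials at 500 Hz (Nyquist comfortably above the highest
amplitude band edge of 64 Hz); cluster calibration uses 500 null
datasets of 110 electrodes with 20 + 20 participants and 200
permutations; EMD calibration uses 200 null simulations on a 12 × 8
grid with 40 permutations (the top-5% rule then has nominal level
2/41 ≈ 4.9%); prediction calibration uses cohorts of 45–200.
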