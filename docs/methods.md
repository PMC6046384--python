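# Methods

This note documents the models and procedures implemented in `hrvcc`, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data validation does and does not demonstrate.

## Preprocessing

A raw recording is an ordered sequence of interbeat intervals (IBIs) in
milliseconds. Preprocessing applies, in order:

1. **Trim** — `trim_minutes` (default 15) of *cumulative time* removed from
   each end, to drop the adaptation period at the start and the wind-down at
   the end of an ambulatory session. Boundaries are half-open: an interval
   is kept iff its end time exceeds the leading trim and its start time
   precedes the trailing trim, so a 120-min recording yields ≈90 min ± one
   interval. Trimming by cumulative time (not beat count) keeps the retained
   duration independent of heart rate.
2. **Band filter** — intervals outside [400, 1100] ms removed. The band
   brackets plausible adolescent/adult heart rates (≈55–150 bpm); values
   outside it are detector artifacts (missed or doubled beats).
3. **Central-interval filter** — a single forward pass with an 11-interval
   window (halfwidth 5). The candidate is compared with the mean of its 10
   neighbours (candidate excluded); it is removed when
   |candidate − mean| > 0.20 × mean. The pass operates on the *evolving*
   series: a removed interval no longer participates in later windows, and
   after a removal the window is advanced to the next surviving interval.
   The alternative convention (windows always over the original series) is
   equally defensible; the evolving-series single pass was chosen because it
   matches how a streaming filter advances, and the two differ only when
   artifacts cluster within one window. Edge intervals without a complete
   window are never candidates.

Excluded intervals are **removed, not interpolated**; all downstream
measures operate on the gapless surviving sequence, and the per-subject
report carries the counts per rule. Running the filter a second time on its
own output excludes nothing new (verified property) except in contrived
series with values exactly at the 20% boundary.

## HRV measures

* AVNN = mean NN interval (ms); HR = 60000/AVNN (bpm) — the identity
  HR·AVNN = 60000 holds exactly.
* RMSSD = √(mean of squared successive differences) (ms); invariant under
  adding a constant to all intervals.
* Spectral powers: the beat series is a set of samples at uneven times
  tₖ = Σᵢ≤ₖ IBIᵢ. The default estimator interpolates (cubic spline) onto a
  uniform grid at 4 Hz — comfortably above twice the 0.4 Hz upper band edge
  — linearly detrends, applies a Hann taper, and integrates the one-sided
  periodogram density over LF = [0.04, 0.15) Hz and HF = [0.15, 0.40) Hz.
  Bands are half-open so LF and HF never double-count the shared 0.15 Hz
  bin. The periodogram scaling is Parseval-consistent: with the taper
  disabled the full-range integral equals the variance of the detrended
  resampled signal to well under 1%.
* A Lomb–Scargle estimator works directly on the uneven samples, with the
  raw Lomb power rescaled so its full-range integral equals the detrended
  series variance. FFT and Lomb band powers agree within 15% on clean
  modulated test series; FFT is the default because it is the conventional
  choice when a resampled series is acceptable, and the dual route guards
  against interpolation artifacts.
* HF power is strongly right-skewed across subjects; cohort statistics use
  lnHF (natural log). The `normality_screen` helper (Shapiro–Wilk W plus
  skewness/kurtosis) documents the motivation on any sample.

Only LF and HF are reported; total/VLF power, normalized units and LF/HF
ratios are deliberately out of scope.

## Complexity measures

**DFA.** The mean-centred series is integrated; for each box size n the
profile is split into ⌊N/n⌋ non-overlapping boxes (remainder dropped), the
least-squares line (order 1) is removed per box, and F(n) is the RMS
residual over all retained points. α₁ is the unweighted least-squares slope
of log F(n) vs log n over integer box sizes 4–11, α₂ over 12–64. The lower
bound of the long range is canonical (beyond ~11 beats); the 64-beat
ceiling is a package default — long-range fits need several boxes per
series and 9000/64 ≈ 140 boxes keeps F(n) stable — and is config-exposed.
Estimator calibration (tested): on exact fractional Gaussian noise with
Hurst exponent H ∈ {0.5, 0.7, 0.9}, the mean fitted exponent over a seed
ensemble at n = 9000 is within ±0.05 of H. On white noise the 4–64 fit
averages ≈0.52, the small positive bias of box-wise linear detrending at
small n; it is reported as estimated, not corrected.

**Allometric aggregation.** For levels k = 1, 10, 20, …, 100, adjacent
points are summed in non-overlapping blocks of k (remainder dropped) and
the mean and SD (ddof = 1) of each aggregated series recorded; h is the
least-squares slope of log SD vs log mean across levels, and FD = 2 − h by
definition. Sums (not means) are essential: for uncorrelated data the mean
grows as k and the SD as √k, giving h = 0.5; a deterministic ramp gives
h = 1. Fitting SD rather than variance halves the slope (variance would
give 2h); natural logs are used but the slope is base-invariant. Levels
with zero SD are dropped with a warning; fewer than three usable levels is
an error, as is a non-positive mean (the log is undefined).

**Multiscale entropy.** Coarse-graining *averages* non-overlapping windows
of τ points (contrast the allometric sums — both conventions are preserved
as the field defines them). SampEn(m, r) = −ln(A/B), where B counts pairs
of m-length templates within Chebyshev distance r (self-matches excluded)
and A the same for m+1; both template indices are restricted so the
(m+1)-length template exists. Matches use ≤ r. Defaults m = 2 and
r = 0.15 × SD of the original series follow the canonical multiscale
implementation; the tolerance is fixed from the scale-1 series and reused
at all scales (a `per_scale_r` flag re-derives it per scale). Zero matches
make SampEn undefined: the per-scale value is NaN and flagged, never
silently 0. The vectorized implementation is verified to equal an explicit
all-pairs enumeration exactly (1e−12) on random series up to n = 200.

## Heart-rate adjustment

Many variability and complexity indices have a built-in mathematical
dependence on mean heart rate. The adjustment rule: compute each measure's
cross-subject Pearson correlation with mean HR; divide the measure by the
subject's mean HR when the correlation is negative, multiply when positive.
In cohorts with the default generative structure only short-range DFA α₁
correlates positively. An exactly zero or undefined correlation leaves the
measure unadjusted with a warning (the rule covers only signed cases). Both
raw and adjusted values are retained, and every cohort analysis is run on
both.

## Cohort statistics

* **Group comparisons** are per-measure one-way F tests between the sexes,
  computed as the squared pooled-variance t (df 1, N−2) — verified
  equivalent to 1e−9. Cohen's d = |mean₁ − mean₂| / pooled SD, reported as
  a magnitude. Measures are grouped into Bonferroni families sharing a
  corrected alpha: time domain (2 tests, α = 0.025), frequency domain (2,
  α = 0.025), fractal (3, α = 0.017), entropy (5, α = 0.01). No
  multivariate (Pillai-type) statistic is computed; the per-measure
  univariate F is the reporting surface.
* **Moderated regressions**: step 1 fits OLS of the subscale total on sex
  (raw 1/2 coding) and the z-scored measure; step 2 adds sex × z(measure).
  The measure is standardized to prevent multicollinearity with its
  interaction; sex is left on its stated coding and not centred.
  Coefficients are reported as standardized betas (slope × predictor SD /
  outcome SD); the interaction's contribution is the step-2 R² increment.
  Rows with missing values are dropped listwise per regression.
* Calibration (tested): under the null the comparison's type-I error rate
  at α = 0.05 is within [0.04, 0.06] over 1000 replicates; generative
  standardized slopes of −0.17 are recovered within ±0.05 in the mean over
  200 cohorts of ~154 complete cases.

## Synthetic data

`gen_series` produces IBI series by kind: `white` (iid Gaussian), `fgn`
(fractional Gaussian noise via circulant embedding — the construction
reproduces the target autocovariance exactly, verified against the closed
form), `ar1`, `modulated` (sinusoids at the configured HF/LF frequencies
evaluated on the cumulative beat-time axis, so the respiratory modulation
lands in the right spectral band, plus white noise), `ramp` and `periodic`.
Defaults emulate the ambulatory study design the pipeline targets: 120-min
recordings at a 650 ms mean interval (≈92 bpm, ≈11,000 beats), SD 40 ms.
Artifacts are planted as isolated beats, half out-of-band and half in-band
spikes 35–60% away from the local mean, so both filter stages are
exercised; ≥95% of planted artifacts are recovered by the default filter
(tested).

`gen_cohort` draws cardiac measures per sex group from configurable
means/SDs (defaults match the magnitudes typical of adolescent ambulatory
cohorts: girls ≈4 bpm higher HR, lower RMSSD/LF/lnHF/FD/entropy, slightly
higher α₁), sharing a latent per-subject HR factor whose signed loadings
give the adjustment rule a defined direction per measure. The cross-measure
correlation strengths are generator assumptions — the true correlation
structure of real cohorts is not published — and are config-exposed.
Symptom subscale totals come from a linear model on standardized predictors
scaled by the subscale SD, rounded and floored at 0, with whole-row
missingness completely at random (default rate 0.07, giving ≈154 complete
cases out of 166). Measures are drawn at the measure level by default, for
speed; end-to-end tests additionally generate actual IBI series and run the
full pipeline at reduced duration.

**What passing tests show.** The synthetic generator validates estimator
correctness and statistical calibration under known generative truth. It
does not emulate non-stationarity from posture and activity changes,
circadian drift, ectopic-beat morphology, or the baroreflex feedback
structure of real heart-rate dynamics, so passing tests do not certify
accuracy on pathological or heavily artifact-laden real recordings.

## Numerical conventions and degenerate inputs

Box/block/window remainders are always discarded. Log–log fits are
unweighted least squares over the stated grids. Constant series raise
errors wherever an exponent, tolerance or entropy would be undefined (DFA,
allometric with <3 usable levels, SampEn). Parse errors name the offending
line and never drop data silently. Per-subject pipeline failures are
recorded in the output row (`error` column) without aborting the batch.
Every result file carries the configuration hash and seed in a `#` header
line; identical configuration and seed reproduce byte-identical files.

## Problem sizes used in validation

Estimator-recovery suites use n = 9000-beat series (the scale of a 90-min
adolescent recording) with 10–50 seed replicates per claim; cohort
calibration uses the full 166-subject design with 100–1000 replicates
(drawn at the measure level, which keeps the suites light); end-to-end
pipeline tests run single 60–120-min recordings through every stage.

## Known limitations

* The α₂ upper bound (64 beats) and the SampEn parameters (m = 2,
  r = 0.15·SD) are field-standard defaults, not uniquely determined; both
  are config-exposed and results at other settings are not interchangeable.
* The FFT route estimates the spectrum of the interpolated series; very
  high artifact rates distort the interpolation before filtering can help.
* DFA exponents near the estimator bias floor (white-noise series fitted
  from 4 beats) are reported uncorrected.
* Group comparison assumes equal variances (pooled t/F); Cohen's d is not
  bias-corrected (no Hedges' g).
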