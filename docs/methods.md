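# Methods

This note records the models, conventions and numerical choices behind
`budwormsync`, in the order the pipeline runs them.

## Synthetic site generator

The generator produces the coupled data the analysis assumes, with known
ground truth.

**Outbreak forcing.** Relative adult-moth abundance is a rectified sinusoid
of period `outbreak_period` (default 32 yr, inside the historical 30–40 yr
return interval) plus AR(1) noise (lag-1 coefficient 0.3, marginal sd 0.15),
floored at zero and scaled to peak at 1. The rectification constant is
chosen as `c = (cos(πD/P) − θ)/(1 − θ)` so that, without noise, the
population sits at or above the outbreak threshold θ (0.25) for exactly
`outbreak_duration` D years (default 14) of each period. Outbreak years are
the years at or above θ.

**Tree rings.** Each of 25 trees germinates 30–60 yr before 1900 (so the
age trend is exercised and the 1900–2019 window is fully covered) and grows
as `width = age_trend × (1 − depth·pop(t − lag)) × lognormal noise`, with a
negative-exponential age trend, suppression depth 0.5 at peak population, a
per-tree response lag drawn uniformly from {2, 3, 4} yr, and mean-one
lognormal noise (σ = 0.15). With these settings the mean inter-series
correlation of the detrended set is ≈ 0.5.

**Sediment.** Annual scale deposition is Poisson with mean
`area × (background + yield·pop)` (30 cm², 2 and 50 scales·cm⁻²·yr⁻¹). The
realized annual counts are then split across contiguous subsamples (default
3 yr of deposition each, constant sedimentation 0.2 cm/yr) by exact year
overlap, so the record conserves the realized total by construction. The
²¹⁰Pb profile is built on the same (optionally age-jittered) boundaries
under constant ²¹⁰Pb flux, with the deepest interval absorbing the residual
inventory; a CRS fit therefore recovers the boundary ages exactly when the
jitter is zero. The yield constant is arbitrary: no quantitative
scale-flux-to-population calibration exists, and none of the downstream
statistics depend on it.

**What it does not emulate:** spatial moth dispersal, host mortality and
recruitment, sediment mixing/bioturbation, inter-lake taphonomy, or
non-constant sedimentation. Passing recovery tests therefore show the
pipeline's correctness under its own assumptions, not robustness to every
process in real lakes.

## Tree-ring chronologies

* **Detrending.** Ratio standardization (RWI = width / fit) against a
  second-derivative-penalty smoothing spline. The penalty is set from the
  target wavelength by `λ = (w/2π)⁴`, which gives the conventional 50%
  amplitude response at w = 60 yr (the transfer function of this spline
  family is `1/(1 + λ(2πf)⁴)`). Series shorter than w/2 are detrended with
  a fitted negative exponential (falling back to the horizontal mean when
  the fit degenerates), which avoids overfitting short series.
* **Averaging.** Tukey's biweight robust mean (c = 9, median/MAD start);
  the arithmetic mean is available via `robust=False`.
* **r̄** is the mean pairwise Pearson correlation over pairwise-complete
  overlaps of at least 30 yr; shorter overlaps are excluded to stabilize the
  estimate. Negative r̄ is clamped to 0 (with a warning) inside EPS/SSS.
* **Stripping** is greedy leave-one-out: repeatedly remove the series whose
  removal most increases EPS over the target period, stop when no removal
  helps. Ties are broken by removing the shorter series, which keeps
  replication depth. The procedure is deterministic and, by construction,
  never returns an EPS below the full set's.

## Growth suppression and defoliation

GSI follows the host/non-host correction; without a non-host chronology the
standardized host series is used directly. nGSI is the z-scored GSI
(exactly mean 0, sd 1); a perfectly corrected (constant) GSI yields an
all-zero nGSI rather than an error. Defoliation events use the documented
defaults of the tree-ring defoliation method: ≥ 8 consecutive years of
negative nGSI containing at least one year ≤ −1.28 sd. Two interpretation
choices are exposed as flags and enabled by default, matching the pipeline's
purpose of capturing the ongoing outbreak: *bridging* merges qualifying runs
separated by a recovery gap shorter than the duration threshold, and
*series-end* accepts a terminal run that reaches the depth threshold
regardless of duration. Percent affected counts a tree as recording in any
year with a measured ring (no partial-year proration).

## CRS dating and annualization

Unsupported ²¹⁰Pb inventories are interval activities times interval dry
mass (exact for interval-mean measurements); ages are
`t(z) = λ⁻¹ ln(I₀/I(z))` with the half-life fixed at 22.3 yr. Supported
activity is either supplied, taken as zero (profile already corrected), or
estimated as the mean of the deep plateau (< 5% of surface activity). Ages
are clipped at 150 yr — beyond that the residual inventory is within
measurement noise of zero and CRS ages diverge.

Annualization assigns each dated subsample an accumulation rate
`count/(area·span)` and each calendar year `[y, y+1)` the overlap-weighted
sum of the rates covering it (half-open convention, so nothing is double
counted). When spans tile the record the total count is conserved to
floating-point precision; partially covered edge years are trimmed. Gaps in
the dated spans raise an error, since they indicate a broken age model.

## GAM smoothing

Before wavelet analysis each annual series is smoothed with a Gaussian
penalized cubic B-spline (k = 30 basis functions, second-derivative
penalty). The smoothing parameter minimizes the closed-form Gaussian REML
score `V(λ) = (n−M₀)·log(RSS + λβᵀSβ) + log|XᵀX + λS| − log|λS|₊`
(M₀ = 2, the penalty null space). Because V can be multimodal in log λ for
strongly periodic signals, a coarse grid scan (log λ ∈ [−15, 25], step 1)
precedes local refinement. The fit reproduces mgcv's REML B-spline fit to
within ~10⁻⁴ rms on shared inputs (cross-checked in the test suite).
Diagnostics: effective degrees of freedom, Shapiro–Wilk residual normality,
residual lag-1 autocorrelation, R². Note the minimum edf is 2 (the penalty
null space is a line), so "shrinks to the mean" reads as edf → 2 here.
Single-point outliers can be removed and linearly interpolated per site
before smoothing (`impute_years`), for records where one value distorts the
fit.

## Wavelet analysis

* **Transform.** Zero-padded (next power of two) FFT implementation of the
  continuous Morlet transform, ω₀ = 6, dt = 1 yr, s0 = 2 yr, dj = 1/12,
  J = log₂(N/s0)/dj. Fourier period = `4πs/(ω₀+√(2+ω₀²))` ≈ 1.033 s; the
  cone of influence is the √2·s e-folding distance from each edge. Input
  series are mean-removed and variance-normalized; the original variance is
  kept on the product.
* **Red-noise background.** The AR(1) coefficient is estimated as
  `(r₁ + √r₂)/2` (the lag-2 correction; falls back to r₁ when r₂ ≤ 0). The
  CWT significance level at each scale is `P(f)·χ²₂(0.95)/2` with P the
  AR(1) spectrum; significance is reported as the power/level ratio.
* **XWT.** `W_XY = W_X·conj(W_Y)`; positive phase means the first series
  leads. Cross power is tested against
  `Z₂(0.95)/2·√(P_X P_Y)` with Z₂(0.95) = 3.999 (the 95% point of the
  product distribution for two complex-wavelet χ²₂ variables).
* **WTC.** `R² = |S(s⁻¹W_XY)|² / (S(s⁻¹|W_X|²)·S(s⁻¹|W_Y|²))` with S a
  Gaussian time filter (sd = scale) applied in the Fourier domain composed
  with a 0.6-octave boxcar along scale (14 points at dj = 1/12). The 95%
  level per scale is the empirical quantile of R² over COI-interior cells of
  AR(1) surrogate pairs matching both series' estimated coefficients
  (default 1000 pairs; the seed is mandatory, making runs reproducible).
  Both type-I rates calibrate to ≈ 5% on AR(1) nulls (verified by
  simulation in the acceptance tests).

## Phase pooling and agreement calls

Phases are pooled from either the significant-XWT zone (ratio > 1) or the
high-coherence zone (R² ≥ 0.80), always intersected with the cone of
influence — interpretation is restricted to the edge-unaffected region.
Circular mean = atan2 of the mean sine/cosine; circular SD = √(−2 ln R̄).
Windows are fixed as published: O1 1975–1992, O2 1946–1959, O3 1912–1929,
All 1900–2019, inclusive. The continuous mean phase is collapsed to a binary
call by the sign of its cosine (nearest hemisphere): scales~GSI agrees when
anti-phase, scales~pctAff agrees when in-phase; an empty zone yields "–".
The hemisphere rule is the minimal assumption consistent with reporting
binary calls from continuous circular means; lead/lag (±π/2) information is
retained in the reported mean phase for sensitivity checks.

## Problem sizes

The test suite and the acceptance script run the full study window
(N = 120 yr) throughout. Type-I calibration uses 200 AR(1) test pairs
(a = 0.5, N = 120); because the coherence null level depends only on the
AR(1) coefficients and the length, it is estimated once (1000 surrogate
pairs in the acceptance script, 400 in the test suite) and the test pairs
are scored against it. Pipeline-level tests use 50–200 Monte Carlo
surrogates per coherence; the acceptance script and the worked example use
the full 1000.

## Known limitations

* No error propagation from ²¹⁰Pb dating uncertainty into the annual series
  (the synthetic jitter parameter exists precisely to study this, but the
  analysis itself treats CRS ages as exact).
* Only the CRS age-model family is implemented (no CIC or Bayesian ²¹⁰Pb),
  and only the Morlet wavelet.
* The XWT product-distribution quantile is tabulated at α = 0.05 only.
* Cross-dating verification is out of scope: input ring-width series are
  assumed correctly dated.
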