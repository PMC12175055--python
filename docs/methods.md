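# Methods

This note documents the statistical machinery, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
establish.

## 1. Sea-ice phenology covariates

Daily sea-ice concentration (SIC, percent) on a regular lat/lon grid is
reduced per season to ten covariates. A season runs from calendar day 46
(February 15, near the climatological extent minimum) to day 45/46 of the
following year; day-of-window values are 1-based, and
`SeasonWindow.window_day_to_doy` converts to the 46…410/411 day-of-year
axis.

Definitions and conventions:

* **Extent** is the summed area of cells with SIC ≥ 15 %; **area** is the
  concentration-weighted sum. Cell areas use the spherical-rectangle
  formula at cell centers with Earth radius 6371 km.
* **Polygon presence** is area-weighted mean SIC ≥ 15 %. All 15 %
  comparisons are inclusive, including the advance rule ("exceeded" is
  read as ≥ for internal consistency); both threshold and rule are
  configurable.
* **Advance** is the first day of the first run of ≥ 5 consecutive
  presence days (applied to the polygon aggregate, not per cell).
  **Retreat** is the day after the last presence day — the first day the
  region stays below threshold to the season's end. If ice never drops
  below threshold, advance/retreat saturate at the window limits. An
  iceless season (or one whose presence never persists 5 days) records
  advance = retreat = window end, duration 0, persistence 0.
* **Duration** = retreat − advance; **persistence** = 100 × (presence days
  in [advance, retreat)) / duration. The two differ when the ice edge
  oscillates.
* Extrema days are the first day attaining the extremum; all-missing days
  propagate NaN and are excluded; interior gaps of ≤ 2 days are linearly
  interpolated, larger gaps are an error.

PCA operates on the correlation matrix (columns standardized internally,
standardization stored so later seasons can be projected). Implementation
is an SVD of the standardized table; the test oracle is an independent
eigendecomposition. Sign convention: each loading vector's
largest-magnitude element is positive. Zero-variance columns are rejected
at the API level; the pipeline drops them with a logged notice first,
because a synthetic (or heavily iced) region can make "minimum extent"
identically zero.

## 2. The multi-species Gompertz count model

See the README for the model. Parameterization choices:

* **Lagged counts** enter as `ỹ = (log(y+1) − center)/scale`. A Gompertz
  model is log-linear, so raw-count lags would make ν scale-dependent.
  The fitter accepts per-species sample standardization (default for
  observed data) or explicit constants; the synthetic generator cannot
  standardize by statistics of a series it has not yet generated, so it
  uses explicit constants (default `center = log(y0+1)`, `scale = 1`) and
  the recovery experiments hand those same constants to the fitter. One
  convention, exposed in both configs.
* **Initial condition**: `log x_{s,1}` is a free parameter with prior
  N(log(y_{s,1}+1), 10²).
* **Priors**: ᾱ ~ N(0, precision 0.01), i.e. variance 100 (precision
  convention); σ_α ~ U(0, 2); every variance (σ²_δ, σ²_ε,s, slab variances
  σ²_ν, σ²_γ) ~ InverseGamma(shape 1, scale 0.001), equivalently
  Gamma(1, rate 0.001) on the precision; ι ~ Beta(2, 8); r_s ~ U(0, 50).
* The InverseGamma(1, 0.001) slab makes the marginal prior of a
  coefficient a Student-t with 2 degrees of freedom and scale
  √0.001 ≈ 0.032. For a *single* moderate effect this is informative: a
  coefficient of −0.1 is shrunk by roughly half toward zero and its
  credible interval narrows accordingly. With several coefficients sharing
  a slab (the realistic multi-covariate setting) the shrinkage relaxes.
  The recovery experiments keep this prior deliberately — it is part of
  the model — and their results must be read as properties of the full
  Bayesian procedure, not of a flat-prior likelihood analysis.
* **Missing survey years** are latent NB draws, imputed every sweep, and
  the year axis is never compacted.
* **Overall ICC** across species is per-draw σ²_δ/(σ²_δ + mean_s σ²_ε,s);
  a multi-species aggregate has no canonical definition and this one
  reduces to the per-species ICC when variances are equal.
* The interaction-significance screen (95 % CI excluding 0 and ≥ 96 % of
  posterior mass sharing the mean's sign) is reported as a flag; it never
  triggers automatic refits.

### Sampler

A purpose-built Metropolis-within-Gibbs sampler; all chains advance as one
vectorized batch with jittered initial states.

1. **Latent path** `u = log x`: single-site random-walk Metropolis,
   vectorized over species and chains with a checkerboard over years (a
   site interacts only with its two neighbors given the rest).
2. **Partially collapsed coefficient updates.** The shared year effect δ
   is collinear with any covariate effect shared across species, and
   σ²_δ has a funnel at zero. Both pathologies disappear when δ is
   *marginalized out* of the Gaussian increment layer: per year the
   residual vector across species has covariance
   C = σ²_δ·11ᵀ + diag(σ²_ε), handled by Woodbury. α (jointly, S×S
   Cholesky), every ν and γ (Kuo–Mallick: conjugate slab draw plus the
   indicator's Bernoulli full conditional), and the variances (log-scale
   Metropolis on the marginal likelihood) all condition on this
   δ-marginal form; δ itself is redrawn from its exact full conditional at
   the end of each sweep, preserving the correct joint distribution.
3. **ASIS interweaving.** The centered path/variance coupling mixes
   slowly, so each sweep also makes non-centered (ancillarity–sufficiency)
   moves: holding standardized residuals fixed, a variance proposal
   rescales the innovations — and hence the whole latent path — and is
   accepted against the NB likelihood. One move per species variance, one
   for the shared variance.
4. `σ_α`, `r_s` and missing counts use random-walk/independence
   Metropolis. Proposal scales adapt (Robbins–Monro, target 0.44) during
   burn-in only, preserving detailed balance afterwards.

Validation: posterior distributions were checked against JAGS on identical
data and model (coefficients matching to three decimals), and a prior-only
run (likelihood disabled) reproduces the ι and r priors — this check ships
as an acceptance test. Convergence is monitored by split-R̂ on α, variances,
r and ι; a fit with any R̂ ≥ 1.05 is flagged, not discarded.

Profiles: the full profile is 4 chains × 200,000 iterations, 100,000
burn-in, thinning 100 (4,000 retained draws); the reduced profile used by
tests and the replicate experiments is 4 × 5,000 / 2,500 / thin 5 (2,000
retained draws).

### Derived quantities

WAIC = −2(lppd − p_waic) with p_waic the summed pointwise posterior
variances of the log-likelihood (cross-checked against arviz). The
posterior predictive check draws one replicate dataset per retained draw
and reports the fraction whose RMSE against that draw's expected counts is
below the observed RMSE. Geometric-mean growth is
λ = (E[y_T]/E[y_1])^{1/(T−1)} per draw. Covariate contributions C_δ, C_ε,s
use posterior-mean variances from paired fits (without/with covariates);
negative values from sampling noise are reported and flagged, never
clipped.

## 3. Synchrony statistics

Kendall's W uses the rank-sum form with tie correction (fully tied series
stay in, entering through the correction); ρ̄ averages all pairwise Pearson
correlations; φ = Var(Σᵢyᵢ)/(ΣᵢSD(yᵢ))². Log differences use ln(y), falling
back to ln(y+1) when zeros are present (logged). Permutation tests shuffle
each series' time order independently (cyclic shifts available by flag),
one-sided, with the add-one rule p = (1+#{≥obs})/(n_perm+1); the survey-scale
default is 4,999 permutations. Differenced series are permuted directly —
the statistic's input is what the null should scramble.

## 4. Wavelets

Morlet ω₀ = 6 by FFT with zero padding; Fourier factor 1.033, COI at the
√2·s e-folding. Scale grid: 2 to 8 years, dj = 1/12. Coherence smoothing is
a time-Gaussian with SD equal to the scale and a 0.6-octave boxcar across
scales (the only free choices in coherence; configurable). The multivariate
modulus ratio smooths |ΣWᵢ| and Σ|Wᵢ| with a scale-proportional Gaussian.
Significance for power and coherence comes from AR(1) surrogates matched to
the series' lag-1 autocorrelation and variance (300 by default), giving one
null mechanism for all three quantities instead of the chi-square form that
covers power only. The 8-year high-pass Gaussian filter is calibrated so
the transfer function is exactly ½ at the cutoff period
(σ = P√(ln2)/(π√2)), uses reflection padding, and normalizes to mean 0,
SD 1 (constant input returns zeros with a notice).

## 5. Trends

MM regression: S-estimate by 2-point subsampling (all pairs when few,
otherwise 50 seeded draws) with bisquare ρ, c = 1.548, breakdown 50 %,
refined by S-IRLS; then an M-step with bisquare ψ at c = 4.685 (95 %
Gaussian efficiency) holding the S-scale fixed. Everything is vectorized
across bootstrap replicates. The parametric bootstrap resamples Gaussian
noise at the robust scale inflated by √(n/(n−2)) — the usual correction
for residuals of a two-parameter fit — refits MM per replicate, and reports
percentile intervals for the slope and the derived percent declines,
100(1 − e^{slope·span}). Percentile intervals from this procedure run
slightly below nominal on small Gaussian samples (~90–92 % at 20–48
points in our simulations); the coverage experiment reports the honest
number.

The Poisson GAM uses a cubic B-spline basis (10 interior knots by default,
evenly spaced) with a second-order difference penalty as a multivariate
normal precision τ·D₂ᵀD₂ and τ ~ Gamma(1, 0.001), fitted by MCMC
(coefficient-wise random-walk Metropolis exploiting the basis' local
support, Gibbs for τ) so the package keeps one inference style. Unobserved
years stay on the prediction grid, so credible bands widen at survey gaps.
As τ → ∞ the fit collapses to the penalty null space (a straight line in
log mean) — checked with a pinned τ.

## 6. What the synthetic data do and do not show

The count generator *is* the fitted model, so recovery experiments test
inference, not model adequacy: real census data add observer effects,
effort changes and non-NB dispersion the generator does not emulate. The
SIC generator produces trapezoidal seasonal cycles (threshold crossings
placed exactly on prescribed advance/retreat days) with AR(1) noise
(coefficient 0.8 by default) and an optional latitudinal gradient; it makes
no attempt to mimic real spatial covariance, so phenology tests establish
correctness of the day-counting rules, not remote-sensing robustness.

Two results of the replicate experiments deserve emphasis, both verified
against JAGS as properties of the model rather than of this
implementation: with a *single* moderate covariate (−0.103) the t₂-slab
prior shrinks the estimate and can push 95 % CI coverage of the fixed truth
well below 95 %; and with 40 years and a free NB dispersion the split of
year-to-year variance between process and observation noise is weakly
identified, so the posterior-mean ICC scatters widely around its
generating value. Both effects shrink as series lengthen or covariates
share the slab.

## 7. Problem sizes

Replicate experiments use 20 datasets of 3 species × 40 years at the
reduced MCMC profile; bootstrap coverage uses 400 datasets of 48 points
with 299 bootstrap replicates; permutation nulls use 4,999 permutations at
survey scale and 199–999 in property tests; wavelet fixtures use 48–96
point series. These sizes are the package's chosen trade-off between
Monte-Carlo error and a test suite that runs in minutes.
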