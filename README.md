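# sealsync

Tools for asking how sympatric, ice-associated predator populations respond
to a shared, fluctuating sea-ice environment. The package grew out of the
analysis pattern used for multi-decadal seal censuses in the Southern Ocean
— three species counted annually at one island, with the regional sea-ice
season as the common driver — but every stage is generic: it takes a
species × year count matrix and daily gridded sea-ice concentration, and
returns sea-ice phenology covariates, Bayesian estimates of density
dependence, covariate effects and between-species synchrony, classical
synchrony statistics with permutation tests, wavelet coherence, and robust
long-term trends.

## The model at the core

Counts follow a multi-species stochastic Gompertz model with
negative-binomial observation error. For species *s* in year *t*, with
latent expected count *x*ₛ,ₜ:

    yₛ,ₜ ~ NB(rₛ, pₛ,ₜ),   pₛ,ₜ = rₛ / (rₛ + xₛ,ₜ)
    log xₛ,ₜ − log xₛ,ₜ₋₁ = αₛ + Σⱼ νⱼ,ₛ ỹⱼ,ₜ₋₁ + zₜᵀγₛ + δₜ + εₜ,ₛ

* `αₛ` — intrinsic growth (hierarchical across species),
* `νⱼ,ₛ` — interactions on the lagged log count ỹ; the diagonal is Gompertz
  density dependence,
* `zₜᵀγₛ` — sea-ice covariate effects (principal components of ten
  per-season phenology covariates: days of advance/retreat, season
  duration, persistence, and the timing and size of extent/area extrema),
* `δₜ ~ N(0, σ²_δ)` — the year effect **shared** by all species
  (synchronous variation),
* `εₜ,ₛ ~ N(0, σ²_ε,ₛ)` — species-specific (asynchronous) year effects.

Synchrony is the intra-class correlation
`ICCₛ = σ²_δ / (σ²_δ + σ²_ε,ₛ)`, and the contribution of sea-ice covariates
to it is `C_δ = 1 − σ̂²_δ(residual) / σ̂²_δ(total)` between fits with and
without the covariates. Coefficients can carry Kuo–Mallick indicators
(`θ = I·coef`, `I ~ Bernoulli(ι)`, `ι ~ Beta(2, 8)`) for stochastic-search
variable selection. Inference is a purpose-built Metropolis-within-Gibbs
sampler (see `docs/methods.md`), cross-validated against JAGS.

Around the core model: Kendall's *W*, mean pairwise correlation and the
Loreau–de Mazancourt φ with permutation nulls (`synchrony`), Morlet wavelet
power/coherence/multivariate modulus ratio with red-noise significance
(`wavelets`), and MM robust trend regression with parametric bootstrap plus
a Bayesian P-spline Poisson GAM (`trends`). A synthetic-data generator
(`synthetic`) simulates both the count model and daily sea-ice fields with
known truth, so the whole chain is testable without any downloads.

## Worked example

```python
import numpy as np
from sealsync import gompertz, synthetic

# simulate 3 species for 40 years with a shared sea-ice effect of -0.103
rng = np.random.default_rng(11)
z = rng.standard_normal((40, 1)); z = (z - z.mean(0)) / z.std(0)
scenario = synthetic.SimScenario(
    n_species=3, n_years=40, nu=np.eye(3) * -0.15, gamma=-0.103,
    sigma_delta2=0.04, sigma_eps2=0.04, r=20.0, y0=1000.0,
    covariates=z, seed=42)
counts, truth = synthetic.gen_counts(scenario)

spec = gompertz.ModelSpec.build(
    n_species=3, n_cov=1, share_covariates=True,
    lag_transform=(np.log(1001.0), 1.0), standardize_covariates=False)
samples, summary = gompertz.run_mcmc(
    counts, z, spec, config=gompertz.MCMCConfig.reduced(seed=7))

g = samples.stacked("gamma")[:, 0]
print(f"shared ice effect: {g.mean():+.3f} "
      f"[{np.quantile(g, 0.025):+.3f}, {np.quantile(g, 0.975):+.3f}]")
print(f"overall ICC (synchrony): {summary.icc_overall:.3f}")
print(f"posterior predictive p: {summary.bayes_pvalue:.2f}; "
      f"max split-Rhat: {summary.max_rhat:.2f}")
```

prints (seed 7, reduced MCMC profile):

```
shared ice effect: -0.082 [-0.133, -0.021]
overall ICC (synchrony): 0.242
posterior predictive p: 0.55; max split-Rhat: 1.13
```

The credible interval covers the simulated effect (−0.103); the posterior
mean is pulled toward zero by the adaptive Student-t-like slab prior on γ —
expected behavior for a lone moderate effect (see `docs/methods.md`). An
ICC below the generating 0.5 reflects the genuine weak identification of
process versus observation variance at 40 years with a free NB dispersion.
A full config-driven run (`sealsync run --seed 1 --out demo/`) chains
simulation, phenology, PCA, fitting, synchrony, wavelets and trends, and
writes a manifest with every stage seed.

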