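"""Bayesian multi-species Gompertz count models with indicator selection.

The model, for species ``s`` and year ``t`` (T years, S species):

    y[s,t] ~ NB(r_s, p[s,t]),   p = r_s / (r_s + x[s,t])
    log x[s,t] - log x[s,t-1] = alpha_s + sum_j nu[j,s] ylag[j,t-1]
                                + z[t].gamma_s + delta_t + eps[t,s]

``delta_t ~ N(0, sigma_delta^2)`` is the year effect shared by every
species (synchronous variation); ``eps[t,s] ~ N(0, sigma_eps_s^2)`` is
species-specific (asynchronous).  The intra-class correlation
``ICC_s = sigma_delta^2 / (sigma_delta^2 + sigma_eps_s^2)`` measures the
synchrony of species ``s`` with the rest.  ``ylag`` is the lagged count on
the log scale (centered/scaled, see :class:`ModelSpec.lag_transform`), so
``nu[s,s]`` is Gompertz density dependence and off-diagonal ``nu`` are
species interactions.  Covariate and interaction coefficients can carry
Kuo-Mallick indicators ``theta = I * coef`` with ``I ~ Bernoulli(iota)``,
``iota ~ Beta(2, 8)``, giving stochastic-search variable selection.

Inference is Metropolis-within-Gibbs: single-site random-walk Metropolis on
the latent log-mean path (checkerboard over years, vectorized over species
and chains); partially collapsed conjugate draws for alpha, nu, gamma and
the indicators with delta marginalized out of the Gaussian increment layer
(delta itself is redrawn from its exact full conditional each sweep);
marginal-likelihood Metropolis plus non-centered ASIS rescaling moves for
the year-effect variances; and random-walk Metropolis for sigma_alpha, the
NB dispersions r_s, and latent missing counts.  Proposal scales adapt
toward 44 % acceptance during burn-in only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .synthetic import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GammaTerm",
    "ModelSpec",
    "PriorSet",
    "MCMCConfig",
    "PosteriorSamples",
    "FitSummary",
    "ContributionResult",
    "nb_loglik",
    "linear_predictor",
    "run_mcmc",
    "inclusion_probabilities",
    "compute_icc",
    "covariate_contribution",
    "compute_waic",
    "posterior_predictive_pvalue",
    "geometric_lambda",
]


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class GammaTerm:
    """One covariate coefficient: column ``cov`` of z, shared by ``species``."""

    name: str
    cov: int
    species: tuple
    selectable: bool = True


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the linear predictor and the selection layer.

    ``interactions`` lists (j, s) pairs whose ``nu[j, s]`` is in the model;
    diagonal (density-dependence) pairs are always added.  ``lag_transform``
    is either ``"sample"`` (per-species standardization of observed
    log(y+1)) or an explicit ``(center, scale)`` pair of per-species arrays
    shared with the data generator.
    """

    covariate_terms: tuple = ()
    interactions: tuple = ()            # off-diagonal (j, s) pairs
    selection_enabled: bool = False
    select_diagonal: bool = True
    single_species: bool = False
    lag_transform: object = "sample"
    standardize_covariates: bool = True
    likelihood: bool = True             # False = prior-only sampler check

    @staticmethod
    def build(n_species: int, n_cov: int, share_covariates: bool = True,
              interactions="diagonal", selection: bool = False,
              lag_transform="sample", likelihood: bool = True,
              select_diagonal: bool = True,
              standardize_covariates: bool = True) -> "ModelSpec":
        every = tuple(range(n_species))
        if share_covariates:
            terms = tuple(
                GammaTerm(f"gamma_z{k + 1}", k, every) for k in range(n_cov)
            )
        else:
            terms = tuple(
                GammaTerm(f"gamma_z{k + 1}_s{s + 1}", k, (s,))
                for k in range(n_cov) for s in range(n_species)
            )
        if interactions == "diagonal":
            pairs: tuple = ()
        elif interactions == "all":
            pairs = tuple((j, s) for j in range(n_species)
                          for s in range(n_species) if j != s)
        else:
            pairs = tuple(tuple(p) for p in interactions)
        for term in terms:
            if len(term.species) < 1:
                raise ValueError("gamma term with empty species set")
        return ModelSpec(
            covariate_terms=terms,
            interactions=pairs,
            selection_enabled=selection,
            select_diagonal=select_diagonal,
            single_species=n_species == 1,
            lag_transform=lag_transform,
            likelihood=likelihood,
            standardize_covariates=standardize_covariates,
        )


@dataclass(frozen=True)
class PriorSet:
    """Priors: alpha_bar ~ N(0, precision 0.01) i.e. variance 100;
    sigma_alpha ~ U(0, 2); all variances InverseGamma(shape 1, scale 0.001);
    iota ~ Beta(2, 8); r_s ~ U(0, 50); initial log mean ~ N(anchor, 10^2)."""

    alpha_bar_mean: float = 0.0
    alpha_bar_var: float = 100.0
    sigma_alpha_max: float = 2.0
    ig_shape: float = 1.0
    ig_scale: float = 0.001
    iota_a: float = 2.0
    iota_b: float = 8.0
    r_max: float = 50.0
    x0_sd: float = 10.0


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 4
    n_iter: int = 200_000
    n_burn: int = 100_000
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.n_burn:
            raise ValueError("n_iter must exceed n_burn")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @staticmethod
    def reduced(seed: int = 0, n_chains: int = 4) -> "MCMCConfig":
        """Short test profile: 5,000 iterations, half burn-in, thin 5."""
        return MCMCConfig(n_chains=n_chains, n_iter=5_000, n_burn=2_500,
                          thin=5, seed=seed)

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws, stacked as (chain, draw, ...) arrays."""

    draws: dict                      # name -> array
    term_names: list                 # gamma term names, order of gamma axis
    species: list
    years: np.ndarray
    spec: ModelSpec
    config: MCMCConfig
    pointwise_loglik: np.ndarray | None = None  # (chain, draw, n_obs_cells)
    obs_index: np.ndarray | None = None         # (n_obs_cells, 2) (s, t)

    def stacked(self, name: str) -> np.ndarray:
        """(chain*draw, ...) view of one parameter."""
        a = self.draws[name]
        return a.reshape((-1,) + a.shape[2:])


@dataclass
class FitSummary:
    mean: dict
    ci_low: dict
    ci_high: dict
    rhat: dict
    rhat_ok: bool
    max_rhat: float
    waic: float
    p_waic: float
    bayes_pvalue: float
    icc_species: np.ndarray
    icc_overall: float
    icc_ci: dict
    geometric_lambda: dict
    inclusion: dict | None


@dataclass
class ContributionResult:
    """Cdelta / Ceps_s = 1 - residual/total variance; negative values are
    kept (sampling noise) and flagged."""

    c_delta: float
    c_eps: np.ndarray
    total_delta2: float
    resid_delta2: float
    total_eps2: np.ndarray
    resid_eps2: np.ndarray
    negative_flag: bool


# ---------------------------------------------------------------------------
# likelihood pieces


def nb_loglik(y, mu, r):
    """Log pmf of NB with mean ``mu`` and dispersion ``r`` (var mu+mu^2/r).

    Success probability p = r/(r+mu).  Stable for large y via gammaln.
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    r = np.asarray(r, float)
    if np.any(mu <= 0):
        raise ValueError("nb_loglik requires mu > 0")
    if np.any(r <= 0):
        raise ValueError("nb_loglik requires r > 0")
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))


def _nb_ll_logmu(y, log_mu, r):
    """nb_loglik with log-mean input; vectorized, overflow-safe."""
    log_rmu = np.logaddexp(np.log(r), log_mu)
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * (np.log(r) - log_rmu) + y * (log_mu - log_rmu))


def _nb_ll_part(y, log_mu, r):
    """NB log-likelihood up to terms constant in log_mu (same y, r):
    valid for Metropolis ratios where only the mean changes."""
    log_rmu = np.logaddexp(np.log(r), log_mu)
    return y * log_mu - (y + r) * log_rmu


def linear_predictor(alpha, nu, gamma_effect, delta_t, eps_st, ylag, z_t=None):
    """One-year log-mean increment: alpha + nu.ylag + z.gamma + delta + eps.

    ``gamma_effect`` is the already-assembled covariate contribution
    ``z[t] . gamma_s`` (scalar or per-species vector); ``nu`` is the column
    nu[:, s] (or matrix for all species), ``ylag`` the transformed lagged
    counts.  Deterministic given its inputs.
    """
    nu = np.asarray(nu, float)
    ylag = np.asarray(ylag, float)
    if nu.ndim == 2:
        inter = nu.T @ ylag
    else:
        inter = float(nu @ ylag)
    return alpha + inter + gamma_effect + delta_t + eps_st


# ---------------------------------------------------------------------------
# sampler internals


class _AdaptiveScale:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    def __init__(self, shape, init=0.2, target=0.44):
        self.log_s = np.full(shape, np.log(init))
        self.target = target

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, accepted, it):
        rate = 1.0 / max(20, it) ** 0.6
        self.log_s += rate * (np.asarray(accepted, float) - self.target)
        np.clip(self.log_s, -12.0, 4.0, out=self.log_s)


def _lag_constants(y, observed, spec: ModelSpec):
    S = y.shape[0]
    if spec.lag_transform == "sample":
        center = np.empty(S)
        scale = np.empty(S)
        for s in range(S):
            v = np.log(y[s, observed[s]] + 1.0)
            center[s] = v.mean()
            sd = v.std(ddof=0)
            scale[s] = sd if sd > 0 else 1.0
        return center, scale
    center, scale = spec.lag_transform
    return (np.broadcast_to(np.asarray(center, float), (S,)).copy(),
            np.broadcast_to(np.asarray(scale, float), (S,)).copy())


class _Chains:
    """Batched state and update sweeps for all MCMC chains at once.

    Every state array carries a leading chain axis; proposals, acceptance
    decisions and Gibbs draws are vectorized across chains (each chain
    consumes its own independent slice of the shared random stream, so the
    chains remain statistically independent).  Initial states are jittered
    per chain.
    """

    def __init__(self, y, observed, z, spec, priors, rng, n_chains):
        self.rng = rng
        self.spec = spec
        self.pr = priors
        self.obs = observed
        S, T = y.shape
        C = n_chains
        self.C, self.S, self.T = C, S, T
        y0 = y.astype(float).copy()
        # fill unobserved cells from row means before chains diverge
        for s in range(S):
            if not observed[s].all():
                fill = y0[s, observed[s]].mean() if observed[s].any() else 1.0
                y0[s, ~observed[s]] = max(round(fill), 0)
        self.y = np.broadcast_to(y0, (C, S, T)).copy()
        self.z = z  # (T, K) already standardized by run_mcmc
        self.center, self.scale = _lag_constants(y0, observed, spec)

        # nu structure: diagonal always present, plus requested off-diagonals
        pairs = [(s, s) for s in range(S)] + [tuple(p) for p in spec.interactions]
        self.nu_pairs = pairs
        self.nu_select = np.array([
            spec.selection_enabled and (spec.select_diagonal or p[0] != p[1])
            for p in pairs
        ])
        self.terms = list(spec.covariate_terms)
        self.g_select = np.array([
            spec.selection_enabled and t.selectable for t in self.terms
        ])

        # initial state, jittered per chain for overdispersed starts
        anchor = np.where(observed[:, 0], np.log(y0[:, 0] + 1.0), 0.0)
        self.u0_mean = anchor
        self.u = np.log(self.y + 1.0) + 0.02 * rng.standard_normal((C, S, T))
        self.alpha = 0.02 * rng.standard_normal((C, S))
        self.alpha_bar = np.zeros(C)
        self.sigma_alpha = np.full(C, 0.5)
        self.nu_val = np.zeros((C, len(pairs)))
        self.nu_ind = np.ones((C, len(pairs)))
        self.gam_val = np.zeros((C, len(self.terms)))
        self.gam_ind = np.ones((C, len(self.terms)))
        self.iota = np.full(C, priors.iota_a / (priors.iota_a + priors.iota_b))
        self.delta = np.zeros((C, T))     # delta[:, 0] unused
        self.sig_d2 = 0.05 * np.exp(0.3 * rng.standard_normal(C))
        self.sig_e2 = 0.05 * np.exp(0.3 * rng.standard_normal((C, S)))
        self.sig_nu2 = np.ones(C)
        self.sig_g2 = np.ones(C)
        self.r = rng.uniform(0.3, 1.0, size=(C, S)) * priors.r_max

        self.step_u = _AdaptiveScale((C, S, T), init=0.1)
        self.step_sa = _AdaptiveScale((C,), init=0.3)
        self.step_r = _AdaptiveScale((C, S), init=2.0)
        self.step_vd = _AdaptiveScale((C,), init=0.8)
        self.step_ve = _AdaptiveScale((C, S), init=0.8)
        self.step_vd2 = _AdaptiveScale((C,), init=0.5)
        self.step_ve2 = _AdaptiveScale((C, S), init=0.5)
        self.missing = np.argwhere(~observed)

        self._refresh_lag()

    # cached design pieces -------------------------------------------------
    def _refresh_lag(self):
        self.ylag = (np.log(self.y + 1.0)
                     - self.center[None, :, None]) / self.scale[None, :, None]

    def _theta_nu(self):
        th = np.zeros((self.C, self.S, self.S))
        for k, (j, s) in enumerate(self.nu_pairs):
            th[:, j, s] = self.nu_ind[:, k] * self.nu_val[:, k]
        return th

    def _gamma_effect(self):
        """(C, S, T-1) covariate contribution to increments t=1..T-1."""
        eff = np.zeros((self.C, self.S, self.T - 1))
        zt = self.z[1:]  # (T-1, K)
        for k, term in enumerate(self.terms):
            th = self.gam_ind[:, k] * self.gam_val[:, k]
            rows = list(term.species)
            eff[:, rows, :] += th[:, None, None] * zt[:, term.cov][None, None, :]
        return eff

    def _mean_nodelta(self):
        """(C, S, T-1) increment mean without delta."""
        th = self._theta_nu()
        inter = np.einsum("cjs,cjt->cst", th, self.ylag[:, :, :-1])
        return self.alpha[:, :, None] + inter + self._gamma_effect()

    # update sweeps --------------------------------------------------------
    #
    # The synchronous year effect delta is *marginalized out* of every
    # coefficient and variance update (the Gaussian layer then has
    # cross-species covariance C = sigma_d2 * 11' + diag(sigma_e2) per
    # year) and redrawn from its exact full conditional at the end of the
    # sweep — a partially collapsed Gibbs scheme.  Without this, the shared
    # covariate effect and delta are nearly collinear and sigma_d2 gets
    # trapped in the zero-variance funnel.

    def _cinv_parts(self):
        """Woodbury pieces of C^-1 = diag(w) - c w w' per chain."""
        w = 1.0 / self.sig_e2                      # (C, S)
        c = self.sig_d2 / (1.0 + self.sig_d2 * w.sum(axis=1))
        return w, c

    def update_u(self, it, adapt):
        m = self._mean_nodelta() + self.delta[:, None, 1:]
        inv2se2 = 1.0 / (2.0 * self.sig_e2)[:, :, None]
        rate = 1.0 / max(20, it) ** 0.6
        for parity in (0, 1):
            cols = np.arange(parity, self.T, 2)
            u_old = self.u[:, :, cols]
            u_new = u_old + self.rng.standard_normal(u_old.shape) \
                * self.step_u.scale[:, :, cols]
            dlp = np.zeros(u_old.shape)
            if self.spec.likelihood:
                ll_old = _nb_ll_part(self.y[:, :, cols], u_old,
                                     self.r[:, :, None])
                ll_new = _nb_ll_part(self.y[:, :, cols], u_new,
                                     self.r[:, :, None])
                dlp += np.where(self.obs[None, :, cols], ll_new - ll_old, 0.0)
            has0 = cols[0] == 0
            if has0:
                d_old = u_old[:, :, 0] - self.u0_mean
                d_new = u_new[:, :, 0] - self.u0_mean
                dlp[:, :, 0] += (d_old**2 - d_new**2) / (2 * self.pr.x0_sd**2)
            cb = cols[1:] if has0 else cols          # t >= 1: increment at t
            ib = slice(1, None) if has0 else slice(None)
            base = self.u[:, :, cb - 1] + m[:, :, cb - 1]
            dlp[:, :, ib] += ((u_old[:, :, ib] - base) ** 2
                              - (u_new[:, :, ib] - base) ** 2) * inv2se2
            cf = cols[cols + 1 < self.T]             # increment at t+1
            jf = slice(None, cf.size)
            nxt = self.u[:, :, cf + 1] - m[:, :, cf]
            dlp[:, :, jf] += ((nxt - u_old[:, :, jf]) ** 2
                              - (nxt - u_new[:, :, jf]) ** 2) * inv2se2
            acc = np.log(self.rng.random(u_old.shape)) < dlp
            self.u[:, :, cols] = np.where(acc, u_new, u_old)
            if adapt:
                self.step_u.log_s[:, :, cols] += rate * (acc - self.step_u.target)
                np.clip(self.step_u.log_s, -12.0, 4.0, out=self.step_u.log_s)

    def update_missing(self):
        if self.missing.size == 0 or not self.spec.likelihood:
            return
        m = self._mean_nodelta() + self.delta[:, None, 1:]
        se = np.sqrt(self.sig_e2)                    # (C, S)
        inc = np.diff(self.u, axis=2)
        th = self._theta_nu()
        for s, t in self.missing:
            mu = np.exp(np.clip(self.u[:, s, t], -30, 30))
            lam = self.rng.gamma(self.r[:, s], mu / self.r[:, s])
            y_prop = self.rng.poisson(lam).astype(float)
            if t + 1 >= self.T:
                self.y[:, s, t] = y_prop
                continue
            yl_old = self.ylag[:, s, t]
            yl_new = (np.log(y_prop + 1.0) - self.center[s]) / self.scale[s]
            dm = th[:, s, :] * (yl_new - yl_old)[:, None]   # (C, S)
            e_old = (inc[:, :, t] - m[:, :, t]) / se
            e_new = (inc[:, :, t] - m[:, :, t] - dm) / se
            dlp = np.sum(e_old**2 - e_new**2, axis=1) / 2.0
            acc = np.log(self.rng.random(self.C)) < dlp
            self.y[:, s, t] = np.where(acc, y_prop, self.y[:, s, t])
            self.ylag[:, s, t] = np.where(acc, yl_new, yl_old)
            m[:, :, t] += np.where(acc[:, None], dm, 0.0)

    def update_delta(self, resid):
        """Exact full conditional of delta given everything else."""
        w, _ = self._cinv_parts()
        prec = 1.0 / self.sig_d2 + w.sum(axis=1)     # (C,)
        mean = np.einsum("cs,cst->ct", w, resid) / prec[:, None]
        self.delta[:, 1:] = mean + self.rng.standard_normal(mean.shape) \
            / np.sqrt(prec)[:, None]

    def _resid(self):
        """inc - mean_nodelta: year-effect residuals, delta not removed."""
        return np.diff(self.u, axis=2) - self._mean_nodelta()

    def _marginal_loglik(self, resid, sig_d2, sig_e2):
        """(C,) log N(resid_t; 0, sig_d2*11' + diag(sig_e2)) over years."""
        w = 1.0 / sig_e2
        a = 1.0 + sig_d2 * w.sum(axis=1)
        c = sig_d2 / a
        wres = np.einsum("cs,cst->ct", w, resid)
        quad = np.einsum("cs,cst->c", w, resid**2) - c * np.sum(wres**2, axis=1)
        n = resid.shape[2]
        logdet = np.sum(np.log(sig_e2), axis=1) + np.log(a)
        return -0.5 * (quad + n * logdet)

    def update_variances(self, resid, it, adapt):
        """Metropolis on log variances with delta marginalized out."""
        a, b = self.pr.ig_shape, self.pr.ig_scale

        def logprior_jac(v):
            # IG(a, b) prior density plus the log-scale proposal Jacobian
            return -a * np.log(v) - b / v

        ll = self._marginal_loglik(resid, self.sig_d2, self.sig_e2)
        # shared variance
        prop = self.sig_d2 * np.exp(self.rng.standard_normal(self.C)
                                    * self.step_vd.scale)
        ll_prop = self._marginal_loglik(resid, prop, self.sig_e2)
        dlp = (ll_prop + logprior_jac(prop)) - (ll + logprior_jac(self.sig_d2))
        acc_d = np.log(self.rng.random(self.C)) < dlp
        self.sig_d2 = np.where(acc_d, prop, self.sig_d2)
        ll = np.where(acc_d, ll_prop, ll)
        # species variances, one species at a time across chains
        acc_e = np.zeros((self.C, self.S))
        for s in range(self.S):
            prop_e = self.sig_e2.copy()
            prop_e[:, s] *= np.exp(self.rng.standard_normal(self.C)
                                   * self.step_ve.scale[:, s])
            ll_prop = self._marginal_loglik(resid, self.sig_d2, prop_e)
            dlp = (ll_prop + logprior_jac(prop_e[:, s])) \
                - (ll + logprior_jac(self.sig_e2[:, s]))
            acc = np.log(self.rng.random(self.C)) < dlp
            self.sig_e2[:, s] = np.where(acc, prop_e[:, s], self.sig_e2[:, s])
            ll = np.where(acc, ll_prop, ll)
            acc_e[:, s] = acc
        if adapt:
            self.step_vd.update(acc_d, it)
            self.step_ve.update(acc_e, it)

    def update_alpha(self, resid):
        """Joint Gibbs draw of alpha with delta marginalized out."""
        w, c = self._cinv_parts()
        cinv = w[:, :, None] * np.eye(self.S)[None] \
            - c[:, None, None] * np.einsum("ci,cj->cij", w, w)
        n = self.T - 1
        resid_plus = resid + self.alpha[:, :, None]
        P = n * cinv + np.eye(self.S)[None] / self.sigma_alpha[:, None, None]**2
        bvec = np.einsum("cij,cj->ci", cinv, resid_plus.sum(axis=2)) \
            + (self.alpha_bar / self.sigma_alpha**2)[:, None]
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, bvec[:, :, None])[:, :, 0]
        zdraw = self.rng.standard_normal((self.C, self.S, 1))
        noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), zdraw)[:, :, 0]
        alpha_new = mean + noise
        resid += (self.alpha - alpha_new)[:, :, None]
        self.alpha = alpha_new
        # alpha_bar
        prec_b = self.S / self.sigma_alpha**2 + 1.0 / self.pr.alpha_bar_var
        mean_b = (self.alpha.sum(axis=1) / self.sigma_alpha**2
                  + self.pr.alpha_bar_mean / self.pr.alpha_bar_var) / prec_b
        self.alpha_bar = mean_b + self.rng.standard_normal(self.C) \
            / np.sqrt(prec_b)
        return resid

    def update_sigma_alpha(self, it, adapt):
        prop = self.sigma_alpha + self.rng.standard_normal(self.C) \
            * self.step_sa.scale
        inside = (prop > 0.0) & (prop < self.pr.sigma_alpha_max)
        prop_safe = np.where(inside, prop, self.sigma_alpha)
        dev = np.sum((self.alpha - self.alpha_bar[:, None]) ** 2, axis=1)
        lp_old = -self.S * np.log(self.sigma_alpha) \
            - dev / (2 * self.sigma_alpha**2)
        lp_new = -self.S * np.log(prop_safe) - dev / (2 * prop_safe**2)
        acc = inside & (np.log(self.rng.random(self.C)) < lp_new - lp_old)
        self.sigma_alpha = np.where(acc, prop_safe, self.sigma_alpha)
        if adapt:
            self.step_sa.update(acc, it)

    def _km_update(self, resid, x, rows, k, vals, inds, sig2_slab, selectable):
        """Kuo-Mallick update of coefficient ``k`` shared by ``rows``.

        ``x`` is the (C, T-1) regressor applied identically to every row in
        ``rows``; resid holds the full residuals and is updated in place.
        The slab draw is conjugate Gaussian under the delta-marginal
        covariance; the indicator uses its Bernoulli full conditional.
        """
        w, c = self._cinv_parts()
        w_rows = w[:, rows]                          # (C, len(rows))
        W_r = w_rows.sum(axis=1)                     # (C,)
        theta_old = inds[:, k] * vals[:, k]
        sx2 = np.sum(x**2, axis=1)                   # (C,)
        sxx = (W_r - c * W_r**2) * sx2
        # weighted residual sums with the term's contribution restored
        wres_rows = np.einsum("cr,crt->ct", w_rows, resid[:, rows, :]) \
            + W_r[:, None] * theta_old[:, None] * x
        wres_all = np.einsum("cs,cst->ct", w, resid) \
            + W_r[:, None] * theta_old[:, None] * x
        direct = np.sum(x * wres_rows, axis=1)
        shared = W_r * np.sum(x * wres_all, axis=1)
        sxe = direct - c * shared
        on = inds[:, k] == 1.0
        V = 1.0 / (sxx + 1.0 / sig2_slab)
        noise = self.rng.standard_normal(self.C)
        val = np.where(on, V * sxe + noise * np.sqrt(V),
                       noise * np.sqrt(sig2_slab))
        ind = inds[:, k].copy()
        if selectable:
            dll = val * sxe - 0.5 * val**2 * sxx
            logit = np.log(self.iota / (1.0 - self.iota)) + dll
            log_p_on = np.where(logit >= 0,
                                -np.log1p(np.exp(-np.abs(logit))),
                                logit - np.log1p(np.exp(-np.abs(logit))))
            ind = (np.log(self.rng.random(self.C)) < log_p_on).astype(float)
        dtheta = ind * val - theta_old
        resid[:, rows, :] -= dtheta[:, None, None] * x[:, None, :]
        vals[:, k] = val
        inds[:, k] = ind

    def update_coefficients(self, resid):
        ylag0 = self.ylag[:, :, :-1]
        zt = self.z[1:]
        for k, (j, s) in enumerate(self.nu_pairs):
            self._km_update(resid, ylag0[:, j, :], [s], k, self.nu_val,
                            self.nu_ind, self.sig_nu2, self.nu_select[k])
        for k, term in enumerate(self.terms):
            x = np.broadcast_to(zt[:, term.cov], (self.C, self.T - 1))
            self._km_update(resid, x, list(term.species), k, self.gam_val,
                            self.gam_ind, self.sig_g2, self.g_select[k])
        # slab variances over all coefficients (spike draws included)
        a, b = self.pr.ig_shape, self.pr.ig_scale
        n_nu, n_g = self.nu_val.shape[1], self.gam_val.shape[1]
        if n_nu:
            self.sig_nu2 = 1.0 / self.rng.gamma(
                a + n_nu / 2.0,
                1.0 / (b + np.sum(self.nu_val**2, axis=1) / 2.0))
        if n_g:
            self.sig_g2 = 1.0 / self.rng.gamma(
                a + n_g / 2.0,
                1.0 / (b + np.sum(self.gam_val**2, axis=1) / 2.0))
        n_sel = int(self.nu_select.sum() + self.g_select.sum())
        if n_sel:
            k_on = self.nu_ind[:, self.nu_select].sum(axis=1) \
                + self.gam_ind[:, self.g_select].sum(axis=1)
            self.iota = self.rng.beta(self.pr.iota_a + k_on,
                                      self.pr.iota_b + n_sel - k_on)
        else:
            self.iota = self.rng.beta(self.pr.iota_a * np.ones(self.C),
                                      self.pr.iota_b)

    def _nb_ll_obs_sum(self, u, r):
        """(C,) NB log-likelihood over observed cells, constants dropped."""
        ll = _nb_ll_part(self.y, u, r[:, :, None])
        return np.sum(np.where(self.obs[None], ll, 0.0), axis=(1, 2))

    def update_variances_asis(self, it, adapt, resid):
        """Non-centered (ASIS) rescaling moves for the year-effect variances.

        Holding the standardized residuals fixed, a variance proposal
        rescales the innovations and hence the whole latent path, which is
        re-scored against the NB likelihood.  Interweaving these with the
        centered updates breaks the path/variance funnel.  ``resid`` is the
        current inc - mean_nodelta matrix (invalidated by this update).
        """
        eps = resid - self.delta[:, None, 1:]
        a, b = self.pr.ig_shape, self.pr.ig_scale

        def dprior_jac(v_new, v):
            return (-a * np.log(v_new) - b / v_new) - (-a * np.log(v) - b / v)

        acc_e = np.zeros((self.C, self.S))
        for s in range(self.S):
            v = self.sig_e2[:, s]
            v_new = v * np.exp(self.rng.standard_normal(self.C)
                               * self.step_ve2.scale[:, s])
            ratio = np.sqrt(v_new / v)
            shift = np.cumsum(eps[:, s, :] * (ratio[:, None] - 1.0), axis=1)
            u_new = self.u[:, s, :].copy()
            u_new[:, 1:] += shift
            dlp = dprior_jac(v_new, v)
            if self.spec.likelihood:
                ll = _nb_ll_part(self.y[:, s, :], u_new, self.r[:, s, None]) \
                    - _nb_ll_part(self.y[:, s, :], self.u[:, s, :],
                                  self.r[:, s, None])
                dlp += np.sum(np.where(self.obs[None, s], ll, 0.0), axis=1)
            acc = np.log(self.rng.random(self.C)) < dlp
            self.sig_e2[:, s] = np.where(acc, v_new, v)
            self.u[:, s, :] = np.where(acc[:, None], u_new, self.u[:, s, :])
            acc_e[:, s] = acc
        # shared variance: rescaling delta shifts every species' path
        v = self.sig_d2
        v_new = v * np.exp(self.rng.standard_normal(self.C)
                           * self.step_vd2.scale)
        ratio = np.sqrt(v_new / v)
        delta_new = self.delta * ratio[:, None]
        shift = np.cumsum(delta_new[:, 1:] - self.delta[:, 1:], axis=1)
        shift = np.concatenate([np.zeros((self.C, 1)), shift], axis=1)
        u_new = self.u + shift[:, None, :]
        dlp = dprior_jac(v_new, v)
        if self.spec.likelihood:
            dlp += self._nb_ll_obs_sum(u_new, self.r) \
                - self._nb_ll_obs_sum(self.u, self.r)
        acc_d = np.log(self.rng.random(self.C)) < dlp
        self.sig_d2 = np.where(acc_d, v_new, v)
        self.delta = np.where(acc_d[:, None], delta_new, self.delta)
        self.u = np.where(acc_d[:, None, None], u_new, self.u)
        if adapt:
            self.step_ve2.update(acc_e, it)
            self.step_vd2.update(acc_d, it)

    def update_r(self, it, adapt):
        prop = self.r + self.rng.standard_normal((self.C, self.S)) \
            * self.step_r.scale
        inside = (prop > 0) & (prop < self.pr.r_max)
        acc = np.zeros((self.C, self.S))
        if self.spec.likelihood:
            for s in range(self.S):
                o = self.obs[s]
                p_safe = np.where(inside[:, s], prop[:, s], self.r[:, s])
                ll_old = _nb_ll_logmu(self.y[:, s, o], self.u[:, s, o],
                                      self.r[:, s, None]).sum(axis=1)
                ll_new = _nb_ll_logmu(self.y[:, s, o], self.u[:, s, o],
                                      p_safe[:, None]).sum(axis=1)
                ok = inside[:, s] & (np.log(self.rng.random(self.C))
                                     < ll_new - ll_old)
                self.r[:, s] = np.where(ok, p_safe, self.r[:, s])
                acc[:, s] = ok
        else:
            self.r = np.where(inside, prop, self.r)
            acc = inside.astype(float)
        if adapt:
            self.step_r.update(acc, it)

    def loglik_pointwise(self, obs_index):
        s_idx, t_idx = obs_index[:, 0], obs_index[:, 1]
        return _nb_ll_logmu(self.y[:, s_idx, t_idx], self.u[:, s_idx, t_idx],
                            self.r[:, s_idx])

    def sweep(self, it, adapt):
        self.update_u(it, adapt)
        self.update_missing()
        resid = self._resid()
        resid = self.update_alpha(resid)
        self.update_sigma_alpha(it, adapt)
        self.update_coefficients(resid)
        self.update_variances(resid, it, adapt)
        self.update_delta(resid)
        self.update_variances_asis(it, adapt, resid)
        self.update_r(it, adapt)


# ---------------------------------------------------------------------------
# driver


def _standardize_z(z):
    z = np.asarray(z, float)
    if z.ndim == 1:
        z = z[:, None]
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (z - mean) / sd


def run_mcmc(counts: CountMatrix, covariates, spec: ModelSpec,
             priors: PriorSet | None = None,
             config: MCMCConfig | None = None,
             rhat_params=("alpha", "sigma_delta2", "sigma_eps2", "r", "iota"),
             ) -> tuple[PosteriorSamples, FitSummary]:
    """Fit the multi-species synchrony model by MCMC.

    All chains advance together on a single random stream derived from
    ``config.seed`` (each chain drawing its own independent variates);
    identical inputs give identical retained draws.  The fit is flagged
    (``FitSummary.rhat_ok``) rather than rejected when any monitored
    split-Rhat exceeds 1.05.
    """
    priors = priors or PriorSet()
    config = config or MCMCConfig()
    counts.validate()
    y = np.asarray(counts.y)
    observed = np.asarray(counts.observed, bool)
    S, T = y.shape
    if T < 10:
        raise ValueError("counts must span at least 10 years")
    if covariates is None:
        z = np.zeros((T, 0))
    else:
        z = np.asarray(covariates, float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != T:
            raise ValueError("covariate rows must align with count years")
        if spec.standardize_covariates and z.shape[1]:
            z = _standardize_z(z)
    for term in spec.covariate_terms:
        if term.cov >= z.shape[1]:
            raise ValueError(f"term {term.name} references missing covariate column")

    obs_index = np.argwhere(observed)
    C = config.n_chains
    n_keep = config.n_retained_per_chain
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ch = _Chains(y, observed, z, spec, priors, rng, C)

    names_scalar = ["alpha_bar", "sigma_alpha", "sigma_delta2", "iota",
                    "sigma_nu2", "sigma_gamma2"]
    draws = {n: np.empty((C, n_keep)) for n in names_scalar}
    draws["alpha"] = np.empty((C, n_keep, S))
    draws["sigma_eps2"] = np.empty((C, n_keep, S))
    draws["r"] = np.empty((C, n_keep, S))
    draws["delta"] = np.empty((C, n_keep, T - 1))
    draws["log_mean"] = np.empty((C, n_keep, S, T))
    draws["y_imputed"] = np.empty((C, n_keep, S, T))
    draws["nu"] = np.empty((C, n_keep, len(ch.nu_pairs)))
    draws["nu_ind"] = np.empty((C, n_keep, len(ch.nu_pairs)))
    draws["gamma"] = np.empty((C, n_keep, len(ch.terms)))
    draws["gamma_ind"] = np.empty((C, n_keep, len(ch.terms)))
    pw = np.empty((C, n_keep, len(obs_index)))

    kept = 0
    for it in range(config.n_iter):
        ch.sweep(it, adapt=it < config.n_burn)
        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0 \
                and kept < n_keep:
            draws["alpha"][:, kept] = ch.alpha
            draws["alpha_bar"][:, kept] = ch.alpha_bar
            draws["sigma_alpha"][:, kept] = ch.sigma_alpha
            draws["sigma_delta2"][:, kept] = ch.sig_d2
            draws["sigma_eps2"][:, kept] = ch.sig_e2
            draws["sigma_nu2"][:, kept] = ch.sig_nu2
            draws["sigma_gamma2"][:, kept] = ch.sig_g2
            draws["iota"][:, kept] = ch.iota
            draws["r"][:, kept] = ch.r
            draws["delta"][:, kept] = ch.delta[:, 1:]
            draws["nu"][:, kept] = ch.nu_ind * ch.nu_val
            draws["nu_ind"][:, kept] = ch.nu_ind
            draws["gamma"][:, kept] = ch.gam_ind * ch.gam_val
            draws["gamma_ind"][:, kept] = ch.gam_ind
            draws["log_mean"][:, kept] = ch.u
            draws["y_imputed"][:, kept] = ch.y
            pw[:, kept] = ch.loglik_pointwise(obs_index) \
                if spec.likelihood else 0.0
            kept += 1

    samples = PosteriorSamples(
        draws=draws,
        term_names=[t.name for t in ch.terms],
        species=list(counts.species),
        years=np.asarray(counts.years),
        spec=spec,
        config=config,
        pointwise_loglik=pw if spec.likelihood else None,
        obs_index=obs_index,
    )
    summary = summarize(samples, counts, rhat_params=rhat_params)
    return samples, summary


def _split_rhat(x: np.ndarray) -> float:
    """Split potential-scale-reduction factor (each chain halved)."""
    x = np.asarray(x, float)
    c, n = x.shape
    half = n // 2
    if half < 2:
        return float("nan")
    splits = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    within = splits.var(axis=1, ddof=1).mean()
    between = half * splits.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_hat = (half - 1) / half * within + between / half
    return float(np.sqrt(var_hat / within))


def summarize(samples: PosteriorSamples, counts: CountMatrix,
              rhat_params=("alpha", "sigma_delta2", "sigma_eps2", "r", "iota"),
              ppc_seed: int = 0) -> FitSummary:
    d = samples.draws
    mean, lo, hi, rhat = {}, {}, {}, {}
    for name, arr in d.items():
        if name in ("log_mean", "y_imputed") or arr.size == 0:
            continue
        flat = arr.reshape(-1, *arr.shape[2:])
        mean[name] = flat.mean(axis=0)
        lo[name] = np.quantile(flat, 0.025, axis=0)
        hi[name] = np.quantile(flat, 0.975, axis=0)
    for name in rhat_params:
        arr = d[name]
        if arr.ndim == 2:
            rhat[name] = _split_rhat(arr)
        else:
            for i in range(arr.shape[2]):
                rhat[f"{name}[{i}]"] = _split_rhat(arr[:, :, i])
    max_rhat = max(rhat.values()) if rhat else float("nan")
    rhat_ok = bool(np.isfinite(max_rhat) and max_rhat < 1.05)
    if not rhat_ok:
        logger.warning("fit flagged: max split-Rhat %.3f >= 1.05", max_rhat)

    icc_s, icc_all, icc_ci = compute_icc(
        samples.stacked("sigma_delta2"), samples.stacked("sigma_eps2"))

    if samples.pointwise_loglik is not None:
        waic, p_waic = compute_waic(samples, counts)
        bayes_p = posterior_predictive_pvalue(samples, counts, seed=ppc_seed)
    else:
        waic = p_waic = bayes_p = float("nan")

    lam = {}
    for s, sp in enumerate(samples.species):
        ldraws = geometric_lambda(samples, s)
        lam[sp] = (float(ldraws.mean()), float(np.quantile(ldraws, 0.025)),
                   float(np.quantile(ldraws, 0.975)))

    incl = None
    if samples.spec.selection_enabled:
        incl = inclusion_probabilities(samples)

    return FitSummary(
        mean=mean, ci_low=lo, ci_high=hi, rhat=rhat, rhat_ok=rhat_ok,
        max_rhat=max_rhat, waic=waic, p_waic=p_waic, bayes_pvalue=bayes_p,
        icc_species=icc_s, icc_overall=icc_all, icc_ci=icc_ci,
        geometric_lambda=lam, inclusion=incl,
    )


# ---------------------------------------------------------------------------
# derived quantities


def inclusion_probabilities(samples: PosteriorSamples) -> dict:
    """Posterior inclusion probability per selectable term."""
    if not samples.spec.selection_enabled:
        raise ValueError("selection was not enabled for this fit")
    out = {}
    nu_ind = samples.stacked("nu_ind")
    S = samples.draws["alpha"].shape[2]
    pairs = [(s, s) for s in range(S)] + [tuple(p) for p in samples.spec.interactions]
    for k, (j, s) in enumerate(pairs):
        out[f"nu[{j + 1},{s + 1}]"] = float(nu_ind[:, k].mean())
    g_ind = samples.stacked("gamma_ind")
    for k, name in enumerate(samples.term_names):
        out[name] = float(g_ind[:, k].mean())
    return out


def compute_icc(sigma_delta2_draws, sigma_eps2_draws):
    """Per-draw ICC_s = sd2/(sd2+se2_s) and the overall multi-species ICC
    (shared variance over shared plus the species-mean unshared variance).

    Returns (per-species posterior means, overall posterior mean, dict of
    95% intervals).
    """
    sd2 = np.asarray(sigma_delta2_draws, float)
    se2 = np.asarray(sigma_eps2_draws, float)
    if se2.ndim == 1:
        se2 = se2[:, None]
    icc_draws = sd2[:, None] / (sd2[:, None] + se2)
    overall = sd2 / (sd2 + se2.mean(axis=1))
    ci = {"overall": (float(np.quantile(overall, 0.025)),
                      float(np.quantile(overall, 0.975)))}
    for s in range(se2.shape[1]):
        ci[f"species{s + 1}"] = (float(np.quantile(icc_draws[:, s], 0.025)),
                                 float(np.quantile(icc_draws[:, s], 0.975)))
    return icc_draws.mean(axis=0), float(overall.mean()), ci


def covariate_contribution(fit_total: PosteriorSamples,
                           fit_residual: PosteriorSamples) -> ContributionResult:
    """Proportional reduction of year-effect variances by the covariates.

    ``fit_total`` is the fit without sea-ice covariates, ``fit_residual``
    includes them; Cdelta = 1 - resid/total on posterior-mean variances.
    """
    if fit_total.draws["alpha"].shape[2] != fit_residual.draws["alpha"].shape[2] \
            or len(fit_total.years) != len(fit_residual.years):
        raise ValueError("fits must share the same data dimensions")
    tot_d = float(fit_total.stacked("sigma_delta2").mean())
    res_d = float(fit_residual.stacked("sigma_delta2").mean())
    tot_e = fit_total.stacked("sigma_eps2").mean(axis=0)
    res_e = fit_residual.stacked("sigma_eps2").mean(axis=0)
    c_delta = 1.0 - res_d / tot_d
    c_eps = 1.0 - res_e / tot_e
    return ContributionResult(
        c_delta=float(c_delta), c_eps=c_eps,
        total_delta2=tot_d, resid_delta2=res_d,
        total_eps2=tot_e, resid_eps2=res_e,
        negative_flag=bool(c_delta < 0 or np.any(c_eps < 0)),
    )


def compute_waic(samples: PosteriorSamples, counts: CountMatrix):
    """WAIC = -2 (lppd - p_waic), p_waic = sum of pointwise variances."""
    if samples.pointwise_loglik is None:
        raise ValueError("pointwise log-likelihoods were not stored")
    ll = samples.pointwise_loglik.reshape(-1, samples.pointwise_loglik.shape[-1])
    n_draws = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_draws)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


def posterior_predictive_pvalue(samples: PosteriorSamples, counts: CountMatrix,
                                seed: int = 0) -> float:
    """Fraction of draws whose replicated-count RMSE (vs the draw's expected
    counts) is below the observed-count RMSE: the Bayesian p-value of the
    posterior predictive check (≈0.5 for a well-calibrated model)."""
    rng = np.random.default_rng(seed)
    obs_index = samples.obs_index
    s_idx, t_idx = obs_index[:, 0], obs_index[:, 1]
    y_obs = np.asarray(counts.y)[s_idx, t_idx].astype(float)
    u = samples.stacked("log_mean")[:, s_idx, t_idx]
    r = samples.stacked("r")[:, s_idx]
    mu = np.exp(np.clip(u, -30, 30))
    lam = rng.gamma(r, mu / r)
    y_rep = rng.poisson(lam).astype(float)
    rmse_obs = np.sqrt(np.mean((y_obs[None, :] - mu) ** 2, axis=1))
    rmse_rep = np.sqrt(np.mean((y_rep - mu) ** 2, axis=1))
    return float(np.mean(rmse_rep < rmse_obs))


def geometric_lambda(samples: PosteriorSamples, s: int) -> np.ndarray:
    """Per-draw geometric-mean growth rate of the fitted expected counts:
    lambda = (E[y_T]/E[y_1])^(1/(T-1))."""
    u = samples.stacked("log_mean")[:, s, :]
    T = u.shape[1]
    return np.exp((u[:, -1] - u[:, 0]) / (T - 1))
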