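"""Synthetic data with known truth for every downstream stage.

Two generators:

* :func:`gen_counts` draws multi-species count series from the stochastic
  Gompertz model with negative-binomial observation error — the same
  generative structure the fitter assumes — so parameter-recovery tests can
  compare posteriors against known alpha, nu, gamma, sigma_delta^2,
  sigma_eps^2 and r.

* :func:`gen_sic` builds daily sea-ice concentration grids with a
  trapezoidal seasonal cycle whose 15 %-threshold crossings land exactly on
  prescribed advance/retreat days, plus optional AR(1) noise, so the
  phenology covariates can be checked against truth.

The latent model, per species s and year t (log means x):

    log x[s,t] - log x[s,t-1] = alpha_s + sum_j nu[j,s] * ylag[j,t-1]
                                + z[t] . gamma_s + delta_t + eps[t,s]
    y[s,t] ~ NB(r_s, p),  p = r_s / (r_s + x[s,t])

with delta_t ~ N(0, sigma_delta^2) shared across species (the synchronous
year effect) and eps[t,s] ~ N(0, sigma_eps_s^2) species-specific.  The
lagged regressor ylag is log(y+1) centered/scaled by explicit constants
(``lag_center``/``lag_scale``) shared with the fitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .phenology import SICGrid, SeasonWindow, SIC_THRESHOLD

__all__ = [
    "SimScenario",
    "SimTruth",
    "SeasonParams",
    "gen_counts",
    "gen_sic",
    "scenario_cooling_interval",
]


@dataclass(frozen=True)
class SimScenario:
    """Generative settings for a multi-species count study."""

    n_species: int = 3
    n_years: int = 40
    alpha: np.ndarray | float = 0.0
    nu: np.ndarray | float = 0.0          # (S, S); nu[j, s]: effect of j's lag on s
    gamma: np.ndarray | float = 0.0       # (S, K)
    sigma_delta2: float = 0.04
    sigma_eps2: np.ndarray | float = 0.04
    r: np.ndarray | float = 20.0
    y0: np.ndarray | float = 1000.0
    covariates: np.ndarray | None = None  # (T, K) standardized
    n_covariates: int = 1
    missing_years: frozenset = frozenset()
    lag_center: np.ndarray | None = None  # default log(y0 + 1)
    lag_scale: np.ndarray | None = None   # default 1
    seed: int = 0
    altered_window: tuple[int, int] | None = None  # cooling-interval annotation

    def _vec(self, x, n=None) -> np.ndarray:
        n = self.n_species if n is None else n
        return np.broadcast_to(np.asarray(x, float), (n,)).copy()

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        if np.any(self._vec(self.r) <= 0):
            raise ValueError("NB dispersion r must be > 0")
        if self.sigma_delta2 < 0 or np.any(self._vec(self.sigma_eps2) < 0):
            raise ValueError("variances must be >= 0")
        if np.any(self._vec(self.y0) < 0):
            raise ValueError("y0 must be >= 0")

    # resolved parameter arrays -------------------------------------------
    def arrays(self):
        S, T = self.n_species, self.n_years
        alpha = self._vec(self.alpha)
        nu = np.broadcast_to(np.asarray(self.nu, float), (S, S)).copy()
        sig_eps2 = self._vec(self.sigma_eps2)
        r = self._vec(self.r)
        y0 = self._vec(self.y0)
        if self.covariates is not None:
            z = np.asarray(self.covariates, float)
            if z.ndim == 1:
                z = z[:, None]
            if z.shape[0] != T:
                raise ValueError("covariates must have n_years rows")
        else:
            z = None
        K = z.shape[1] if z is not None else self.n_covariates
        gamma = np.broadcast_to(np.asarray(self.gamma, float), (S, K)).copy()
        center = (np.log(y0 + 1.0) if self.lag_center is None
                  else self._vec(self.lag_center))
        scale = (np.ones(S) if self.lag_scale is None
                 else self._vec(self.lag_scale))
        return alpha, nu, gamma, sig_eps2, r, y0, z, center, scale


@dataclass
class SimTruth:
    """Ground truth recorded by the generators."""

    log_mean: np.ndarray | None = None   # x[s, t] latent log means
    delta: np.ndarray | None = None      # shared year effects, length T
    eps: np.ndarray | None = None        # (S, T) species-specific year effects
    icc: np.ndarray | None = None        # per-species sigma_d2/(sigma_d2+sigma_e2)
    icc_overall: float | None = None
    advance: dict = field(default_factory=dict)    # label_year -> window day
    retreat: dict = field(default_factory=dict)
    season_profile: dict = field(default_factory=dict)  # label_year -> noiseless daily pct
    altered_window: tuple[int, int] | None = None


@dataclass
class CountMatrix:
    """Species x year integer counts with an observation mask."""

    species: list
    years: np.ndarray
    y: np.ndarray          # (S, T), filled values at unobserved cells
    observed: np.ndarray   # (S, T) bool

    def validate(self) -> None:
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")
        if np.any(self.y[self.observed] < 0):
            raise ValueError("observed counts must be >= 0")

    def to_frame(self):
        import pandas as pd

        recs = []
        for i, sp in enumerate(self.species):
            for j, yr in enumerate(self.years):
                recs.append({
                    "species": sp,
                    "year": int(yr),
                    "count": int(self.y[i, j]),
                    "observed_flag": int(self.observed[i, j]),
                })
        return pd.DataFrame(recs)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, r: np.ndarray) -> np.ndarray:
    """NB(r, p=r/(r+mean)) draws; r=inf gives the Poisson limit."""
    mean = np.asarray(mean, float)
    r = np.broadcast_to(np.asarray(r, float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    inf = np.isinf(r)
    if inf.any():
        out[inf] = rng.poisson(mean[inf])
    if (~inf).any():
        # gamma-Poisson mixture keeps real-valued r exact
        lam = rng.gamma(shape=r[~inf], scale=mean[~inf] / r[~inf])
        out[~inf] = rng.poisson(lam)
    return out


def gen_counts(scenario: SimScenario) -> tuple[CountMatrix, SimTruth]:
    """Simulate the multi-species NB-Gompertz model.

    Missing years are generated then masked so indices stay aligned.
    Raises if the latent log mean leaves [-30, 30] (explosive interactions),
    naming the offending species and year.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    S, T = scenario.n_species, scenario.n_years
    alpha, nu, gamma, sig_eps2, r, y0, z, center, scale = scenario.arrays()
    if z is None:
        K = scenario.n_covariates
        z = rng.standard_normal((T, K))
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)

    delta = rng.normal(0.0, np.sqrt(scenario.sigma_delta2), size=T)
    eps = rng.normal(0.0, np.sqrt(sig_eps2)[:, None], size=(S, T))

    log_x = np.empty((S, T))
    y = np.empty((S, T), dtype=np.int64)
    log_x[:, 0] = np.log(np.maximum(y0, 1e-12))
    y[:, 0] = _nb_draw(rng, np.exp(log_x[:, 0]), r)
    for t in range(1, T):
        ylag = (np.log(y[:, t - 1] + 1.0) - center) / scale
        inc = alpha + nu.T @ ylag + gamma @ z[t] + delta[t] + eps[:, t]
        log_x[:, t] = log_x[:, t - 1] + inc
        if not np.all(np.abs(log_x[:, t]) < 30):
            s_bad = int(np.argmax(np.abs(log_x[:, t])))
            raise FloatingPointError(
                f"latent log mean diverged for species {s_bad} at year index {t}"
            )
        y[:, t] = _nb_draw(rng, np.exp(log_x[:, t]), r)

    observed = np.ones((S, T), dtype=bool)
    for t in scenario.missing_years:
        observed[:, int(t)] = False

    var_sum = scenario.sigma_delta2 + sig_eps2
    with np.errstate(invalid="ignore"):
        icc = np.where(var_sum > 0, scenario.sigma_delta2 / var_sum, 0.0)
    denom = scenario.sigma_delta2 + sig_eps2.mean()
    truth = SimTruth(
        log_mean=log_x,
        delta=delta,
        eps=eps,
        icc=icc,
        icc_overall=float(scenario.sigma_delta2 / denom) if denom > 0 else 0.0,
        altered_window=scenario.altered_window,
    )
    counts = CountMatrix(
        species=[f"sp{i + 1}" for i in range(S)],
        years=np.arange(T),
        y=y,
        observed=observed,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# sea-ice concentration fields


@dataclass(frozen=True)
class SeasonParams:
    """Trapezoidal season: SIC rises through the 15 % threshold exactly on
    ``advance_day`` and falls through it on ``retreat_day`` (1-based window
    days); ``plateau`` percent in between, 0 outside, linear ramps of
    ``ramp_days`` days (0 = step season)."""

    label_year: int
    advance_day: int
    retreat_day: int
    plateau: float = 80.0
    ramp_days: int = 0

    def __post_init__(self) -> None:
        if self.retreat_day <= self.advance_day:
            raise ValueError("retreat_day must be > advance_day")
        if not 0.0 <= self.plateau <= 100.0:
            raise ValueError("plateau must be in [0, 100]")


def _season_profile(params: SeasonParams, n_days: int,
                    threshold: float = SIC_THRESHOLD) -> np.ndarray:
    """Noiseless daily percent for one window (1-based days)."""
    d = np.arange(1, n_days + 1, dtype=float)
    a, r, p, L = params.advance_day, params.retreat_day, params.plateau, params.ramp_days
    if L == 0 or p <= threshold:
        return np.where((d >= a) & (d < r), p, 0.0)
    # rising ramp crosses `threshold` at day a (first present day); falling
    # ramp holds >= threshold through day r-1 so the scanned retreat is r
    rise0 = a - L * threshold / p
    fall1 = (r - 1) + L * threshold / p
    up = np.clip((d - rise0) / L, 0.0, 1.0)
    down = np.clip((fall1 - d) / L, 0.0, 1.0)
    return p * np.minimum(up, down)


def _scan_truth(profile: np.ndarray, threshold: float = SIC_THRESHOLD,
                run: int = 5) -> tuple[int, int]:
    """Advance/retreat from a noiseless profile by direct day counting."""
    present = profile >= threshold
    n = present.size
    if not present.any():
        return n, n
    adv = None
    for i in range(n - run + 1):
        if present[i:i + run].all():
            adv = i + 1
            break
    if adv is None:
        return n, n
    if present.all():
        return 1, n
    last = int(np.flatnonzero(present)[-1])
    return adv, min(last + 2, n)


def gen_sic(season_params, grid_shape=(4, 4), noise_sd: float = 0.0,
            seed: int = 0, ar1: float = 0.8,
            lon0: float = -47.0, lat0: float = -62.0,
            cell_deg: float = 0.25,
            spatial_gradient: float = 0.0) -> tuple[SICGrid, SimTruth]:
    """Daily SIC grids for consecutive seasons with known phenology truth.

    Each season's trapezoidal profile is applied over the grid, optionally
    scaled by a latitudinal factor spanning ``1 -/+ spatial_gradient/2``
    (more ice toward the southern rows) so extent and area covariates vary;
    AR(1) daily noise (coefficient ``ar1``, innovation SD chosen so the
    marginal SD is ``noise_sd``) is added per cell before clipping to
    [0, 100].  Seasons must be consecutive label years.  Phenology truth
    refers to the mean (factor-1) profile; with ``spatial_gradient=0`` and
    no noise it is exact.
    """
    params = sorted(season_params, key=lambda p: p.label_year)
    years = [p.label_year for p in params]
    if any(b - a != 1 for a, b in zip(years, years[1:])):
        raise ValueError("season label years must be consecutive")
    rng = np.random.default_rng(seed)
    nlat, nlon = grid_shape
    lat = lat0 + cell_deg * (np.arange(nlat) + 0.5)
    lon = lon0 + cell_deg * (np.arange(nlon) + 0.5)

    truth = SimTruth()
    chunks = []
    dates = []
    for p in params:
        window = SeasonWindow(p.label_year)
        n_days = window.n_days
        profile = _season_profile(p, n_days)
        adv, ret = _scan_truth(profile)
        truth.advance[p.label_year] = adv
        truth.retreat[p.label_year] = ret
        truth.season_profile[p.label_year] = profile
        fields = np.repeat(profile[:, None, None], nlat, axis=1)
        fields = np.repeat(fields, nlon, axis=2)
        if spatial_gradient != 0.0:
            factor = 1.0 + spatial_gradient * (0.5 - (np.arange(nlat) + 0.5)
                                               / nlat)
            fields = fields * factor[None, :, None]
        if noise_sd > 0:
            innov_sd = noise_sd * np.sqrt(1.0 - ar1**2)
            e = rng.normal(0.0, innov_sd, size=(n_days, nlat, nlon))
            noise = np.empty_like(e)
            noise[0] = rng.normal(0.0, noise_sd, size=(nlat, nlon))
            for t in range(1, n_days):
                noise[t] = ar1 * noise[t - 1] + e[t]
            fields = fields + noise
        chunks.append(np.clip(fields, 0.0, 100.0))
        dates.append(window.start_date + np.arange(n_days))
    grid = SICGrid(
        dates=np.concatenate(dates),
        lat=lat,
        lon=lon,
        sic=np.concatenate(chunks, axis=0),
    )
    return grid, truth


def scenario_cooling_interval(base: SimScenario, shift: float = 1.5,
                              column: int = 0) -> SimScenario:
    """Shift one covariate by ``shift`` SD in the middle third of the series.

    Emulates a block of extended ice seasons (a cooling interval) so
    transient-synchrony detection can be exercised; the altered window is
    annotated on the returned scenario.
    """
    base.validate()
    T = base.n_years
    if T < 9:
        raise ValueError("series too short to hold a middle third (need >= 9 years)")
    rng = np.random.default_rng(base.seed)
    if base.covariates is not None:
        z = np.array(base.covariates, float, copy=True)
        if z.ndim == 1:
            z = z[:, None]
    else:
        z = rng.standard_normal((T, base.n_covariates))
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)
    t0, t1 = T // 3, T - T // 3
    z[t0:t1, column] += shift
    return replace(base, covariates=z, altered_window=(t0, t1))
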