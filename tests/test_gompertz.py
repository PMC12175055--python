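"""Gompertz model pieces: likelihood, predictor, derived statistics, MCMC
contracts.  Parameter-recovery behavior at scale lives in the acceptance
suite; these tests pin the arithmetic and the sampler's contracts."""

import numpy as np
import pytest
from scipy.special import logsumexp

from sealsync import gompertz as gz
from sealsync.synthetic import CountMatrix


def brute_force_nb_logpmf(y, r, p):
    """Independent oracle: NB pmf via the explicit Gamma-function product,
    computed term by term in plain floats."""
    coef = 1.0
    for i in range(1, y + 1):
        coef *= (r + i - 1) / i
    return np.log(coef * p**r * (1 - p) ** y)


class TestNbLoglik:
    def test_success_probability_parameterization(self):
        # r=1, mu=1 -> p=0.5 -> P(y=0) = 0.5
        assert gz.nb_loglik(0, 1.0, 1.0) == pytest.approx(np.log(0.5))

    def test_matches_brute_force_pmf(self):
        y, r, mu = 3, 2.0, 4.0
        p = r / (r + mu)
        assert gz.nb_loglik(y, mu, r) == pytest.approx(
            brute_force_nb_logpmf(y, r, p), abs=1e-12)

    @pytest.mark.parametrize("y,r,mu", [(0, 0.5, 2.0), (7, 3.3, 1.2),
                                        (25, 12.0, 30.0)])
    def test_matches_scipy_nbinom(self, y, r, mu):
        from scipy.stats import nbinom

        p = r / (r + mu)
        assert gz.nb_loglik(y, mu, r) == pytest.approx(
            nbinom.logpmf(y, r, p), abs=1e-10)

    def test_small_mean_concentrates_at_zero(self):
        assert gz.nb_loglik(0, 1e-12, 5.0) == pytest.approx(0.0, abs=1e-10)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            gz.nb_loglik(1, 0.0, 2.0)

    def test_normalized_over_support(self):
        r, mu = 2.5, 6.0
        total = logsumexp([gz.nb_loglik(y, mu, r) for y in range(400)])
        assert total == pytest.approx(0.0, abs=1e-8)


class TestLinearPredictor:
    def test_all_zero_parameters_give_zero_increment(self):
        assert gz.linear_predictor(0.0, np.zeros(2), 0.0, 0.0, 0.0,
                                   np.ones(2)) == 0.0

    def test_pure_intrinsic_growth_telescopes(self):
        inc = gz.linear_predictor(0.1, np.zeros(1), 0.0, 0.0, 0.0, np.zeros(1))
        assert 10 * inc == pytest.approx(1.0)

    def test_arithmetic_example(self):
        # alpha + nu*ylag + gamma*z + delta + eps
        inc = gz.linear_predictor(
            alpha=0.2, nu=np.array([-0.2]), gamma_effect=0.3 * (-1.0),
            delta_t=0.05, eps_st=-0.05, ylag=np.array([1.5]))
        assert inc == pytest.approx(0.2 - 0.3 - 0.3 + 0.05 - 0.05)

    def test_covariate_sign_flip_equivariance(self, rng):
        z = rng.standard_normal(3)
        g = rng.standard_normal(3)
        a = gz.linear_predictor(0.1, np.array([0.3]), float(z @ g), 0.0, 0.0,
                                np.array([0.5]))
        b = gz.linear_predictor(0.1, np.array([0.3]), float((-z) @ (-g)), 0.0,
                                0.0, np.array([0.5]))
        assert a == pytest.approx(b)


class TestIcc:
    def test_equal_variances(self):
        icc_s, overall, _ = gz.compute_icc(np.ones(100), np.ones((100, 3)))
        np.testing.assert_allclose(icc_s, 0.5)
        assert overall == pytest.approx(0.5)

    def test_zero_shared_variance(self):
        icc_s, overall, _ = gz.compute_icc(np.zeros(50) + 1e-300,
                                           np.ones((50, 2)))
        assert overall == pytest.approx(0.0, abs=1e-12)

    def test_draws_bounded(self, rng):
        sd2 = rng.gamma(1.0, 1.0, size=200)
        se2 = rng.gamma(1.0, 1.0, size=(200, 3))
        icc_s, overall, ci = gz.compute_icc(sd2, se2)
        assert np.all((icc_s >= 0) & (icc_s <= 1))
        assert 0 <= overall <= 1
        assert ci["overall"][0] <= ci["overall"][1]


class TestWaic:
    def test_hand_computed_two_by_two(self):
        """2 draws x 2 observations, WAIC evaluated by hand from the
        definition lppd = sum log mean exp(ll), p = sum var(ll)."""
        ll = np.array([[[-1.0, -2.0]], [[-1.5, -2.5]]])  # (chain=2, draw=1, 2)
        samples = _samples_with_loglik(ll)
        waic, p_waic = gz.compute_waic(samples, None)
        lppd = (np.log(0.5 * (np.exp(-1.0) + np.exp(-1.5)))
                + np.log(0.5 * (np.exp(-2.0) + np.exp(-2.5))))
        p = np.var([-1.0, -1.5], ddof=1) + np.var([-2.0, -2.5], ddof=1)
        assert p_waic == pytest.approx(p, abs=1e-12)
        assert waic == pytest.approx(-2 * (lppd - p), abs=1e-12)

    def test_identical_sample_sets_identical_waic(self, rng):
        ll = rng.normal(-3, 0.5, size=(2, 40, 10))
        w1 = gz.compute_waic(_samples_with_loglik(ll), None)
        w2 = gz.compute_waic(_samples_with_loglik(ll.copy()), None)
        assert w1 == w2

    def test_matches_arviz(self, rng):
        """Cross-check the WAIC formula against arviz (elpd scale)."""
        import arviz as az

        ll = rng.normal(-3, 0.4, size=(2, 100, 12))
        waic, p_waic = gz.compute_waic(_samples_with_loglik(ll), None)
        ds = az.from_dict(log_likelihood={"y": ll})
        ref = az.waic(ds, scale="deviance")
        assert waic == pytest.approx(float(ref.elpd_waic), rel=1e-3)

    def test_observation_order_invariance(self, rng):
        ll = rng.normal(-2, 0.3, size=(2, 30, 8))
        perm = rng.permutation(8)
        w1, _ = gz.compute_waic(_samples_with_loglik(ll), None)
        w2, _ = gz.compute_waic(_samples_with_loglik(ll[:, :, perm]), None)
        assert w1 == pytest.approx(w2, abs=1e-10)


def _samples_with_loglik(ll):
    return gz.PosteriorSamples(
        draws={}, term_names=[], species=[], years=np.array([]),
        spec=gz.ModelSpec(), config=gz.MCMCConfig.reduced(),
        pointwise_loglik=np.asarray(ll), obs_index=None)


class TestGeometricLambda:
    def _samples_with_path(self, u):
        return gz.PosteriorSamples(
            draws={"log_mean": np.asarray(u)[None]}, term_names=[],
            species=["a"], years=np.arange(u.shape[-1]), spec=gz.ModelSpec(),
            config=gz.MCMCConfig.reduced())

    def test_constant_path(self):
        u = np.full((5, 1, 10), 3.0)
        lam = gz.geometric_lambda(self._samples_with_path(u), 0)
        np.testing.assert_allclose(lam, 1.0)

    def test_doubling_path(self):
        path = np.log(2.0) * np.arange(8)
        u = np.tile(path, (4, 1, 1))
        lam = gz.geometric_lambda(self._samples_with_path(u), 0)
        np.testing.assert_allclose(lam, 2.0)


class TestPosteriorPredictive:
    def test_single_draw_p_is_zero_or_one(self):
        u = np.log(np.array([[[50.0, 60.0, 70.0]]]))  # (1 chain, 1 draw, ...)
        counts = CountMatrix(species=["a"], years=np.arange(3),
                             y=np.array([[50, 60, 70]]),
                             observed=np.ones((1, 3), bool))
        samples = gz.PosteriorSamples(
            draws={"log_mean": u[:, :, None, :].reshape(1, 1, 1, 3),
                   "r": np.full((1, 1, 1), 20.0)},
            term_names=[], species=["a"], years=np.arange(3),
            spec=gz.ModelSpec(), config=gz.MCMCConfig.reduced(),
            obs_index=np.array([[0, 0], [0, 1], [0, 2]]))
        p = gz.posterior_predictive_pvalue(samples, counts, seed=0)
        assert p in (0.0, 1.0)


class TestContribution:
    def _fit_like(self, sd2, se2):
        return gz.PosteriorSamples(
            draws={"alpha": np.zeros((1, len(sd2), 2)),
                   "sigma_delta2": np.asarray(sd2)[None],
                   "sigma_eps2": np.asarray(se2)[None]},
            term_names=[], species=["a", "b"], years=np.arange(12),
            spec=gz.ModelSpec(), config=gz.MCMCConfig.reduced())

    def test_equal_variances_zero_contribution(self):
        tot = self._fit_like(np.full(10, 0.5), np.full((10, 2), 0.3))
        res = gz.covariate_contribution(tot, tot)
        assert res.c_delta == pytest.approx(0.0)
        np.testing.assert_allclose(res.c_eps, 0.0)
        assert not res.negative_flag

    def test_zero_residual_full_contribution(self):
        tot = self._fit_like(np.full(10, 0.5), np.full((10, 2), 0.3))
        res_fit = self._fit_like(np.full(10, 1e-12), np.full((10, 2), 1e-12))
        res = gz.covariate_contribution(tot, res_fit)
        assert res.c_delta == pytest.approx(1.0)

    def test_negative_contribution_flagged(self):
        tot = self._fit_like(np.full(10, 0.2), np.full((10, 2), 0.2))
        res_fit = self._fit_like(np.full(10, 0.4), np.full((10, 2), 0.1))
        out = gz.covariate_contribution(tot, res_fit)
        assert out.c_delta < 0
        assert out.negative_flag

    def test_mismatched_fits_rejected(self):
        a = self._fit_like(np.full(4, 0.2), np.full((4, 2), 0.2))
        b = gz.PosteriorSamples(
            draws={"alpha": np.zeros((1, 4, 3)),
                   "sigma_delta2": np.full((1, 4), 0.2),
                   "sigma_eps2": np.full((1, 4, 3), 0.2)},
            term_names=[], species=list("abc"), years=np.arange(12),
            spec=gz.ModelSpec(), config=gz.MCMCConfig.reduced())
        with pytest.raises(ValueError):
            gz.covariate_contribution(a, b)


class TestMcmcContracts:
    def test_same_seed_identical_draws(self, small_fit):
        counts, _, samples, _ = small_fit
        spec = samples.spec
        config = samples.config
        z = np.zeros((len(counts.years), 1))
        z[:, 0] = np.linspace(-1, 1, len(counts.years))
        s2, _ = gz.run_mcmc(counts, z, spec, config=config)
        s3, _ = gz.run_mcmc(counts, z, spec, config=config)
        for name in ("alpha", "gamma", "sigma_delta2", "r"):
            np.testing.assert_array_equal(s2.draws[name], s3.draws[name])

    def test_retained_draw_count(self, small_fit):
        _, _, samples, _ = small_fit
        cfg = samples.config
        assert samples.draws["alpha"].shape[:2] == \
            (cfg.n_chains, cfg.n_retained_per_chain)

    def test_variances_positive_indicators_binary(self, small_fit):
        _, _, samples, _ = small_fit
        assert np.all(samples.stacked("sigma_delta2") > 0)
        assert np.all(samples.stacked("sigma_eps2") > 0)
        ind = samples.stacked("nu_ind")
        assert set(np.unique(ind)) <= {0.0, 1.0}

    def test_missing_year_imputed_as_latent_count(self, small_fit):
        counts, _, samples, _ = small_fit
        imput = samples.stacked("y_imputed")[:, :, 12]
        assert np.all(imput >= 0)
        # imputations vary across draws (latent, not fixed)
        assert np.std(imput) > 0

    def test_icc_draws_in_unit_interval(self, small_fit):
        _, _, samples, summary = small_fit
        assert 0.0 <= summary.icc_overall <= 1.0
        assert np.all((summary.icc_species >= 0) & (summary.icc_species <= 1))

    def test_inclusion_requires_selection(self, small_fit):
        _, _, samples, _ = small_fit
        with pytest.raises(ValueError):
            gz.inclusion_probabilities(samples)

    def test_indicator_fixed_one_when_not_selectable(self, small_fit):
        _, _, samples, _ = small_fit
        # selection disabled: every indicator stays at exactly 1
        assert np.all(samples.stacked("nu_ind") == 1.0)
        assert np.all(samples.stacked("gamma_ind") == 1.0)

    def test_too_short_series_rejected(self):
        counts = CountMatrix(species=["a"], years=np.arange(5),
                             y=np.ones((1, 5), int),
                             observed=np.ones((1, 5), bool))
        with pytest.raises(ValueError, match="10 years"):
            gz.run_mcmc(counts, None, gz.ModelSpec.build(1, 0),
                        config=gz.MCMCConfig.reduced())

    def test_waic_species_relabeling_invariance(self, small_fit):
        counts, _, samples, _ = small_fit
        w1, _ = gz.compute_waic(samples, counts)
        # relabeled species = permuted pointwise likelihood columns
        perm = np.random.default_rng(0).permutation(
            samples.pointwise_loglik.shape[-1])
        shuffled = _samples_with_loglik(samples.pointwise_loglik[:, :, perm])
        w2, _ = gz.compute_waic(shuffled, counts)
        assert w1 == pytest.approx(w2, abs=1e-10)


def test_config_validation():
    with pytest.raises(ValueError):
        gz.MCMCConfig(n_iter=100, n_burn=100)
    with pytest.raises(ValueError):
        gz.MCMCConfig(n_iter=100, n_burn=10, thin=0)
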