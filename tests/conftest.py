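import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def step_seasons():
    """Four consecutive noiseless step seasons with known phenology."""
    from sealsync import synthetic

    params = [
        synthetic.SeasonParams(label_year=2000 + i, advance_day=100 + 5 * i,
                               retreat_day=300 - 3 * i, plateau=80.0,
                               ramp_days=0)
        for i in range(4)
    ]
    grid, truth = synthetic.gen_sic(params, grid_shape=(4, 4), noise_sd=0.0,
                                    seed=11)
    return params, grid, truth


@pytest.fixture(scope="session")
def small_fit():
    """One quick reduced-profile fit on simulated 3-species data, shared by
    the tests that only inspect posterior structure."""
    from sealsync import gompertz, synthetic

    rng = np.random.default_rng(77)
    z = rng.standard_normal((30, 1))
    z = (z - z.mean(0)) / z.std(0)
    scenario = synthetic.SimScenario(n_species=3, n_years=30,
                                     nu=np.eye(3) * -0.15, gamma=-0.103,
                                     covariates=z, seed=5,
                                     missing_years=frozenset({12}))
    counts, truth = synthetic.gen_counts(scenario)
    spec = gompertz.ModelSpec.build(3, 1,
                                    lag_transform=(np.log(1001.0), 1.0),
                                    standardize_covariates=False)
    config = gompertz.MCMCConfig(n_chains=2, n_iter=1200, n_burn=600, thin=3,
                                 seed=9)
    samples, summary = gompertz.run_mcmc(counts, z, spec, config=config)
    return counts, truth, samples, summary
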