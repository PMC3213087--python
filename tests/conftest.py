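import numpy as np
import pytest

from geobma import (
    CovarianceParams,
    ModelIndicator,
    SamplerConfig,
    SimulationScenario,
    simulate_gaussian_data,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_indicator(p, included, n_forced=1):
    gamma = np.zeros(p, dtype=np.int8)
    gamma[list(included)] = 1
    forced = np.zeros(p, dtype=bool)
    forced[:n_forced] = True
    gamma[forced] = 1
    return ModelIndicator(gamma, forced)


@pytest.fixture
def tiny_gaussian_dataset():
    """Small Gaussian dataset (n=20, intercept + 3 selectable covariates)."""
    scenario = SimulationScenario(
        n_sites=20,
        true_theta=CovarianceParams(
            log_sill=0.0,
            log_ranges=(np.log(1.5), np.log(1.5)),
            psi=0.0,
            log_nugget=float(np.log(0.25)),
        ),
        true_gamma=make_indicator(4, [1]),
        true_beta=np.array([0.3, 1.0, 0.0, 0.0]),
        seed=7,
    )
    return simulate_gaussian_data(scenario), scenario


@pytest.fixture
def fast_config():
    return SamplerConfig(
        n_iter=600,
        burn_in=200,
        seed=5,
        include_anisotropy=False,
    )
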