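"""Shared fixtures: a small simulated dataset and reduced sampler configs.

Expensive fits are session-scoped so several tests can interrogate the same
posterior.
"""

import warnings

import numpy as np
import pytest

from plastsel.mcmc import SamplerConfig
from plastsel.reaction_norms import extract_blups, fit_rrmm
from plastsel.simulate import SimulationTruth, StudyDesign, simulate_dataset

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="arviz")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reduced_config():
    return SamplerConfig(chains=2, iterations=800, burn_in=400, thin=1, seed=99)


@pytest.fixture(scope="session")
def small_truth():
    return SimulationTruth(design=StudyDesign(n_individuals=150, n_years=15))


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return simulate_dataset(small_truth, seed=42)


@pytest.fixture(scope="session")
def m2_fit(small_dataset, reduced_config):
    return fit_rrmm(small_dataset.events, small_dataset.climate, "m2",
                    config=reduced_config)


@pytest.fixture(scope="session")
def blups(m2_fit):
    return extract_blups(m2_fit)
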