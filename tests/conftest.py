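import dataclasses

import numpy as np
import pytest

from allogrowth import synthetic_data as sd


@pytest.fixture(scope="session")
def rearing_truth():
    return sd.scenario_truth("constant_rearing")


@pytest.fixture(scope="session")
def small_population(rearing_truth):
    """One noisy 40-individual cohort, reused across read-only tests."""
    return sd.generate_population(rearing_truth, 40, seed=123)


@pytest.fixture(scope="session")
def noiseless_population(rearing_truth):
    truth = dataclasses.replace(rearing_truth, obs_noise_cv=0.0)
    return sd.generate_population(truth, 40, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
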