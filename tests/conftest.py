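import numpy as np
import pandas as pd
import pytest

from dualrisk.io import BetaMatrix, WeightTable
from dualrisk.simulate import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_weights(rng):
    probes = [f"cgsyn{j:06d}" for j in range(20)]
    return WeightTable(dict(zip(probes, rng.normal(0.0, 0.3, 20))))


@pytest.fixture
def random_beta_matrix(rng, small_weights):
    """20 probes x 10 samples of uniform betas, probes match small_weights."""
    values = rng.uniform(0.05, 0.95, (20, 10))
    samples = [f"s{j}@5" for j in range(10)]
    return BetaMatrix(list(small_weights.probes), samples, values)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config cohort (221 couples, study missingness pattern)."""
    cfg = GeneratorConfig()
    return generate_cohort(cfg, seed=20240101)


@pytest.fixture
def complete_cohort():
    """A cohort with no missing person-waves."""
    cfg = GeneratorConfig(n_couples=120, missingness=(1.0, 0.0, 0.0))
    return generate_cohort(cfg, seed=7)
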