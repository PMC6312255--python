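import numpy as np
import pytest

from domix.io import RunConfig
from domix.simulate import simulate_cohort, simulate_proteome


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: 3/6/10/10 samples, dose-age rho ~0.7."""
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def small_proteome(cohort):
    """120-protein matrix with the default category mix, plus its truth."""
    return simulate_proteome(cohort, n_features=120, seed=1)


@pytest.fixture()
def config():
    return RunConfig(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
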