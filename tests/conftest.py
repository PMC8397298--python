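import numpy as np
import pytest

from latentroc import MCMCConfig, fit_latent_mixture, generate_study_like

#: chain settings used throughout the unit tests: long enough for stable
#: posterior means at study size, short enough to keep the suite fast
SHORT_CHAIN = dict(n_iter=2000, n_burnin=600)


@pytest.fixture(scope="session")
def study_data():
    return generate_study_like(seed=1)


@pytest.fixture(scope="session")
def study_fit(study_data):
    """One pooled fit on a study-like dataset, shared across test modules."""
    return fit_latent_mixture(
        study_data, config=MCMCConfig(seed=7, **SHORT_CHAIN)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
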