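import numpy as np
import pytest

import dtdecode as dd


@pytest.fixture(scope="session")
def small_population():
    """A modest multi-site population shared by read-only tests."""
    cfg = dd.PopulationConfig(n_subjects=500, n_regions=15, n_sites=4, seed=7)
    return dd.generate_population(cfg)


@pytest.fixture(scope="session")
def small_split(small_population):
    return dd.split_train_validation(small_population, ratio=4.0, seed=8,
                                     match_age=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
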