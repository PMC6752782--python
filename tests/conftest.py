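import numpy as np
import pytest
from hypothesis import settings

from robagree import SyntheticConfig, deduplicate, generate_study

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study (20 reviews) shared across tests."""
    cfg = SyntheticConfig(n_reviews=20, seed=11)
    records, truth = generate_study(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_dedup(small_study):
    _, records, _ = small_study
    return deduplicate(records, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
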