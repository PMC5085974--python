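import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_pair():
    """One default-resolution phantom pair on the cohort grid (shared)."""
    from atelect import synthetic as syn

    spec = syn.PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(5.0, 5.0, 5.0), seed=7)
    return syn.generate_pair(spec)


@pytest.fixture(scope="session")
def default_pair():
    """Default 96^3 phantom pair (shared across tests that need detail)."""
    from atelect import synthetic as syn

    return syn.generate_pair(syn.PhantomSpec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
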