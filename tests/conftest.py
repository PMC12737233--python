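import numpy as np
import pytest

from gaitpheno.config import SignalConfig
from gaitpheno.synthetic import default_archetypes, generate_cohort


@pytest.fixture(scope="session")
def signal_config():
    return SignalConfig()


@pytest.fixture(scope="session")
def small_cohort(signal_config):
    """Well-separated 40-subject cohort with few strides per subject; shared
    across tests that only need plausible structure, not statistical power."""
    return generate_cohort(
        default_archetypes(2.5), 40, signal_config, seed=5, n_strides_range=(6, 10)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
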