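import numpy as np
import pytest

from ihcquant import SyntheticConfig, generate_sample


@pytest.fixture(scope="session")
def small_config():
    """A fast desk-scale synthetic sample configuration."""
    return SyntheticConfig(
        image_height=160,
        image_width=160,
        nucleus_count=30,
        dab_target_fraction=0.2,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sample(small_config):
    return generate_sample(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
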