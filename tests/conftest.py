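import numpy as np
import pytest

from spdefmeth.config import default_config


@pytest.fixture
def config():
    """Default calibrated config with a fixed test seed."""
    return default_config(seed=101)


@pytest.fixture
def noiseless_config():
    """Forward model with every noise source switched off."""
    return default_config(
        seed=101, ct_noise_sd=0.0, gel_noise_sd=0.0, within_stratum_sd=0.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
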