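import numpy as np
import pytest

from ribotrace import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def params():
    """Default assay conditions."""
    return SimParams(seed=11)


@pytest.fixture
def quiet_params():
    """Noise-free, deterministic-friendly conditions for exact checks."""
    return SimParams(seed=11, noise_sigma=0.0)
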