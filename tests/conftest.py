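import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fig1_outcomes():
    """The 20-trial toy sequence: 9 non-rewards then 11 rewards."""
    return np.concatenate([np.zeros(9), np.ones(11)])
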