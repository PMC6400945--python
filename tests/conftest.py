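import numpy as np
import pytest

from symspeed.stimgen import StimulusParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_params():
    return StimulusParams()


@pytest.fixture
def two_speed_params():
    return StimulusParams(condition="non_segregated", speeds=(3.33, 10.0))
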