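import numpy as np
import pytest

from balloonassim import (DEFAULT_PARAMS, FilterConfig, StimulusTrain,
                          make_block_design)


@pytest.fixture(scope="session")
def block_stimulus():
    """9 on/off blocks of 20 s each, amplitude 0.3, TR 2 s (400 s span)."""
    base = make_block_design(9, 20.0, 20.0, 2.0)
    return StimulusTrain(base.onsets, base.durations, amplitude=0.3,
                         sampling_dt=2.0)


@pytest.fixture(scope="session")
def sample_times():
    return 2.0 * np.arange(200)


@pytest.fixture
def default_params():
    return DEFAULT_PARAMS


@pytest.fixture
def filter_config():
    return FilterConfig(measurement_var=1e-4)
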