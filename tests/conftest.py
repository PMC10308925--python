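import pytest

from nitripartition import default_gradient_config, default_microcosm_config

SAMPLE_TIMES = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0)


@pytest.fixture
def microcosm_config():
    return default_microcosm_config()


@pytest.fixture
def quiet_config():
    """Noise-free microcosm config for deterministic checks."""
    return default_microcosm_config().with_(meas_sd=0.0)


@pytest.fixture
def gradient_config():
    return default_gradient_config()


@pytest.fixture
def sample_times():
    return SAMPLE_TIMES
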