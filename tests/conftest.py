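import numpy as np
import pytest

from spikelapse import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One short synthetic session shared by read-only tests."""
    cfg = sd.SynthConfig(seed=3, duration_s=60.0, n_sessions=2, trials_per_session=5)
    return cfg, sd.make_behavior(cfg)
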