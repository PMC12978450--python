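import numpy as np
import pytest

from callcode import SynthConfig
from callcode.synthgen import gen_spike_population


@pytest.fixture(scope="session")
def small_recording():
    """One small recording session with both waveform classes."""
    cfg = SynthConfig(seed=11, n_narrow=8, n_broad=12, n_trials_per_condition=30)
    return gen_spike_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
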