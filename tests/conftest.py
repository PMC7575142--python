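import numpy as np
import pytest

from sparseconn import SimConfig, Trace
from sparseconn.core import VOLTAGE_CLAMP


@pytest.fixture
def config():
    return SimConfig(seed=0)


@pytest.fixture
def fs():
    return 10_000.0


def make_noise_trace(fs, duration_s, sd, seed=0, clamp=VOLTAGE_CLAMP):
    rng = np.random.default_rng(seed)
    return Trace(rng.normal(0.0, sd, int(duration_s * fs)), fs, clamp)
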