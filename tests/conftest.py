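import numpy as np
import pytest

from anemowhisk.config import SimConfig
from anemowhisk.layout import default_layout


@pytest.fixture
def cfg():
    """Default simulation config with a fixed seed and small sizes."""
    c = SimConfig(seed=42, n_frames=600)
    c.ephys_params.n_units = {"SO": 6, "pad": 6}
    c.epoch_params.n_per_speed = 8
    return c


@pytest.fixture
def layout():
    return default_layout()


@pytest.fixture
def rng():
    return np.random.default_rng(7)
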