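import numpy as np
import pytest

from devconn.synthetic import SimConfig, simulate_lfp


@pytest.fixture(scope="session")
def con_sim():
    """One 180 s control-condition simulation shared across tests."""
    cfg = SimConfig(duration_s=180.0)
    rec, events, model = simulate_lfp(cfg, rng=11)
    return cfg, rec, events, model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
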