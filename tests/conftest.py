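import numpy as np
import pytest

from myoagg.pipeline import DEMO_SIM
from myoagg.simgen import simulate_roi


@pytest.fixture(scope="session")
def sim_config():
    """Fast section-simulation conditions shared across the suite."""
    return DEMO_SIM


@pytest.fixture(scope="session")
def simulated_rois(sim_config):
    """Fifty simulated ROIs (images + ground truth), one per seed."""
    from dataclasses import replace

    out = []
    for seed in range(50):
        dapi, s830, truth = simulate_roi(replace(sim_config, seed=seed))
        out.append((dapi, s830, truth))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
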