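import numpy as np
import pytest

import netcog as nc


@pytest.fixture(scope="session")
def layout():
    return nc.make_layout()


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-structure cohort shared across read-only tests."""
    cfg = nc.SimulationConfig(n_hc=10, n_sz=10, seed=42)
    return nc.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
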