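import numpy as np
import pytest

import otoquant as oq


@pytest.fixture(scope="session")
def wt_config():
    return oq.make_scenario("wildtype", {"seed": 11})


@pytest.fixture(scope="session")
def wt_sim(wt_config):
    """One wild-type embryo shared by read-only tests."""
    return oq.simulate_embryo(wt_config)


@pytest.fixture(scope="session")
def wt_partition(wt_sim):
    lo, hi = wt_sim.geometry.bounding_box()
    return oq.build_cuboid_partition(np.array([lo, hi]))


@pytest.fixture(scope="session")
def local_spec_sim():
    """Eleven locally specified cells followed individually (level trigger)."""
    return oq.simulate_local_specification(11, seed=3)
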