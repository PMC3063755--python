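import numpy as np
import pytest

import magcable as mc


@pytest.fixture(scope="session")
def std_coil():
    return mc.standard_coil()


@pytest.fixture(scope="session")
def std_pulse():
    return mc.standard_pulse(36.0)


@pytest.fixture(scope="session")
def small_soma_cell():
    """20 um HH soma with two thin passive dendrites (fast to simulate)."""
    return mc.soma_n_dendrites(20.0, 1.0, 2)


@pytest.fixture(scope="session")
def fig2_axon_model():
    """The 100 um x 16 cm straight HH axon, discretised once per session."""
    return mc.build_model(mc.straight_axon(100.0, 16e4))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260917)
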