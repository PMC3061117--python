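import numpy as np
import pytest

from phosphorelay import build_relay, compile_reactions


@pytest.fixture(scope="session")
def default_spec():
    return build_relay(4)


@pytest.fixture(scope="session")
def default_network(default_spec):
    return compile_reactions(default_spec)


@pytest.fixture(scope="session")
def default_grid():
    return np.linspace(0.0, 2.0, 200)
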