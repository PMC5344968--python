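import numpy as np
import pytest

from seedshadow import synthetic


@pytest.fixture(scope="session")
def world():
    """One synthetic study at the default (field-emulating) design."""
    return synthetic.simulate_world(synthetic.WorldConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
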