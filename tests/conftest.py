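import numpy as np
import pytest

from motorloop import harness


@pytest.fixture(scope="session")
def unit_bundle():
    """A small fully-wired model (5 actions, 50 reservoir units)."""
    return harness.make_fixture("unit", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
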