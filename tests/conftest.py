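import numpy as np
import pytest

from paleolimb import synthetic


@pytest.fixture(scope="session")
def toy_spec():
    return synthetic.ToyTaxonSpec(seed=0)


@pytest.fixture(scope="session")
def toy_skeleton(toy_spec):
    return synthetic.make_toy_skeleton(toy_spec)


@pytest.fixture(scope="session")
def toy_chain(toy_spec):
    return synthetic.make_toy_chain(toy_spec)


@pytest.fixture(scope="session")
def toy_muscles(toy_spec):
    return synthetic.make_toy_muscles(toy_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
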