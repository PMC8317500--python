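import numpy as np
import pytest

import mbffnet as mb


@pytest.fixture(scope="session")
def tiny_model():
    """A small seeded network shared by read-only tests."""
    return mb.MBFFNet(mb.tiny_config(64, seed=0))


@pytest.fixture(scope="session")
def scene64():
    return mb.generate_scene(mb.SyntheticSceneSpec(side=64, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
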