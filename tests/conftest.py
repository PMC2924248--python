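import numpy as np
import pytest

import sfarl as s
from sfarl.environment import generate_training_stream, watermaze_world
from sfarl.hierarchy import HierarchyConfig, LayerSpec, train_hierarchy


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    """21x21 image, two layers converging to one node; minutes-free scale."""
    return HierarchyConfig(
        image_side=21,
        layers=(
            LayerSpec(7, 0, s.NodeSpec(sfa1_dim=8, sfa2_dim=8)),
            LayerSpec(3, 0, s.NodeSpec(sfa1_dim=12, sfa2_dim=8)),
        ),
        samples_lower=600,
        samples_upper=600,
        n_lower_layers=1,
    )


@pytest.fixture(scope="session")
def tiny_world():
    return watermaze_world(21)


@pytest.fixture(scope="session")
def tiny_model(tiny_config, tiny_world):
    """A small trained hierarchy shared by forward/serialization tests."""

    def factory(n, seed):
        return generate_training_stream(n, tiny_world, np.random.default_rng(seed))

    return train_hierarchy(factory, tiny_config, seed=123)
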