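import numpy as np
import pytest

from hccanet import (
    AttentionWeights,
    MCCBAMConfig,
    SEPARABLE_INTERVALS,
    SyntheticDatasetSpec,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cfg():
    return MCCBAMConfig()


@pytest.fixture
def small_fm(rng):
    return rng.normal(size=(4, 4, 2))


@pytest.fixture
def small_weights(small_cfg):
    return AttentionWeights.initialize(2, small_cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_separable_dataset():
    """30 well-separated images (10 per grade) at 32x32, shared across tests."""
    spec = SyntheticDatasetSpec(classes=dict(SEPARABLE_INTERVALS), n_per_class=10,
                                image_size=(32, 32), seed=11)
    return generate_dataset(spec)
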