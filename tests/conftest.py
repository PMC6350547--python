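import numpy as np
import pytest

from pollenspect import (CLASSES, MixupConfig, NetworkConfig, SoftSample,
                         build_network, generate_dataset, one_hot)


@pytest.fixture(scope="session")
def tiny_counts():
    return {"graves": 30, "hashimoto": 30, "subacute": 30, "normal": 30}


@pytest.fixture(scope="session")
def tiny_dataset(tiny_counts):
    return generate_dataset(tiny_counts, image_size=32, seed=11)


@pytest.fixture(scope="session")
def tiny_soft_samples(tiny_dataset):
    return [SoftSample(im.pixels, one_hot(im.label), "real",
                       CLASSES.index(im.label), im.id) for im in tiny_dataset]


@pytest.fixture(scope="session")
def tiny_mixup_config():
    return MixupConfig(target_per_class=50, train_per_class=40, test_per_class=10)


@pytest.fixture
def tiny_network():
    return build_network(NetworkConfig.preset("tiny"), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
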