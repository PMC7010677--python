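import numpy as np
import pytest

from tremorsep.model import NetworkConfig, train
from tremorsep.synthetic_data import TremorSimParams, build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small subject-wise dataset: 6 subjects x 5 segments of 80 samples."""
    return build_dataset(
        n_subjects=6,
        segments_per_subject=5,
        window=80,
        config=TremorSimParams(),
        rng=np.random.default_rng(7),
    )


@pytest.fixture(scope="session")
def tiny_config():
    return NetworkConfig(
        n_layers=2,
        hidden_size=8,
        window=80,
        learning_rate=1e-3,
        epochs=8,
        batch_size=8,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset, tiny_config):
    """A quickly trained miniature network (seconds)."""
    params, history = train(tiny_dataset, tiny_config, rng=np.random.default_rng(3))
    return params, history
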