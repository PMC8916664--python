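import numpy as np
import pytest

from gaitproto.encoder import EncoderConfig, train
from gaitproto.synthetic import GenerationConfig, generate_dataset

TINY_T = 40


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 subjects x 10 short steps: enough structure for pipeline tests."""
    return generate_dataset(
        GenerationConfig(n_subjects=4, steps_per_subject=10, T=TINY_T, seed=123)
    )


@pytest.fixture(scope="session")
def tiny_config():
    return EncoderConfig(T=TINY_T, epochs=3, anchors_per_epoch=None,
                         batch_size=16, seed=7)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset, tiny_config):
    return train(tiny_dataset.steps, tiny_config)


@pytest.fixture(scope="session")
def small_encoder64():
    """Untrained float64 encoder on short steps, for numerical oracles."""
    from gaitproto.encoder import Encoder

    config = EncoderConfig(T=12, dtype="float64", use_bias=False)
    return Encoder(config, np.random.default_rng(42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
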