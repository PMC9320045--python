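import numpy as np
import pytest

from fedleak import synthetic_data as sd
from fedleak.models import ModelConfig, build_model


@pytest.fixture(scope="session")
def toy_model_bn():
    """Toy CNN with frozen batch-norm statistics, fixed init."""
    return build_model(ModelConfig(architecture="toy_cnn",
                                   freezing="batch_norm"), init_seed=0)


@pytest.fixture(scope="session")
def six_client_federation():
    """Six 100-image clients, alternating populations, and their images."""
    layout = sd.FederationLayout(clients=[
        sd.ClientSpec(f"k{i}", sd.ADULT if i % 2 else sd.PEDIATRIC, 100,
                      *sd.split_client_dataset(100))
        for i in range(6)], seed=0)
    return layout, sd.generate_images(layout, 32, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def client_arrays(data, client_id, split="train"):
    images = data[client_id][split]
    return (np.stack([im.pixels for im in images]),
            np.array([im.label for im in images], dtype=float))
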