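import numpy as np
import pytest

from cwqsar.descriptor import ModelConfig
from cwqsar.optimizer import split_dataset, train
from cwqsar.synthetic import generate_library, plant_and_label


@pytest.fixture(scope="session")
def small_library():
    """~100 unique molecules of at most 8 heavy atoms (oracle-sized)."""
    return generate_library(100, seed=11, max_heavy=8)


@pytest.fixture(scope="session")
def default_config():
    """General systemic recipe: α+γ blocks, all n-gram orders, T=1, N=30."""
    return ModelConfig()


@pytest.fixture(scope="session")
def full_config():
    """Every attribute block enabled (exercises EC/NNC/APP extraction)."""
    return ModelConfig(alpha=1, beta=1, gamma=1, delta=1)


@pytest.fixture(scope="session")
def noise_free_run(default_config):
    """One trained model on noise-free planted data, shared across modules."""
    library = generate_library(200, seed=1)
    records, planted = plant_and_label(library, default_config, noise_sigma=0.0, seed=1)
    split = split_dataset(records, seed=1)
    model = train(split, default_config, seed=1)
    return split, model, planted
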