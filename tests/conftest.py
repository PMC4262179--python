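import numpy as np
import pytest

from contactzone.morpho_io import LandmarkConfiguration, LandmarkDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def square_config():
    return LandmarkConfiguration("sq", np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def random_dataset(rng):
    """Twelve random 10-landmark configurations."""
    configs = [
        LandmarkConfiguration(f"s{i}", rng.normal(size=(10, 2)) + rng.uniform(5, 10))
        for i in range(12)
    ]
    return LandmarkDataset(configs)


def random_similarity(rng, coords):
    """Apply a random rotation, translation and positive scaling."""
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    scale = rng.uniform(0.2, 5.0)
    shift = rng.uniform(-100, 100, size=2)
    return coords @ rot.T * scale + shift
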