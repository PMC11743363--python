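import numpy as np
import pytest

from proxyvit.config import TrainConfig
from proxyvit.data import Dataset
from proxyvit.model import ModelConfig
from proxyvit.pipeline import train
from proxyvit.synthetic import DatasetSpec, generate_arrays


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiny_binary_dataset(n: int, seed: int, size: int = 32) -> Dataset:
    spec = DatasetSpec(n_images=n, class_probs=(0.5, 0.5), image_size=size,
                       seed=seed)
    images, labels, _ = generate_arrays(spec)
    return Dataset(images, labels, [f"syn_{i:05d}" for i in range(n)], 2)


@pytest.fixture(scope="session")
def small_binary_dataset() -> Dataset:
    """120 synthetic 32x32 binary-grade images, fixed seed."""
    return tiny_binary_dataset(120, seed=2)


@pytest.fixture(scope="session")
def trained_tiny(small_binary_dataset):
    """A tiny model trained for a few epochs; reused across tests."""
    cfg = ModelConfig(image_size=32, patch_size=8, d_model=32, depth=2,
                      heads=2, n_classes=2, mean_pool_head=True)
    tc = TrainConfig(epochs=4, seed=2, lr=3e-3)
    result = train(small_binary_dataset, cfg, tc,
                   val_idx=np.arange(100, 120))
    return result, small_binary_dataset
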