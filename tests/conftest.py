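import numpy as np
import pytest

from nactformer.model import ModelConfig
from nactformer.train import TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def micro_model_config():
    """Tiny architecture for fast contract tests (16-px images, 8-dim tokens)."""
    return ModelConfig.test_profile(
        image_side=16,
        block_dims=(8, 8),
        heads=2,
        kernel_sizes=(3, 5),
        encoder_dim=8,
        encoder_depth=1,
        hard_patch=4,
    )


@pytest.fixture(scope="session")
def micro_train_config():
    return TrainConfig.test_profile(epochs_max=3, patience=2, batch_size=8)


def make_micro_pairs(n=16, seed=0, image_size=(16, 16)):
    """Tiny in-memory synthetic cohort for smoke-level training tests."""
    from nactformer.experiments import build_synthetic_pairs

    half = n // 2
    return build_synthetic_pairs(
        n_patients=n,
        category_counts={"PR": half, "SD": n - half},
        seed=seed,
        image_size=image_size,
        noise_sd=0.02,
    )
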