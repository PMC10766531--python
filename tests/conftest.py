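import numpy as np
import pytest

from srdtrans.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(rng):
    """A 16x16x8 random nonnegative stack."""
    return rng.random((16, 16, 8)).astype(np.float32)


def reduced_config(**overrides) -> ModelConfig:
    """Small configuration used throughout the tests (fast on one CPU)."""
    defaults = dict(embed_channels=32, heads=4)
    defaults.update(overrides)
    return ModelConfig(**defaults)
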