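import numpy as np
import pytest

from textoncaps.data import synth_textured_dataset
from textoncaps.model import ModelConfig, TTDCapsNet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """A small built (untrained) network shared by read-only forward tests."""
    cfg = ModelConfig.compact(n_classes=4)
    return TTDCapsNet(cfg, seed=7).eval()


@pytest.fixture(scope="session")
def tiny_batch():
    ds = synth_textured_dataset(8, n_classes=4, seed=3)
    return ds.to_float(), ds.labels
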