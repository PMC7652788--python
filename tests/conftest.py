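import numpy as np
import pytest

import ratpose as rp


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 12-image synthetic dataset shared by read-only tests."""
    out = tmp_path_factory.mktemp("tiny_ds")
    ds = rp.generate_dataset(12, str(out), seed=11)
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def small_model_config(**overrides):
    """Desk-scale model config small enough for per-test forward passes."""
    defaults = dict(
        structure="CCN",
        decoder="HIR",
        stride=8,
        base_channels=4,
        max_channels=8,
        stage_channels=8,
        input_size=(64, 128),
        init_seed=0,
    )
    defaults.update(overrides)
    return rp.ModelConfig(**defaults)


@pytest.fixture()
def small_config():
    return small_model_config()
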