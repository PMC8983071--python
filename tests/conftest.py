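import numpy as np
import pytest

from microsr import NetworkConfig, PhantomSpec, TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net_cfg():
    """Smallest architecture that exercises every layer type (2x scale)."""
    return NetworkConfig(
        scale_k=1, n_resblocks=1, base_channels=4,
        head_kernels=(3, 3), tail_kernel=3, norm="instance",
    )


@pytest.fixture
def tiny_train_cfg(tmp_path):
    return TrainConfig(
        epochs=2, batch_size=2, lr0=1e-3, decay_start_epoch=1,
        pool_size=4, seed=7, out_dir=str(tmp_path / "run"),
    )


@pytest.fixture
def tiny_phantom_spec():
    return PhantomSpec(hr_size=32, s=2)


@pytest.fixture
def desk_phantom_spec():
    """The desk-scale 4x phantom family used for end-to-end checks."""
    return PhantomSpec(hr_size=64, s=4)
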