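import numpy as np
import pytest

from isorestore.volsim import SimSpec, generate_bead_volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bead_volume():
    spec = SimSpec(kind="beads", shape=(32, 64, 64), n_objects=12,
                   radius_range=(2.0, 3.0), seed=7)
    return generate_bead_volume(spec)


def tiny_train_config(**overrides):
    """Desk-scale training settings shared by the training tests."""
    from isorestore.trainer import TrainConfig

    defaults = dict(lr=1e-3, epochs=1, iterations_per_epoch=5, batch=4,
                    patch=16, features=8, n_resblocks=1,
                    disc_features=(8, 16, 16, 1), augment=False, seed=0)
    defaults.update(overrides)
    return TrainConfig(**defaults)
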