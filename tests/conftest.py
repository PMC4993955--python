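import numpy as np
import pytest

from kneeshape.shape import ShapeVectorModel
from kneeshape.simulate import SimConfig, generate_training_set


@pytest.fixture(scope="session")
def sim_config():
    """Default study conditions with a fixed seed."""
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def femur_model(sim_config):
    """Shape vector model trained on the default 96-shape training set."""
    return ShapeVectorModel(generate_training_set(sim_config, "femur")).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rigid_motion(rng):
    """A random proper rotation and translation."""
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return q, t
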