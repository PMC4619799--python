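import numpy as np
import pytest

from polyqlab import descriptors as desc
from polyqlab import go_model as go
from polyqlab import synthetic as syn


@pytest.fixture(scope="session")
def helix20():
    return syn.make_ideal("helix", 20)


@pytest.fixture(scope="session")
def hairpin16():
    return syn.make_ideal("hairpin", 16)


@pytest.fixture(scope="session")
def extended10():
    return syn.make_ideal("extended", 10)


@pytest.fixture(scope="session")
def hairpin_model(hairpin16):
    cmap = desc.build_contact_map(hairpin16)
    return go.build_go_model(hairpin16, cmap), cmap


@pytest.fixture(scope="session")
def hairpin_pull(hairpin_model):
    """One constant-speed pull of the 16-residue hairpin at default params."""
    model, cmap = hairpin_model
    params = go.GoModelParams(seed=11)
    curve, traj = go.pull_constant_speed(model, params)
    return model, cmap, params, curve, traj


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
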