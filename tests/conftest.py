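import numpy as np
import pytest

from bindmodes.fixtures import ToySpec, make_toy_monomer, mini_forcefield


@pytest.fixture(scope="session")
def mini_ff():
    return mini_forcefield()


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec(seed=1)


@pytest.fixture(scope="session")
def toy_monomer(toy_spec):
    return make_toy_monomer(toy_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
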