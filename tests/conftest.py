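import numpy as np
import pytest

from mole8.fixtures import make_ethanol, make_toy_dataset
from mole8.featurizer import build_dictionary


@pytest.fixture(scope="session")
def ethanol():
    return make_ethanol()


@pytest.fixture(scope="session")
def toy50():
    return make_toy_dataset(50, seed=0)


@pytest.fixture(scope="session")
def toy50_dictionary(toy50, ethanol):
    return build_dictionary(toy50 + [ethanol])


def random_rigid_transform(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random proper rotation plus translation of an (n, 3) coordinate array."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=5.0, size=3)
    return coords @ Q.T + t
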