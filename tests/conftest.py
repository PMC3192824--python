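import numpy as np
import pytest

from pathmetad import make_mini_receptor
from pathmetad.geometry import Conformation


@pytest.fixture(scope="session")
def mini_receptor():
    return make_mini_receptor(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_conformation(rng, n_atoms=10, scale=1.0):
    return Conformation(
        coords=scale * rng.normal(size=(n_atoms, 3)),
        atom_names=["CA"] * n_atoms,
        residue_ids=np.arange(1, n_atoms + 1),
        residue_names=["GLY"] * n_atoms,
        chain_ids=["A"] * n_atoms,
    )


@pytest.fixture()
def make_random_conformation(rng):
    def _make(n_atoms=10, scale=1.0):
        return random_conformation(rng, n_atoms, scale)

    return _make


def random_rotation(rng):
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
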