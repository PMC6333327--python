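import numpy as np
import pytest

import nonaffine as na
from nonaffine import synthetic as syn

HELIX_RADIUS = 6.5  # A; median neighborhood ~50 heavy atoms on the helix chain


@pytest.fixture(scope="session")
def lattice():
    """5x5x5 cubic lattice, 1.5 A spacing (125 heavy atoms)."""
    return syn.lattice_reference((5, 5, 5), spacing=1.5)


@pytest.fixture(scope="session")
def helix():
    """Helical pseudo-protein chain of 60 residues (480 heavy atoms)."""
    return syn.helix_reference(n_residues=60, seed=1)


@pytest.fixture(scope="session")
def helix_nb(helix):
    """A mid-chain neighborhood on the helix fixture."""
    return na.build_neighborhood(helix, helix.n_atoms // 2, HELIX_RADIUS)


@pytest.fixture(scope="session")
def helix_proj(helix_nb):
    return na.build_projection(helix_nb)


def random_neighborhood(seed, n_atoms=120, density=0.12, radius=5.0):
    """A neighborhood of a random interior atom of a random cloud."""
    rng = np.random.default_rng(seed)
    ref = syn.cloud_reference(n_atoms=n_atoms, density=density, seed=seed)
    # pick the atom closest to the cloud center so the ball is well filled
    center = int(np.argmin(np.linalg.norm(ref.positions - ref.positions.mean(0), axis=1)))
    nb = na.build_neighborhood(ref, center, radius, min_size=10)
    return ref, nb, rng
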