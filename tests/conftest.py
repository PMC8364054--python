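import numpy as np
import pytest

from aevnet.aev import AEVParams
from aevnet.chem_io import AtomicSystem


@pytest.fixture
def small_params():
    """Cheap AEV layout: 2 species, 4 radial shifts, restricted angular."""
    return AEVParams(
        species=("C", "O"),
        Rc_radial=5.2,
        Rc_angular=3.5,
        eta_R=16.0,
        radial_shifts=(0.9, 2.0, 3.1, 4.2),
        eta_A=8.0,
        zeta=32.0,
        theta_shifts=(0.0, np.pi),
        angular_radial_shifts=(0.0,),
    )


@pytest.fixture
def three_species_params():
    return AEVParams(species=("C", "N", "O"))


def random_system(rng, n_atoms, species=("C", "O"), box=6.0, min_dist=0.8):
    """Random atom cloud with a pairwise distance floor; first atom is ligand."""
    coords = []
    while len(coords) < n_atoms:
        p = rng.uniform(-box / 2, box / 2, size=3)
        if all(np.linalg.norm(p - q) >= min_dist for q in coords):
            coords.append(p)
    elements = [str(rng.choice(species)) for _ in range(n_atoms)]
    mask = np.zeros(n_atoms, dtype=bool)
    mask[: max(1, n_atoms // 3)] = True
    return AtomicSystem(elements, np.array(coords), mask)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
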