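import numpy as np
import pytest

from voxflex import Ensemble, SyntheticSpec, generate_ensemble
from voxflex.io_formats import Atom, Topology


def toy_topology(n_atoms=5, chain="A"):
    """Minimal single-residue-per-atom topology for geometric tests."""
    atoms = tuple(
        Atom(
            serial=i + 1, name="CA", element="C", vdw_radius=1.7,
            residue_index=i, residue_name="GLY", residue_seq=str(i + 1),
            chain_id=chain,
        )
        for i in range(n_atoms)
    )
    residues = tuple((chain, str(i + 1), "GLY") for i in range(n_atoms))
    return Topology(atoms=atoms, residues=residues)


def ensemble_from_coords(coords):
    coords = np.asarray(coords, dtype=float)
    return Ensemble(topology=toy_topology(coords.shape[1]), coords=coords)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def static_ensemble():
    spec = SyntheticSpec(sigma_scaffold=0.0, sigma_loop=0.0, two_state=False,
                         n_frames=5, seed=7)
    return generate_ensemble(spec)


@pytest.fixture
def small_pair():
    from voxflex import naive_matured_pair
    return naive_matured_pair(seed=3, n_frames=80)
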