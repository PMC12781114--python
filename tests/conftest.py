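import numpy as np
import pytest

from nqogate import synthetic as syn
from nqogate import trajectory as tj


@pytest.fixture(scope="session")
def small_ensemble():
    """A compact two-state gate ensemble shared across structural tests."""
    spec = syn.EnsembleSpec(n_residues=20, atoms_per_residue=2, n_frames=150,
                            gate_pair=(5, 15), rng_seed=42)
    top, traj, states = syn.simulate_gate_ensemble(spec, return_states=True)
    return spec, top, traj, states


@pytest.fixture
def two_residue_backbone():
    """A 2-residue toy with a full N/CA/C/O backbone plus one hydrogen."""
    names = ["N", "CA", "C", "O", "H", "N", "CA", "C", "O"]
    elements = ["N", "C", "C", "O", "H", "N", "C", "C", "O"]
    resids = [1, 1, 1, 1, 1, 2, 2, 2, 2]
    rng = np.random.default_rng(0)
    return tj.Structure(
        names=np.array(names), elements=np.array(elements),
        resids=np.array(resids), resnames=np.array(["ALA"] * 9),
        chains=np.array(["A"] * 9), xyz=rng.normal(size=(9, 3)) * 3.0)


def random_toy_structure(rng: np.random.Generator, n_residues: int = 30,
                         atoms_per_residue: int = 3,
                         box: float = 25.0) -> tj.Structure:
    """Random cluster of residues for contact-kernel oracle tests."""
    names, elements, resids = [], [], []
    coords = []
    elem_cycle = ["C", "N", "O", "H"]
    for r in range(n_residues):
        center = rng.uniform(0, box, 3)
        for a in range(atoms_per_residue):
            names.append(f"X{a}")
            elements.append(elem_cycle[(r + a) % len(elem_cycle)])
            resids.append(r + 1)
            coords.append(center + rng.normal(0, 1.0, 3))
    return tj.Structure(
        names=np.array(names), elements=np.array(elements),
        resids=np.array(resids, dtype=int),
        resnames=np.array(["GLY"] * len(names)),
        chains=np.array(["A"] * len(names)),
        xyz=np.array(coords))
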