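import numpy as np
import pytest

from pocketdyn.trajectory_io import FrameEnsemble, ResidueID, Topology


def make_ensemble(coords, residue_atoms, chain="A"):
    """Build a FrameEnsemble from (M, N, 3) coords and per-residue atom specs.

    ``residue_atoms`` is a list of (residue_number, [(atom_name, element)])
    tuples in atom order.
    """
    atom_names, elements, res_index, residues = [], [], [], []
    for number, atoms in residue_atoms:
        residues.append(ResidueID(chain, number, "", "GLY"))
        for name, el in atoms:
            atom_names.append(name)
            elements.append(el)
            res_index.append(len(residues) - 1)
    topo = Topology(np.array(atom_names, dtype=object), np.array(elements, dtype=object),
                    np.array(res_index), residues)
    return FrameEnsemble(topo, np.asarray(coords, dtype=float))


def make_ca_ensemble(ca_coords, chain="A"):
    """Cα-only ensemble from an (M, n_res, 3) coordinate array."""
    m, n, _ = np.asarray(ca_coords).shape
    return make_ensemble(ca_coords, [(i + 1, [("CA", "C")]) for i in range(n)], chain=chain)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
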