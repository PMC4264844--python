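import numpy as np
import pytest

from ratchetpath.io_model import Atom, Topology, Trajectory


@pytest.fixture
def tiny_topology():
    """Four heavy atoms over two residues plus a ligand atom and a water."""
    atoms = [
        Atom(1, "CA", "C", 12.011, 5, "GLU"),
        Atom(2, "CB", "C", 12.011, 5, "GLU"),
        Atom(3, "CA", "C", 12.011, 56, "ILE"),
        Atom(4, "N7", "N", 14.007, 200, "LIG"),
        Atom(5, "O", "O", 15.999, 300, "HOH"),
        Atom(6, "H1", "H", 1.008, 300, "HOH"),
    ]
    groups = {
        "protein": (0, 1, 2),
        "ligand": (3,),
        "solvent": (4, 5),
        "core": (3,),
    }
    return Topology(atoms=atoms, groups=groups)


@pytest.fixture
def pdb_fixture(tmp_path):
    """Hand-written 3-atom PDB file."""
    text = (
        "ATOM      1  CA  GLU A   5       1.000   2.000   3.000  1.00  0.00           C\n"
        "ATOM      2  CB  GLU A   5       2.500   2.000   3.000  1.00  0.00           C\n"
        "HETATM    3  N7  LIG A 200       4.000   5.250   6.125  1.00  0.00           N\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return str(path)


@pytest.fixture
def altloc_pdb(tmp_path):
    """PDB with altloc duplicates: CA has A (occ 0.3) and B (occ 0.7)."""
    text = (
        "ATOM      1  N   GLU A   5       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA AGLU A   5       1.000   0.000   0.000  0.30  0.00           C\n"
        "ATOM      3  CA BGLU A   5       9.000   0.000   0.000  0.70  0.00           C\n"
        "ATOM      4  C   GLU A   5       2.000   1.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "altloc.pdb"
    path.write_text(text)
    return str(path)


def make_trajectory(topology, frames, dt=1.0):
    return Trajectory(topology=topology, frames=np.asarray(frames, float), dt=dt)
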