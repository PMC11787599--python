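import numpy as np
import pytest

from trajcouple import Selection, Topology, Trajectory

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00      A    N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00      A    C
ATOM      3  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00      A
END
"""

TOY_PDB_2MODEL = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00      A    N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00      A    C
ATOM      3  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00      A    C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.000   0.000   1.000  1.00  0.00      A    N
ATOM      2  CA  ALA A   1       1.500   0.000   1.000  1.00  0.00      A    C
ATOM      3  CA  GLY A   2       3.000   0.000   1.000  1.00  0.00      A    C
ENDMDL
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def toy_pdb_2model(tmp_path):
    p = tmp_path / "toy2.pdb"
    p.write_text(TOY_PDB_2MODEL)
    return p


def bead_trajectory(coords: np.ndarray, segment: str = "A") -> Trajectory:
    """Trajectory over a one-bead-per-residue topology from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    topo = Topology(
        atom_names=np.array(["CA"] * n_atoms),
        elements=np.full(n_atoms, "C"),
        residue_numbers=np.arange(1, n_atoms + 1),
        residue_names=np.full(n_atoms, "BEA"),
        segment_ids=np.full(n_atoms, segment),
        masses=np.full(n_atoms, 12.011),
    )
    return Trajectory(topo, coords, np.arange(coords.shape[0], dtype=float))


def all_atoms(traj: Trajectory, label: str = "all") -> Selection:
    return Selection(label, np.arange(traj.topology.n_atoms))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
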