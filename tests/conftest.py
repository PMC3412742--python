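import numpy as np
import pytest

from enmpbsa.enm import build_hessian, build_network, eigenmodes
from enmpbsa.synthetic import ToySpec, make_toy_structure

TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 20.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 20.00           C
ATOM      3  C   ALA A   1      10.722   6.745  -4.124  1.00 20.00           C
ATOM      4  O   ALA A   1       9.581   6.322  -3.926  1.00 20.00           O
ATOM      5  CB  ALA A   1      11.856   4.613  -4.731  1.00 20.00           C
ATOM      6  N   GLY A   2      11.232   7.811  -3.505  1.00 20.00           N
ATOM      7  CA  GLY A   2      10.450   8.563  -2.520  1.00 20.00           C
ATOM      8  C   GLY A   2      11.273   9.693  -1.907  1.00 20.00           C
ATOM      9  O   GLY A   2      12.487   9.743  -2.106  1.00 20.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA  SER A   1       1.500   0.000   0.000  1.00 20.00           C
ATOM      3  OG ASER A   1       2.000   1.000   0.000  0.40 20.00           O
ATOM      4  OG BSER A   1       2.000  -1.000   0.000  0.60 20.00           O
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path):
    path = tmp_path / "two_residues.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture(scope="session")
def toy30():
    """30-residue mixed-topology toy used across the ENM tests."""
    spec = ToySpec(n_residues=30, ss_pattern="H" * 10 + "C" * 10 + "E" * 10, seed=11)
    return make_toy_structure(spec)


@pytest.fixture(scope="session")
def toy30_network(toy30):
    return build_network(toy30)


@pytest.fixture(scope="session")
def toy30_modes(toy30_network):
    return eigenmodes(build_hessian(toy30_network), network=toy30_network)


@pytest.fixture
def random_rotation():
    """Factory for seeded random rotation matrices."""

    def make(seed=0):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()

    return make
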