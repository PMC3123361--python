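"""Shared fixtures: synthetic template structures and small text fixtures."""

import numpy as np
import pytest

from camotif import StructureSimConfig, make_loop_structure, reference_motif
from camotif.synthetic import FLANK_LEN


@pytest.fixture(scope="session")
def template():
    """Noise-free synthetic calcium-loop structure and its ground truth."""
    return make_loop_structure(StructureSimConfig(seed=0))


@pytest.fixture(scope="session")
def template_structure(template):
    return template[0]


@pytest.fixture(scope="session")
def template_truth(template):
    return template[1]


@pytest.fixture(scope="session")
def motif_window(template_structure):
    """The six motif residues of the template (positions 1-6)."""
    return template_structure.chains["A"][FLANK_LEN : FLANK_LEN + 6]


@pytest.fixture(scope="session")
def reference():
    return reference_motif()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


MINIMAL_PDB = """\
ATOM      1  N   ASP A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ASP A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ASP A   1       2.004   1.420   0.000  1.00 10.00           C
ATOM      4  O   ASP A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  N   GLY A   2       3.320   1.540   0.000  1.00 10.00           N
ATOM      6  CA  GLY A   2       3.950   2.860   0.000  1.00 10.00           C
ATOM      7  C   GLY A   2       5.460   2.750   0.000  1.00 10.00           C
ATOM      8  O   GLY A   2       6.030   1.660   0.000  1.00 10.00           O
HETATM    9 CA    CA A 101       4.500   5.500   1.500  1.00 20.00          CA
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   SER A   1       2.004   1.420   0.000  1.00 10.00           C
ATOM      4  O   SER A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  CB ASER A   1       2.000  -0.800   1.200  0.60 10.00           C
ATOM      6  CB BSER A   1       2.100  -0.900   1.100  0.40 10.00           C
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture()
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path
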