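import numpy as np
import pytest

from structphos.structure import Atom, ProteinStructure, Residue, parse_structure

THREE_ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.773  -1.199  1.00  0.00           C
ATOM      6  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      8  C   ALA A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      9  O   ALA A   2       6.030   1.581   0.000  1.00  0.00           O
ATOM     10  CB  ALA A   2       3.575   3.655   1.225  1.00  0.00           C
ATOM     11  N   ALA A   3       6.236   3.800   0.000  1.00  0.00           N
ATOM     12  CA  ALA A   3       7.692   3.765   0.000  1.00  0.00           C
ATOM     13  C   ALA A   3       8.239   5.184   0.000  1.00  0.00           C
ATOM     14  O   ALA A   3       7.481   6.153   0.000  1.00  0.00           O
ATOM     15  CB  ALA A   3       8.219   2.993   1.210  1.00  0.00           C
END
"""


@pytest.fixture
def three_ala():
    return parse_structure(THREE_ALA_PDB, "3ALA")


def single_atom_residue(chain, resseq, aa, coord, linear_index=0, name="CA"):
    return Residue(
        chain_id=chain,
        resseq=resseq,
        icode=" ",
        aa=aa,
        resname="",
        linear_index=linear_index,
        heavy_atoms=[Atom(name, "C", np.asarray(coord, dtype=float), 1.0)],
    )


def point_structure(coords, letters=None, pdb_id="PTS"):
    """Structure of single-atom residues at the given coordinates."""
    letters = letters or ["A"] * len(coords)
    residues = [
        single_atom_residue("A", i + 1, aa, c, linear_index=i)
        for i, (c, aa) in enumerate(zip(coords, letters))
    ]
    return ProteinStructure(pdb_id=pdb_id, chains={"A": residues})


@pytest.fixture
def tetra_structure():
    """Four single-atom residues at the vertices of a regular-ish tetrahedron."""
    coords = [(0, 0, 0), (3, 0, 0), (1.5, 2.6, 0), (1.5, 0.9, 2.5)]
    return point_structure(coords, letters=list("ASTY"))
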