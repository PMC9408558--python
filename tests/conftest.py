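"""Shared fixtures: tiny structure files and a reduced reference library."""

from __future__ import annotations

import numpy as np
import pytest

from abcconform.references import build_synthetic_library
from abcconform.structure_io import CoordinateSet, ResidueLabel

# Minimal fixed-column PDB fixture: one chain, two residues, full backbone
# on residue 1, CA-only residue 2.
TWO_RESIDUE_PDB = """\
HEADER    TRANSPORT PROTEIN                       01-JAN-20   XXXX
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.776   7.073  -4.964  1.00  0.00           C
ATOM      4  O   ALA A   1      13.424   7.447  -5.939  1.00  0.00           O
ATOM      5  N   GLY A   2      13.021   7.485  -3.722  1.00  0.00           N
ATOM      6  CA  GLY A   2      14.089   8.430  -3.433  1.00  0.00           C
TER       7      GLY A   2
END
"""

# Same content in mmCIF dialect.
TWO_RESIDUE_CIF = """\
data_XXXX
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N   . ALA A 1 1 ? 11.104 6.134 -6.504 1.00 0.00 1 A 1
ATOM 2 C CA  . ALA A 1 1 ? 11.639 6.071 -5.147 1.00 0.00 1 A 1
ATOM 3 C C   . ALA A 1 1 ? 12.776 7.073 -4.964 1.00 0.00 1 A 1
ATOM 4 O O   . ALA A 1 1 ? 13.424 7.447 -5.939 1.00 0.00 1 A 1
ATOM 5 N N   . GLY A 1 2 ? 13.021 7.485 -3.722 1.00 0.00 2 A 1
ATOM 6 C CA  . GLY A 1 2 ? 14.089 8.430 -3.433 1.00 0.00 2 A 1
"""

# Three-model NMR-style fixture; model 1 has 2 residues, models 2/3 shifted.
THREE_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        3
ATOM      1  CA  ALA A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       5.800   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path


@pytest.fixture
def two_residue_cif(tmp_path):
    path = tmp_path / "tiny.cif"
    path.write_text(TWO_RESIDUE_CIF)
    return path


@pytest.fixture
def three_model_pdb(tmp_path):
    path = tmp_path / "models.pdb"
    path.write_text(THREE_MODEL_PDB)
    return path


@pytest.fixture(scope="session")
def small_library():
    """Three-class synthetic reference library (keeps alignments cheap)."""
    return build_synthetic_library(
        classes=["Pgp-like", "ABCG2-like", "MacB-like"], seed=0
    )


@pytest.fixture(scope="session")
def full_library():
    return build_synthetic_library(seed=0)


def coordinate_set(coords: np.ndarray, chain: str = "A") -> CoordinateSet:
    coords = np.asarray(coords, dtype=float)
    labels = [ResidueLabel(chain, i + 1) for i in range(len(coords))]
    return CoordinateSet(labels, coords)
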