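"""Shared fixtures: generated toy structures and datasets (no stored data)."""

from __future__ import annotations

import pytest

from fcgr3kit.structure import assign_complex_roles, detect_glycans
from fcgr3kit.synthetic import (
    GlycoDatasetSpec,
    ToyComplexSpec,
    make_glyco_dataset,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def toy_complex():
    """Default toy receptor-Fc complex with glycans and roles assigned."""
    model, truth = make_toy_complex(ToyComplexSpec(seed=1))
    detect_glycans(model)
    assign_complex_roles(model)
    return model, truth


@pytest.fixture(scope="session")
def glyco_dataset():
    """Default glyco dataset (with filter plants) and its ground truth."""
    return make_glyco_dataset(GlycoDatasetSpec(seed=7))


@pytest.fixture(scope="session")
def clean_glyco_dataset():
    """Glyco dataset without filter plants, for clean fraction recovery."""
    spec = GlycoDatasetSpec(seed=11, low_prob_frac=0.0, singleton_frac=0.0)
    return make_glyco_dataset(spec)


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00 10.00           C
ATOM      4  O   ALA A   1      13.560   7.331  -5.840  1.00 10.00           O
ATOM      5  CB  ALA A   1      12.217   4.682  -4.898  1.00 10.00           C
ATOM      6  N   GLY A   2      12.638   7.878  -3.860  1.00 10.00           N
ATOM      7  CA  GLY A   2      13.586   8.952  -3.571  1.00 10.00           C
ATOM      8  C   GLY A   2      13.028  10.322  -3.939  1.00 10.00           C
ATOM      9  O   GLY A   2      11.827  10.474  -4.163  1.00 10.00           O
ATOM     10  N   SER A   3      13.905  11.320  -4.005  1.00 10.00           N
ATOM     11  CA  SER A   3      13.506  12.688  -4.336  1.00 10.00           C
ATOM     12  C   SER A   3      13.055  13.411  -3.068  1.00 10.00           C
ATOM     13  O   SER A   3      13.733  13.355  -2.037  1.00 10.00           O
ATOM     14  CB  SER A   3      14.666  13.443  -4.990  1.00 10.00           C
ATOM     15  OG  SER A   3      15.093  12.785  -6.177  1.00 10.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.40 10.00           C
ATOM      3  CA BALA A   1       1.400   0.300   0.000  0.60 10.00           C
ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00 10.00           C
ATOM      5  O   ALA A   1       1.300   2.400   0.000  1.00 10.00           O
END
"""


@pytest.fixture()
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture()
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path
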