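"""Shared fixtures: hand-written PDB text and small synthetic instances."""

from __future__ import annotations

import numpy as np
import pytest

from pocketforge.structures import Atom, ProteinStructure, Residue
from pocketforge.synthetic import generate_structure, plant_ligand

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.759   7.092  -4.973  1.00 10.00           C
END
"""

PDB_WITH_LIGANDS = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 90.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 85.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00 80.00           C
HETATM    4  O   HOH A 101       1.000   1.000   1.000  1.00  0.00           O
HETATM    5  O   HOH A 102       2.000   2.000   2.000  1.00  0.00           O
HETATM    6  C1  ATP A 201       4.000   3.000   0.000  1.00  0.00           C
HETATM    7  C2  ATP A 201       4.500   3.500   0.000  1.00  0.00           C
HETATM    8  MG  MG  A 202       9.000   1.000   0.000  1.00  0.00          MG
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def ligand_pdb(tmp_path):
    p = tmp_path / "lig.pdb"
    p.write_text(PDB_WITH_LIGANDS)
    return p


def make_linear_structure(
    n: int = 10, spacing: float = 3.8, structure_id: str = "linear"
) -> ProteinStructure:
    """Straight Cα chain along x with the given spacing."""
    residues = [
        Residue(
            chain_id="A",
            res_id=str(i + 1),
            aa="A",
            atoms=[Atom(name="CA", element="C", position=[i * spacing, 0.0, 0.0])],
        )
        for i in range(n)
    ]
    return ProteinStructure(
        structure_id=structure_id, source="experimental", chains={"A": residues}
    )


@pytest.fixture
def linear10():
    return make_linear_structure(10)


@pytest.fixture
def compact_structure():
    return generate_structure(80, seed=7)


@pytest.fixture
def annotated_structure():
    structure = generate_structure(120, seed=11)
    _, annotation = plant_ligand(structure, seed=11)
    return structure, annotation


def brute_force_members(structure, points, radius):
    """O(atoms x points) membership oracle for the geometric pocket rules."""
    points = np.atleast_2d(points)
    members = set()
    for res in structure.iter_residues():
        for atom in res.atoms:
            if np.any(np.linalg.norm(points - atom.position, axis=1) <= radius):
                members.add((res.chain_id, res.res_id))
                break
    return members
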