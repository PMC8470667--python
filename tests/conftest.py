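"""Shared fixtures: tiny PDB texts and toy trajectory builders."""

import numpy as np
import pytest

import cypflex as cf

ASP_PDB = """\
ATOM      1  N   ASP A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ASP A   1      10.000   5.000  -6.000  1.00  0.00           C
ATOM      3  CB  ASP A   1       9.500   4.200  -7.100  1.00  0.00           C
ATOM      4  OD1 ASP A   1       9.000   4.000  -5.000  1.00  0.00           O
ATOM      5  OD2 ASP A   1       8.000   3.000  -4.000  1.00  0.00           O
END
"""


@pytest.fixture
def asp_pdb(tmp_path):
    path = tmp_path / "asp.pdb"
    path.write_text(ASP_PDB)
    return path


@pytest.fixture
def asp_multimodel_pdb(tmp_path):
    body = "".join(
        line for line in ASP_PDB.splitlines(keepends=True) if line != "END\n"
    )
    text = f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{body}ENDMDL\nEND\n"
    path = tmp_path / "asp_mm.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def protein_with_hetero_pdb(tmp_path):
    text = ASP_PDB.replace("END\n", "") + (
        "HETATM    6  O   HOH A 101       1.000   1.000   1.000  1.00  0.00           O\n"
        "HETATM    7  C1  CAM A 102       2.000   2.000   2.000  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "het.pdb"
    path.write_text(text)
    return path


def make_frozen_trajectory(n_residues=20, n_frames=10, dt=10.0):
    structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=n_residues))
    frames = np.repeat(structure.coords[None], n_frames, axis=0)
    return cf.Trajectory(topology=structure, frames=frames, dt=dt)


@pytest.fixture
def frozen_trajectory():
    return make_frozen_trajectory()
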