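"""Shared fixtures: hand-authored miniature structure files and builders."""

import numpy as np
import pytest

from bdspec.structure_io import Atom, Residue, Structure

# A one-residue, three-atom protein chain; authored by hand so every number
# in it is known to the tests that read it.
TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
TER       4
END
"""

# the same content rendered as mmCIF
TINY_CIF = """\
data_tiny
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
ATOM 1 N N . ALA A 1 1 ? 0.000 0.000 0.000 1.00 0.00 1 A 1
ATOM 2 C CA . ALA A 1 1 ? 1.458 0.000 0.000 1.00 0.00 1 A 1
ATOM 3 C C . ALA A 1 1 ? 2.009 1.420 0.000 1.00 0.00 1 A 1
"""

# glutamate with two sidechain conformers (A: 60%, B: 40%) and a water
ALTLOC_PDB = """\
ATOM      1  N   GLU A  10      -1.200   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLU A  10       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  GLU A  10       0.500   1.400   0.000  1.00  0.00           C
ATOM      4  CG AGLU A  10       1.800   1.600   0.800  0.60  0.00           C
ATOM      5  CG BGLU A  10       1.800   1.600  -0.800  0.40  0.00           C
TER       6
HETATM    7  O   HOH W 100       5.000   5.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture
def tiny_cif(tmp_path):
    p = tmp_path / "tiny.cif"
    p.write_text(TINY_CIF)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def make_residue(chain, num, name, atom_spec):
    """atom_spec: list of (atom name, element, xyz[, altloc, occupancy])."""
    atoms = []
    for spec in atom_spec:
        aname, element, xyz = spec[:3]
        altloc = spec[3] if len(spec) > 3 else ""
        occ = spec[4] if len(spec) > 4 else 1.0
        atoms.append(Atom(aname, element, np.asarray(xyz, float), altloc, occ))
    return Residue(chain, num, name, atoms)


def single_atom_residue(chain, num, xyz, name="C", element="C", res_name="ALA"):
    return make_residue(chain, num, res_name, [(name, element, xyz)])


def structure_from_residues(chains: dict, waters=()) -> Structure:
    st = Structure(id="fixture")
    for cid, residues in chains.items():
        st.chains[cid] = sorted(residues, key=lambda r: r.key)
    st.waters = list(waters)
    return st
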