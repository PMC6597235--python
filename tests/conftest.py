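import numpy as np
import pytest

from dualprofiler.fixtures import load_fixtures
from dualprofiler.interactions import InteractionRecord
from dualprofiler.profile_analysis import build_profile
from dualprofiler.structures_io import Atom, Residue, Structure

TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def two_atom_pdb(tmp_path):
    p = tmp_path / "two_atom.pdb"
    p.write_text(TWO_ATOM_PDB)
    return p


@pytest.fixture
def water_only_pdb(tmp_path):
    p = tmp_path / "waters.pdb"
    p.write_text(WATER_ONLY_PDB)
    return p


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


def profile_from_table(table, ligand_id, target_id):
    """Binding profile from a Tables-1/3-shaped frame (residue, counts, ΔASA)."""
    records = []
    for row in table.itertuples():
        name, num = row.residue.split("-")
        n_hb = int(getattr(row, "n_hbonds", 0))
        records.append(
            InteractionRecord(
                residue_key=("A", int(num), name.upper()),
                label=row.residue,
                n_nonbonded=int(row.n_nonbonded),
                n_hbonds=n_hb,
                hbond_lengths=[0.0] * n_hb,
            )
        )
    dasa = dict(zip(table["residue"], table["delta_asa"]))
    return build_profile(records, dasa, ligand_id=ligand_id, target_id=target_id)


@pytest.fixture(scope="session")
def pi3k_profile(fixtures):
    return profile_from_table(fixtures.table1, "XL765", "PI3Kgamma")


@pytest.fixture(scope="session")
def mtor_profile(fixtures):
    return profile_from_table(fixtures.table3, "XL765", "mTOR")


def single_atom_structure(radius=1.9, element="C"):
    atom = Atom(1, element, element, "LIG", "L", 1, np.zeros(3), vdw_radius=radius)
    return Structure([Residue("L", 1, "LIG", [atom])])
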