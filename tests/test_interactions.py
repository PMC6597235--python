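"""Contact and hydrogen-bond detection vs an exhaustive pairwise oracle."""

import numpy as np
import pytest

from dualprofiler.interactions import (
    ContactParams,
    find_contacts,
    find_hbonds,
    per_residue_counts,
)
from dualprofiler.structures_io import Atom, ComplexPair, Residue, Structure
from dualprofiler.synthetic_data import PocketSpec, make_pocket_complex


def _pair_from_atoms(protein_specs, ligand_specs):
    """(element, xyz) lists → ComplexPair with one residue per side."""
    p_atoms = [
        Atom(i + 1, f"{el}{i+1}", el, "ALA", "A", 1, np.asarray(xyz, float))
        for i, (el, xyz) in enumerate(protein_specs)
    ]
    l_atoms = [
        Atom(100 + j, f"{el}{j+1}", el, "LIG", "L", 1, np.asarray(xyz, float))
        for j, (el, xyz) in enumerate(ligand_specs)
    ]
    protein = Structure([Residue("A", 1, "ALA", p_atoms)])
    ligand = Structure([Residue("L", 1, "LIG", l_atoms)])
    complex_s = Structure(list(protein.residues) + list(ligand.residues))
    return ComplexPair(protein, ligand, complex_s)


def brute_force_pairs(pair, params):
    """O(n²) oracle: classify every cross pair independently."""
    hbonds, contacts = [], []
    for pa in pair.protein.atoms():
        for la in pair.ligand.atoms():
            d = float(np.linalg.norm(pa.coordinates - la.coordinates))
            capable = (
                pa.element.upper() in params.hbond_elements
                and la.element.upper() in params.hbond_elements
            )
            if capable and d <= params.hbond_max:
                hbonds.append((pa.serial, la.serial))
            elif params.contact_min <= d <= params.contact_max:
                contacts.append((pa.serial, la.serial))
    return contacts, hbonds


@pytest.mark.parametrize(
    "distance,expected", [(3.5, 1), (4.5, 0), (2.5, 0), (2.9, 1), (3.9, 1)]
)
def test_contact_distance_window(distance, expected):
    pair = _pair_from_atoms([("C", (0, 0, 0))], [("C", (distance, 0, 0))])
    assert len(find_contacts(pair)) == expected


def test_no_to_pair_at_hbond_distance_is_hbond_not_contact():
    pair = _pair_from_atoms([("N", (0, 0, 0))], [("O", (2.9, 0, 0))])
    hbonds = find_hbonds(pair)
    assert len(hbonds) == 1 and hbonds[0][2] == 2.9
    assert find_contacts(pair) == []  # not double-counted


def test_carbon_pair_never_hydrogen_bonds():
    pair = _pair_from_atoms([("C", (0, 0, 0))], [("C", (2.9, 0, 0))])
    assert find_hbonds(pair) == []
    assert len(find_contacts(pair)) == 1


def test_empty_ligand_gives_empty_lists():
    protein = Structure(
        [Residue("A", 1, "ALA", [Atom(1, "CA", "C", "ALA", "A", 1, np.zeros(3))])]
    )
    ligand = Structure([], source_id="empty")
    pair = ComplexPair(protein, ligand, protein)
    assert find_contacts(pair) == [] and find_hbonds(pair) == []


@pytest.mark.parametrize("seed", range(20))
def test_detection_equals_brute_force_oracle_on_planted_pockets(seed):
    spec = PocketSpec(
        n_residues=6,
        planted_contacts=((1, 1 + seed % 4, 3.5), (3, 2, 3.45 + 0.02 * (seed % 5))),
        planted_hbonds=((2, "O", "N", 2.9), (4, "N", "O", 2.8 + 0.05 * (seed % 6))),
        seed=seed,
    )
    params = ContactParams()
    pair, ledger = make_pocket_complex(spec, params)
    contacts = {(pa.serial, la.serial) for pa, la, _ in find_contacts(pair, params)}
    hbonds = {(pa.serial, la.serial) for pa, la, _ in find_hbonds(pair, params)}
    oracle_contacts, oracle_hbonds = brute_force_pairs(pair, params)
    assert contacts == set(oracle_contacts)
    assert hbonds == set(oracle_hbonds)
    # and the ledger is recovered exactly
    planted_contacts = sum(c for _, c, _ in ledger["contacts"])
    assert len(contacts) == planted_contacts
    assert len(hbonds) == len(ledger["hbonds"])


def test_per_residue_counts_conserve_totals(fixtures):
    spec = PocketSpec(
        n_residues=6,
        planted_contacts=((1, 3, 3.5), (3, 2, 3.6), (5, 2, 3.45)),
        planted_hbonds=((2, "O", "N", 2.9),),
        seed=9,
    )
    pair, _ = make_pocket_complex(spec)
    contacts, hbonds = find_contacts(pair), find_hbonds(pair)
    records = per_residue_counts(contacts, hbonds)
    assert sum(r.n_nonbonded for r in records) == len(contacts)
    assert sum(r.n_hbonds for r in records) == len(hbonds)
    for rec in records:
        assert len(rec.hbond_lengths) == rec.n_hbonds


def test_printed_profile_totals(fixtures):
    """The tabulated per-residue counts sum to the stated totals: 28
    non-bonded interactions on one target, 37 on the other."""
    assert fixtures.table1["n_nonbonded"].sum() == 28
    assert list(fixtures.table1["n_nonbonded"]) == [3, 1, 5, 1, 2, 2, 1, 4, 8, 1]
    assert fixtures.table3["n_nonbonded"].sum() == 37


def test_count_monotone_in_contact_max():
    spec = PocketSpec(n_residues=4, planted_contacts=((1, 3, 3.5),), seed=5)
    pair, _ = make_pocket_complex(spec)
    narrow = ContactParams(contact_max=3.6)
    wide = ContactParams(contact_max=4.5)
    n_narrow = len(find_contacts(pair, narrow))
    n_wide = len(find_contacts(pair, wide))
    assert n_wide >= n_narrow


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ContactParams(contact_min=4.0, contact_max=3.0)
    with pytest.raises(ValueError):
        ContactParams(hbond_max=5.0)
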