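"""Shrake–Rupley ASA against closed forms and an independent Monte-Carlo oracle."""

import numpy as np
import pytest

from conftest import single_atom_structure
from dualprofiler.structures_io import Atom, ComplexPair, Residue, Structure, StructureError
from dualprofiler.surface_area import (
    ASAParams,
    DeltaASAMap,
    classify_interacting,
    delta_asa,
    residue_asa,
    shrake_rupley,
)
from dualprofiler.synthetic_data import PocketSpec, make_pocket_complex
from dualprofiler.structures_io import assign_radii


def mc_surface_area(coords, radii, probe=1.4, n_samples=1_000_000, seed=12345):
    """Independent Monte-Carlo ASA oracle: uniform random points on each
    atom's expanded sphere, kept if outside every other expanded sphere."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe
    n_atoms = len(coords)
    per_atom = n_samples // n_atoms
    total = 0.0
    for i in range(n_atoms):
        v = rng.normal(size=(per_atom, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * v
        exposed = np.ones(per_atom, bool)
        for j in range(n_atoms):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > expanded[j] ** 2
        total += exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return total


def _structure_from(coords, radii):
    atoms = [
        Atom(i + 1, f"C{i+1}", "C", "LIG", "L", 1, c, vdw_radius=r)
        for i, (c, r) in enumerate(zip(coords, radii))
    ]
    return Structure([Residue("L", 1, "LIG", atoms)])


def test_isolated_atom_closed_form():
    s = single_atom_structure(radius=1.9)
    asa = shrake_rupley(s, ASAParams(probe_radius=1.4))
    assert asa[1] == pytest.approx(4 * np.pi * 3.3**2, rel=1e-12)


def test_additivity_at_infinite_separation():
    coords = [np.zeros(3), np.array([100.0, 0, 0])]
    s = _structure_from(coords, [1.9, 1.6])
    asa = shrake_rupley(s)
    expected = 4 * np.pi * (1.9 + 1.4) ** 2 + 4 * np.pi * (1.6 + 1.4) ** 2
    assert sum(asa.values()) == pytest.approx(expected, rel=1e-12)


def test_enclosed_atom_has_zero_asa():
    # central small atom caged by 26 large overlapping spheres
    offsets = [
        np.array([x, y, z])
        for x in (-2.0, 0, 2.0)
        for y in (-2.0, 0, 2.0)
        for z in (-2.0, 0, 2.0)
        if (x, y, z) != (0, 0, 0)
    ]
    coords = [np.zeros(3)] + offsets
    radii = [1.2] + [1.9] * len(offsets)
    asa = shrake_rupley(_structure_from(coords, radii))
    assert asa[1] == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cluster_matches_monte_carlo_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 5 if seed == 0 else 5 + 5 * seed  # 5, 10, 15 atoms
    coords = rng.uniform(-3, 3, size=(n, 3))
    radii = rng.uniform(1.4, 1.9, size=n)
    s = _structure_from(coords, radii)
    ours = sum(shrake_rupley(s).values())
    oracle = mc_surface_area(coords, radii, n_samples=1_000_000, seed=999 + seed)
    assert ours == pytest.approx(oracle, rel=0.02)


def test_residue_aggregation_conserves_total():
    spec = PocketSpec(n_residues=5, planted_contacts=((1, 2, 3.5),), seed=11)
    pair, _ = make_pocket_complex(spec)
    assign_radii(pair.protein)
    atom_asa = shrake_rupley(pair.protein)
    per_res = residue_asa(pair.protein, atom_asa)
    assert sum(r.asa for r in per_res) == pytest.approx(sum(atom_asa.values()))
    # grouping equals brute-force per-atom aggregation
    for res, rec in zip(pair.protein.residues, per_res):
        assert rec.asa == pytest.approx(sum(atom_asa[a.serial] for a in res.atoms))


def test_delta_asa_zero_without_ligand_occlusion():
    spec = PocketSpec(n_residues=4, seed=2)  # only the far inert ligand atom
    pair, _ = make_pocket_complex(spec)
    assign_radii(pair.complex)
    d = delta_asa(pair.protein, pair)
    assert all(abs(v) < 1e-9 for v in d.delta_asa.values())


def test_delta_asa_nonnegative_on_synthetic_complexes():
    for seed in range(5):
        spec = PocketSpec(
            n_residues=5, planted_contacts=((1, 3, 3.5), (3, 1, 3.6)),
            planted_burial=(5,), seed=seed,
        )
        pair, _ = make_pocket_complex(spec)
        assign_radii(pair.complex)
        d = delta_asa(pair.protein, pair)
        assert all(v >= -1e-9 for v in d.delta_asa.values())


def test_capped_residue_loses_its_exposed_hemisphere():
    """A cap of occluders over one residue buries it; ΔASA for that residue
    dominates and matches a Monte-Carlo recomputation of both states."""
    spec = PocketSpec(n_residues=3, planted_burial=(1,), seed=4)
    pair, _ = make_pocket_complex(spec)
    assign_radii(pair.complex)
    d = delta_asa(pair.protein, pair)
    buried_key = next(k for k in d.delta_asa if k[1] == 1)
    assert d.delta_asa[buried_key] > 10.0
    assert d.delta_asa[buried_key] == max(d.delta_asa.values())

    # MC cross-check of the buried residue's ΔASA
    prot_atoms = list(pair.protein.atoms())
    lig_atoms = list(pair.ligand.atoms())
    res_idx = [i for i, a in enumerate(prot_atoms) if a.residue_number == 1]

    def mc_residue_asa(all_atoms):
        coords = np.array([a.coordinates for a in all_atoms])
        radii = np.array([a.vdw_radius for a in all_atoms])
        rng = np.random.default_rng(77)
        total = 0.0
        for i in res_idx:
            v = rng.normal(size=(120_000, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = coords[i] + (radii[i] + 1.4) * v
            exposed = np.ones(len(pts), bool)
            for j in range(len(all_atoms)):
                if j == i:
                    continue
                exposed &= ((pts - coords[j]) ** 2).sum(axis=1) > (radii[j] + 1.4) ** 2
            total += exposed.mean() * 4 * np.pi * (radii[i] + 1.4) ** 2
        return total

    mc_delta = mc_residue_asa(prot_atoms) - mc_residue_asa(prot_atoms + lig_atoms)
    assert d.delta_asa[buried_key] == pytest.approx(mc_delta, rel=0.02)


def test_delta_asa_requires_matching_residue_keys():
    spec = PocketSpec(n_residues=3, seed=0)
    pair, _ = make_pocket_complex(spec)
    assign_radii(pair.complex)
    other = Structure(residues=pair.protein.residues[:-1], source_id="truncated")
    with pytest.raises(StructureError):
        delta_asa(other, pair)


def test_classify_interacting_threshold_and_order(fixtures):
    t1 = dict(zip(fixtures.table1["residue"], fixtures.table1["delta_asa"]))
    dmap = DeltaASAMap(
        delta_asa={("A", int(r.split("-")[1]), r.split("-")[0]): v for r, v in t1.items()}
    )
    hits = classify_interacting(dmap)
    assert len(hits) == 10  # every tabulated PI3Kγ residue exceeds 10 Å²
    values = [dmap.delta_asa[k] for k in hits]
    assert values == sorted(values, reverse=True)
    assert values[0] == 59.19


def test_classify_interacting_excludes_below_threshold(fixtures):
    t3 = fixtures.table3
    dmap = DeltaASAMap(
        delta_asa={
            ("A", int(r.split("-")[1]), r.split("-")[0]): v
            for r, v in zip(t3["residue"], t3["delta_asa"])
        }
    )
    hits = {k[1] for k in classify_interacting(dmap)}
    assert 2240 not in hits  # Val-2240 loses only 8.9 Å²
    assert len(hits) == 10


def test_classify_monotone_in_threshold():
    deltas = {("A", i, "ALA"): float(i) for i in range(1, 30)}
    low = set(classify_interacting(DeltaASAMap(deltas, threshold=5)))
    high = set(classify_interacting(DeltaASAMap(deltas, threshold=15)))
    assert high <= low


def test_empty_map_gives_empty_set():
    assert classify_interacting(DeltaASAMap({})) == []
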