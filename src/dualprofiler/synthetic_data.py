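"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators stand in for the external programs whose outputs the
pipeline consumes:

* :func:`make_pocket_complex` builds a toy protein–ligand complex (in place
  of a docking pose) from minimal Gly/Ala-like residue templates, planting
  ligand atoms at exact requested distances so the number of non-bonded
  contacts, hydrogen bonds and buried residues is known by construction.
  The returned ledger lists every planted feature and the generator
  verifies by exhaustive pairwise scan that nothing else was created.
* :func:`make_score_table` draws Gaussian dock scores where actives are
  shifted by δ relative to decoys (δ ≤ 0 means actives score better); only
  the rank order matters to enrichment statistics.
* :func:`make_substituent_sets` provides chemically valid R1/R2 fragment
  sets from a curated internal list, emulating the 9 × 5 study
  configuration.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dualprofiler.chem_library import SubstituentSet
from dualprofiler.interactions import ContactParams
from dualprofiler.structures_io import Atom, ComplexPair, Residue, Structure

__all__ = [
    "PocketSpec",
    "ScreenSpec",
    "GenerationError",
    "make_pocket_complex",
    "make_score_table",
    "make_substituent_sets",
]


class GenerationError(RuntimeError):
    """Raised when a planted-geometry spec cannot be satisfied cleanly."""


# Minimal heavy-atom residue templates (local coordinates, Å). The Ala-like
# template's CB sits below the backbone plane, giving a clean outward ray.
_TEMPLATES = {
    "GLY": [
        ("N", "N", (-1.458, 0.0, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.55, 1.42, 0.0)),
        ("O", "O", (1.77, 1.56, 0.0)),
    ],
    "ALA": [
        ("N", "N", (-1.458, 0.0, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.55, 1.42, 0.0)),
        ("O", "O", (1.77, 1.56, 0.0)),
        ("CB", "C", (0.54, -0.78, -1.21)),
    ],
}

_RESIDUE_SPACING = 15.0  # Å between residue anchors; far beyond any cutoff


@dataclass(frozen=True)
class PocketSpec:
    """Planted-feature description of a toy pocket.

    ``planted_contacts``: (residue_index 1-based, count, distance Å) — the
    distance must lie inside the contact window and outside the H-bond
    cutoff so each planted carbon creates exactly one non-bonded contact.
    ``planted_hbonds``: (residue_index, protein_element 'N'|'O',
    ligand_element, distance Å ≤ hbond_max, ≥ 2.7).
    ``planted_burial``: residue indices shadowed by a cap of distant
    carbons (outside contact range) that bury surface without contacts.
    """

    n_residues: int = 6
    planted_contacts: tuple = ()
    planted_hbonds: tuple = ()
    planted_burial: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise GenerationError("need at least one residue")
        for idx, _count, _d in self.planted_contacts:
            if not (1 <= idx <= self.n_residues):
                raise GenerationError(f"contact residue index {idx} out of range")


@dataclass(frozen=True)
class ScreenSpec:
    """Synthetic screen: actives shifted by ``score_shift`` over decoys."""

    n_actives: int = 6
    decoys_per_active: int = 100
    score_shift: float = -6.0
    noise_sd: float = 3.0
    baseline_score: float = -35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actives < 1:
            raise GenerationError("need at least one active")

    @property
    def n_decoys(self) -> int:
        return self.n_actives * self.decoys_per_active


def _build_protein(spec: PocketSpec, rng: np.random.Generator) -> Structure:
    residues = []
    serial = 0
    for i in range(spec.n_residues):
        name = "ALA" if i % 2 == 0 else "GLY"
        # translational jitter only: planting happens after placement, so
        # planted distances stay exact while seeds still vary the geometry
        offset = np.array([i * _RESIDUE_SPACING, 0.0, 0.0]) + rng.uniform(-0.3, 0.3, 3)
        atoms = []
        for atom_name, element, local in _TEMPLATES[name]:
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=atom_name,
                    element=element,
                    residue_name=name,
                    chain_id="A",
                    residue_number=i + 1,
                    coordinates=np.asarray(local) + offset,
                )
            )
        residues.append(Residue("A", i + 1, name, atoms))
    return Structure(residues=residues, source_id=f"pocket-seed{spec.seed}")


def _atom(res: Residue, name: str) -> Atom:
    for a in res.atoms:
        if a.name == name:
            return a
    raise GenerationError(f"residue {res.label} has no atom {name}")


def _tilted_directions(count: int) -> np.ndarray:
    """Unit vectors near −z: a single straight ray, or a 15° cone for many."""
    if count == 1:
        return np.array([[0.0, 0.0, -1.0]])
    alpha = np.deg2rad(15.0)
    phis = 2.0 * np.pi * np.arange(count) / count
    return np.column_stack(
        [np.sin(alpha) * np.cos(phis), np.sin(alpha) * np.sin(phis), -np.cos(alpha) * np.ones(count)]
    )


def _hemisphere_directions(n: int) -> np.ndarray:
    """Deterministic directions covering a 60° cone around −z."""
    i = np.arange(n, dtype=float)
    cos_a = 1.0 - 0.5 * (i + 0.5) / n  # cos(angle) in (0.5, 1]
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    sin_a = np.sqrt(1.0 - cos_a**2)
    return np.column_stack([sin_a * np.cos(phi), sin_a * np.sin(phi), -cos_a])


def make_pocket_complex(
    spec: PocketSpec, params: ContactParams | None = None
) -> tuple[ComplexPair, dict]:
    """Build a toy complex realizing the planted features exactly.

    Returns the split complex and a ground-truth ledger
    ``{"contacts": [(label, count, distance)], "hbonds": [...],
    "buried": [label, ...]}``. The construction is verified against an
    exhaustive pairwise scan under ``params`` (default cutoffs); any
    accidental extra or missing feature raises :class:`GenerationError`.
    """
    from dualprofiler.interactions import find_contacts, find_hbonds  # cycle guard

    params = params or ContactParams()
    rng = np.random.default_rng(spec.seed)
    protein = _build_protein(spec, rng)
    residues = {r.residue_number: r for r in protein.residues}

    ligand_atoms: list[Atom] = []
    serial = protein.n_atoms
    counters: dict[str, int] = {}

    def _add_ligand_atom(element: str, pos: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        counters[element] = counters.get(element, 0) + 1
        ligand_atoms.append(
            Atom(
                serial=serial,
                name=f"{element}{counters[element]}",
                element=element,
                residue_name="LIG",
                chain_id="L",
                residue_number=1,
                coordinates=pos,
            )
        )

    ledger = {"contacts": [], "hbonds": [], "buried": []}

    for idx, count, dist in spec.planted_contacts:
        if not (params.contact_min <= dist <= params.contact_max) or dist <= params.hbond_max:
            raise GenerationError(
                f"contact distance {dist} must be in ({params.hbond_max}, {params.contact_max}]"
            )
        res = residues[idx]
        anchor = _atom(res, "CB" if res.residue_name == "ALA" else "CA")
        if res.residue_name == "GLY":
            raise GenerationError("plant contacts on ALA residues (odd indices) which carry a CB")
        for u in _tilted_directions(count):
            _add_ligand_atom("C", anchor.coordinates + dist * u)
        ledger["contacts"].append((res.label, count, dist))

    for idx, protein_elem, ligand_elem, dist in spec.planted_hbonds:
        if dist > params.hbond_max or dist < 2.7:
            raise GenerationError(f"h-bond distance {dist} must be in [2.7, {params.hbond_max}]")
        res = residues[idx]
        if protein_elem == "O":
            anchor, back = _atom(res, "O"), _atom(res, "C")
        elif protein_elem == "N":
            anchor, back = _atom(res, "N"), _atom(res, "CA")
        else:
            raise GenerationError("protein h-bond anchor element must be 'N' or 'O'")
        u = anchor.coordinates - back.coordinates
        u = u / np.linalg.norm(u)
        _add_ligand_atom(ligand_elem, anchor.coordinates + dist * u)
        ledger["hbonds"].append((res.label, protein_elem, ligand_elem, round(dist, 2)))

    cap_radius = 5.0  # beyond contact_max: buries surface without contacts
    for idx in spec.planted_burial:
        res = residues[idx]
        anchor = _atom(res, "CB" if res.residue_name == "ALA" else "CA")
        if res.residue_name == "GLY":
            raise GenerationError("plant burial on ALA residues (odd indices) which carry a CB")
        for u in _hemisphere_directions(16):
            _add_ligand_atom("C", anchor.coordinates + cap_radius * u)
        ledger["buried"].append(res.label)

    if not ligand_atoms:
        # an empty ligand breaks the PDB round trip; keep one inert far atom
        _add_ligand_atom("C", np.array([-50.0, 0.0, 0.0]))

    ligand = Structure(
        residues=[Residue("L", 1, "LIG", ligand_atoms)],
        source_id=f"{protein.source_id}:ligand",
    )
    complex_s = Structure(
        residues=list(protein.residues) + list(ligand.residues),
        source_id=protein.source_id,
    )
    pair = ComplexPair(protein=protein, ligand=ligand, complex=complex_s)

    # self-check: detection must reproduce the ledger exactly
    detected_contacts = find_contacts(pair, params)
    detected_hbonds = find_hbonds(pair, params)
    per_res = {}
    for pa, _la, _d in detected_contacts:
        lbl = f"{pa.residue_name.capitalize()}-{pa.residue_number}"
        per_res[lbl] = per_res.get(lbl, 0) + 1
    expected = {label: count for label, count, _ in ledger["contacts"]}
    if per_res != expected:
        raise GenerationError(f"unsatisfiable spec: contacts {per_res} != planted {expected}")
    hb_res = sorted(
        f"{pa.residue_name.capitalize()}-{pa.residue_number}" for pa, _la, _d in detected_hbonds
    )
    if hb_res != sorted(label for label, *_ in ledger["hbonds"]):
        raise GenerationError("unsatisfiable spec: spurious or missing hydrogen bonds")
    return pair, ledger


def make_score_table(
    spec: ScreenSpec, target_id: str = "T1"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic dock-score table plus its active/decoy label list.

    Decoys score ``Normal(μ, σ)`` and actives ``Normal(μ+δ, σ)`` with
    μ = ``baseline_score``, σ = ``noise_sd`` and δ = ``score_shift``
    (δ < 0 means actives dock better, since lower scores rank first).
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"active_{i+1}" for i in range(spec.n_actives)] + [
        f"decoy_{j+1}" for j in range(spec.n_decoys)
    ]
    classes = ["active"] * spec.n_actives + ["decoy"] * spec.n_decoys
    shifts = np.array([spec.score_shift] * spec.n_actives + [0.0] * spec.n_decoys)
    scores = spec.baseline_score + shifts + rng.normal(0.0, spec.noise_sd, len(ids))
    table = pd.DataFrame(
        {"compound_id": ids, "target_id": target_id, "dock_score": scores}
    )
    labels = pd.DataFrame({"compound_id": ids, "class": classes})
    return table, labels


# Curated single-attachment fragments (SMILES); enough for oversized requests
# to be a configuration error rather than silent recycling.
_R1_FRAGMENTS = (
    "[*]c1ccccc1",          # phenyl
    "[*]c1ccncc1",          # 4-pyridyl
    "[*]c1cccnc1",          # 3-pyridyl
    "[*]c1ccc(F)cc1",       # 4-fluorophenyl
    "[*]c1ccc(OC)cc1",      # 4-methoxyphenyl
    "[*]c1ccc(C)cc1",       # 4-tolyl
    "[*]c1ccco1",           # 2-furyl
    "[*]c1cccs1",           # 2-thienyl
    "[*]c1ccc(Cl)cc1",      # 4-chlorophenyl
    "[*]c1ccc2ncccc2c1",    # quinolinyl
    "[*]c1cnc2ccccc2n1",    # quinoxalinyl
    "[*]C1CCCCC1",          # cyclohexyl
)
_R2_FRAGMENTS = (
    "[*]OC",   # methoxy
    "[*]O",    # hydroxy
    "[*]N",    # amino
    "[*]F",    # fluoro
    "[*]Br",   # bromo
    "[*]Cl",   # chloro
    "[*]C",    # methyl
    "[*]C#N",  # cyano
)


def make_substituent_sets(
    n_r1: int = 9, n_r2: int = 5, seed: int = 0
) -> tuple[SubstituentSet, SubstituentSet]:
    """R1/R2 fragment sets of the requested sizes from the curated lists.

    The first ``n`` fragments are taken in list order (the canonical study
    configuration is 9 × 5); a nonzero seed shuffles the pick.
    """
    if n_r1 > len(_R1_FRAGMENTS) or n_r2 > len(_R2_FRAGMENTS):
        raise GenerationError(
            f"requested sizes ({n_r1}, {n_r2}) exceed curated lists "
            f"({len(_R1_FRAGMENTS)}, {len(_R2_FRAGMENTS)})"
        )
    r1, r2 = list(_R1_FRAGMENTS), list(_R2_FRAGMENTS)
    if seed:
        rng = np.random.default_rng(seed)
        r1 = list(rng.permutation(r1))
        r2 = list(rng.permutation(r2))
    return (
        SubstituentSet("R1", tuple(r1[:n_r1])),
        SubstituentSet("R2", tuple(r2[:n_r2])),
    )
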