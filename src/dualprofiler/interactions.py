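"""Geometric protein–ligand interaction detection on heavy atoms.

Two interaction classes are distinguished, following the conventions of
2-D interaction-diagram programs:

* non-bonded contacts — any protein/ligand heavy-atom pair whose distance
  falls in a window (default 2.9–3.9 Å);
* hydrogen bonds — donor/acceptor-capable heavy-atom pairs (N, O, S) within
  a shorter cutoff (default 3.35 Å). No angular term is applied because
  docked poses and crystal structures typically carry no hydrogens.

A pair counted as a hydrogen bond is not double-counted as a contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from dualprofiler.structures_io import Atom, ComplexPair

__all__ = [
    "ContactParams",
    "InteractionRecord",
    "find_contacts",
    "find_hbonds",
    "per_residue_counts",
]

ResidueKey = tuple[str, int, str]

#: Elements able to donate or accept a hydrogen bond (heavy-atom criterion).
HBOND_ELEMENTS = frozenset({"N", "O", "S"})


@dataclass(frozen=True)
class ContactParams:
    contact_min: float = 2.9
    contact_max: float = 3.9
    hbond_max: float = 3.35
    hbond_elements: frozenset = HBOND_ELEMENTS

    def __post_init__(self) -> None:
        if not (0 < self.contact_min < self.contact_max):
            raise ValueError("need 0 < contact_min < contact_max")
        if self.hbond_max > self.contact_max:
            raise ValueError("hbond_max must be <= contact_max")


@dataclass
class InteractionRecord:
    residue_key: ResidueKey
    label: str
    n_nonbonded: int = 0
    n_hbonds: int = 0
    hbond_lengths: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.hbond_lengths) != self.n_hbonds:
            raise ValueError("hbond_lengths length must equal n_hbonds")


Pair = tuple[Atom, Atom, float]


def _cross_distances(pair: ComplexPair):
    prot = list(pair.protein.atoms())
    lig = list(pair.ligand.atoms())
    if not prot or not lig:
        return prot, lig, np.zeros((len(prot), len(lig)))
    d = cdist(
        np.vstack([a.coordinates for a in prot]),
        np.vstack([a.coordinates for a in lig]),
    )
    return prot, lig, d


def find_hbonds(pair: ComplexPair, params: ContactParams | None = None) -> list[Pair]:
    """Hydrogen bonds as (protein atom, ligand atom, distance) triples.

    Both atoms must be hydrogen-bond capable (N/O/S) and within
    ``hbond_max``. Distances are rounded to 2 decimals for reporting.
    """
    params = params or ContactParams()
    prot, lig, d = _cross_distances(pair)
    out: list[Pair] = []
    for i, pa in enumerate(prot):
        if pa.element.upper() not in params.hbond_elements:
            continue
        for j, la in enumerate(lig):
            if la.element.upper() not in params.hbond_elements:
                continue
            if d[i, j] <= params.hbond_max:
                out.append((pa, la, round(float(d[i, j]), 2)))
    return out


def find_contacts(
    pair: ComplexPair,
    params: ContactParams | None = None,
    *,
    exclude_hbonds: bool = True,
) -> list[Pair]:
    """Non-bonded contacts: cross pairs with contact_min ≤ d ≤ contact_max.

    Pairs that qualify as hydrogen bonds are excluded (they are listed
    separately by :func:`find_hbonds`).
    """
    params = params or ContactParams()
    prot, lig, d = _cross_distances(pair)
    hbond_ids = set()
    if exclude_hbonds:
        hbond_ids = {(pa.serial, la.serial) for pa, la, _ in find_hbonds(pair, params)}
    out: list[Pair] = []
    for i, pa in enumerate(prot):
        for j, la in enumerate(lig):
            if (pa.serial, la.serial) in hbond_ids:
                continue
            if params.contact_min <= d[i, j] <= params.contact_max:
                out.append((pa, la, float(d[i, j])))
    return out


def per_residue_counts(contacts: list[Pair], hbonds: list[Pair]) -> list[InteractionRecord]:
    """Group interactions by protein residue; totals are conserved.

    Output is ordered by (chain, residue number).
    """
    records: dict[ResidueKey, InteractionRecord] = {}

    def _rec(atom: Atom) -> InteractionRecord:
        key = (atom.chain_id, atom.residue_number, atom.residue_name)
        if key not in records:
            label = f"{atom.residue_name.capitalize()}-{atom.residue_number}"
            records[key] = InteractionRecord(residue_key=key, label=label)
        return records[key]

    for pa, _la, _d in contacts:
        _rec(pa).n_nonbonded += 1
    for pa, _la, d in hbonds:
        rec = _rec(pa)
        rec.n_hbonds += 1
        rec.hbond_lengths.append(d)
    return sorted(records.values(), key=lambda r: (r.residue_key[0], r.residue_key[1]))
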