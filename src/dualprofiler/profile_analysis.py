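"""Binding profiles: merge interaction counts with ΔASA and compare ligands.

A :class:`BindingProfile` is the per-residue summary table of one docked
complex — the number of non-bonded contacts, hydrogen bonds (with lengths)
and the buried surface area ΔASA. Key residues are those maximizing ΔASA
or the contact count; binding modes of two ligands on the same target are
compared through the intersection of their interacting-residue sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from dualprofiler.interactions import InteractionRecord
from dualprofiler.surface_area import DeltaASAMap

__all__ = [
    "ProfileRecord",
    "BindingProfile",
    "KeyResidueReport",
    "build_profile",
    "key_residues",
    "common_residues",
    "intersect_residue_labels",
    "residue_sort_key",
]


def residue_sort_key(label: str) -> tuple[int, str]:
    """Sort key for residue labels like ``Lys-890`` (by number, then name)."""
    m = re.search(r"-(\d+)$", label)
    return (int(m.group(1)) if m else 0, label)


@dataclass
class ProfileRecord:
    label: str
    n_nonbonded: int = 0
    n_hbonds: int = 0
    hbond_lengths: list[float] = field(default_factory=list)
    delta_asa: float = 0.0


@dataclass
class BindingProfile:
    ligand_id: str
    target_id: str
    records: list[ProfileRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.records]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate residue labels in profile")
        self.records.sort(key=lambda r: residue_sort_key(r.label))

    def interacting_labels(self) -> list[str]:
        """Residues with at least one contact or hydrogen bond."""
        return [r.label for r in self.records if r.n_nonbonded > 0 or r.n_hbonds > 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": [r.label for r in self.records],
                "n_nonbonded": [r.n_nonbonded for r in self.records],
                "n_hbonds": [r.n_hbonds for r in self.records],
                "delta_asa": [round(r.delta_asa, 2) for r in self.records],
            }
        )


@dataclass
class KeyResidueReport:
    max_dasa_residues: list[str]
    max_dasa_value: float
    max_contact_residues: list[str]
    max_contact_value: int


def build_profile(
    records: list[InteractionRecord],
    dasa_map: DeltaASAMap | dict[str, float] | None,
    ligand_id: str,
    target_id: str,
) -> BindingProfile:
    """Outer-join interaction records with a ΔASA map on residue identity.

    ``dasa_map`` may be a :class:`DeltaASAMap` (keys translated through its
    labels) or a plain ``{label: delta_asa}`` dict. Residues present in only
    one input appear with the missing quantity as 0.
    """
    dasa: dict[str, float] = {}
    if isinstance(dasa_map, DeltaASAMap):
        for key, value in dasa_map.delta_asa.items():
            label = dasa_map.labels.get(key) or f"{key[2].capitalize()}-{key[1]}"
            dasa[label] = value
    elif dasa_map:
        dasa = dict(dasa_map)

    merged: dict[str, ProfileRecord] = {}
    for rec in records:
        merged[rec.label] = ProfileRecord(
            label=rec.label,
            n_nonbonded=rec.n_nonbonded,
            n_hbonds=rec.n_hbonds,
            hbond_lengths=list(rec.hbond_lengths),
        )
    for label, value in dasa.items():
        merged.setdefault(label, ProfileRecord(label=label)).delta_asa = value
    return BindingProfile(ligand_id=ligand_id, target_id=target_id, records=list(merged.values()))


def key_residues(p: BindingProfile) -> KeyResidueReport:
    """Argmax over ΔASA and over contact count, reporting all ties.

    Both criteria are always reported separately — a single residue may win
    both, as Trp-2239 does for one target, or two residues may split them,
    as Lys-890 (ΔASA) and Met-953 (contacts) do for the other.
    """
    if not p.records:
        raise ValueError("cannot extract key residues from an empty profile")
    max_dasa = max(r.delta_asa for r in p.records)
    max_contacts = max(r.n_nonbonded for r in p.records)
    return KeyResidueReport(
        max_dasa_residues=[r.label for r in p.records if r.delta_asa == max_dasa],
        max_dasa_value=max_dasa,
        max_contact_residues=[r.label for r in p.records if r.n_nonbonded == max_contacts],
        max_contact_value=max_contacts,
    )


def intersect_residue_labels(a: list[str], b: list[str]) -> list[str]:
    """Intersection of two residue-label lists, ordered by residue number."""
    common = set(a) & set(b)
    return sorted(common, key=residue_sort_key)


def common_residues(p1: BindingProfile, p2: BindingProfile) -> list[str]:
    """Interacting residues shared by two ligands on the same target."""
    if p1.target_id != p2.target_id:
        raise ValueError(f"target mismatch: {p1.target_id!r} vs {p2.target_id!r}")
    return intersect_residue_labels(p1.interacting_labels(), p2.interacting_labels())
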