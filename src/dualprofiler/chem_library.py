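"""Combinatorial R-group enumeration and rule-of-five drug-likeness.

A scaffold is a SMILES string carrying two attachment markers, ``[*:1]``
(R1) and ``[*:2]`` (R2); substituents are single-attachment fragments
(``[*]...``). The library is the full R1 × R2 product, canonicalized and
named with sequential integers, R1 varying in the outer loop and R2 in the
inner one (compound = (r1−1)·|R2| + r2).

Descriptors follow the classic drug-likeness bookkeeping: molecular weight
with implicit hydrogens, H-bond donors as N/O atoms bearing ≥1 H, H-bond
acceptors as the N+O count, rotatable bonds as non-ring single bonds
between substituted heavy atoms (amide C–N excluded), and Wildman–Crippen
logP. The rule-of-five verdicts use strict ``<`` thresholds
(MW 500, HBD 5, HBA 10, rotatable 10, logP 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

__all__ = [
    "Scaffold",
    "SubstituentSet",
    "EnumeratedCompound",
    "CompoundLibrary",
    "DescriptorSet",
    "LipinskiVerdict",
    "EnumerationError",
    "enumerate_library",
    "compute_descriptors",
    "lipinski_evaluate",
    "XL765_SMILES",
]

#: XL765 (PubChem CID 49867926): the quinoxaline bis-arylamine sulfonamide
#: used as the starting dual PI3K/mTOR inhibitor in the worked example.
XL765_SMILES = (
    "COc1cc(Nc2nc3ccccc3nc2NS(=O)(=O)c2ccc(NC(=O)c3ccc(C)c(OC)c3)cc2)cc(OC)c1"
)


class EnumerationError(ValueError):
    """Raised for chemically invalid scaffolds or fragments."""


@dataclass(frozen=True)
class Scaffold:
    """SMILES with exactly one ``[*:1]`` and one ``[*:2]`` attachment marker."""

    smiles: str

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise EnumerationError(f"scaffold does not parse: {self.smiles!r}")
        maps = sorted(
            a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0
        )
        if maps != [1, 2]:
            raise EnumerationError(
                f"scaffold needs exactly one [*:1] and one [*:2]; found map numbers {maps}"
            )


@dataclass(frozen=True)
class SubstituentSet:
    """Named set (R1 or R2) of single-attachment-point fragments."""

    label: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in ("R1", "R2"):
            raise EnumerationError("substituent set label must be 'R1' or 'R2'")
        if not self.members:
            raise EnumerationError(f"{self.label} substituent set is empty")
        for frag in self.members:
            mol = Chem.MolFromSmiles(frag)
            if mol is None:
                raise EnumerationError(f"{self.label} fragment does not parse: {frag!r}")
            n_dummy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
            if n_dummy != 1:
                raise EnumerationError(
                    f"{self.label} fragment {frag!r} must have exactly one attachment point"
                )

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnumeratedCompound:
    compound_number: int
    r1_index: int  # 1-based
    r2_index: int  # 1-based
    structure: str  # canonical SMILES


@dataclass
class CompoundLibrary:
    scaffold: Scaffold
    compounds: list[EnumeratedCompound] = field(default_factory=list)
    numbering: str = "R1-major/R2-minor"

    def __len__(self) -> int:
        return len(self.compounds)


def _mapped_fragment(frag_smiles: str, map_num: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(frag_smiles)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(map_num)
    return mol


def attach(scaffold: Scaffold, r1_fragment: str, r2_fragment: str) -> str:
    """Attach one R1 and one R2 fragment to the scaffold; canonical SMILES."""
    core = Chem.MolFromSmiles(scaffold.smiles)
    combo = Chem.CombineMols(core, _mapped_fragment(r1_fragment, 1))
    combo = Chem.CombineMols(combo, _mapped_fragment(r2_fragment, 2))
    try:
        product = Chem.molzip(combo)
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise EnumerationError(
            f"attachment failed for R1={r1_fragment!r}, R2={r2_fragment!r}: {exc}"
        ) from exc
    return Chem.MolToSmiles(product)


def enumerate_library(
    scaffold: Scaffold, r1: SubstituentSet, r2: SubstituentSet
) -> CompoundLibrary:
    """Full |R1|×|R2| product with systematic integer naming.

    Compound numbers run 1..|R1|·|R2| with R1 as the outer loop:
    number = (r1_index−1)·|R2| + r2_index.
    """
    if r1.label != "R1" or r2.label != "R2":
        raise EnumerationError("pass the R1 set first and the R2 set second")
    compounds = []
    for i, frag1 in enumerate(r1.members, start=1):
        for j, frag2 in enumerate(r2.members, start=1):
            number = (i - 1) * len(r2) + j
            compounds.append(
                EnumeratedCompound(
                    compound_number=number,
                    r1_index=i,
                    r2_index=j,
                    structure=attach(scaffold, frag1, frag2),
                )
            )
    return CompoundLibrary(scaffold=scaffold, compounds=compounds)


@dataclass(frozen=True)
class DescriptorSet:
    mol_weight: float
    hbd: int
    hba: int
    rotatable_bonds: int
    logp: float

    def __post_init__(self) -> None:
        if self.mol_weight <= 0:
            raise ValueError("mol_weight must be > 0")
        if min(self.hbd, self.hba, self.rotatable_bonds) < 0:
            raise ValueError("descriptor counts must be >= 0")


def compute_descriptors(structure: str) -> DescriptorSet:
    """Drug-likeness descriptors for a SMILES structure."""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise EnumerationError(f"structure does not parse: {structure!r}")
    return DescriptorSet(
        mol_weight=float(Descriptors.MolWt(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        hba=int(Lipinski.NOCount(mol)),
        rotatable_bonds=int(Lipinski.NumRotatableBonds(mol)),
        logp=float(Crippen.MolLogP(mol)),
    )


# (threshold, descriptor attribute) per rule, compared with strict "<"
RULE_OF_FIVE_THRESHOLDS = {
    "mol_weight": 500.0,
    "hbd": 5,
    "hba": 10,
    "rotatable_bonds": 10,
    "logp": 5.0,
}


@dataclass(frozen=True)
class LipinskiVerdict:
    rules: dict
    overall_pass: bool


def lipinski_evaluate(d: DescriptorSet) -> LipinskiVerdict:
    """Strict rule-of-five verdicts: value < threshold for every rule.

    A value exactly at a threshold (e.g. MW 500, 10 rotatable bonds) fails.
    """
    rules = {
        name: getattr(d, name) < threshold
        for name, threshold in RULE_OF_FIVE_THRESHOLDS.items()
    }
    return LipinskiVerdict(rules=rules, overall_pass=all(rules.values()))
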