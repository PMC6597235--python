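"""Macromolecular structure I/O and complex splitting.

A thin hierarchical model (Atom → Residue → Structure) tailored to
heavy-atom interface analysis: van der Waals radii live on the atoms, and a
docked complex can be split into protein and ligand halves while conserving
atoms. Parsing is delegated to Bio.PDB; writing emits standard fixed-column
ATOM/HETATM records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ComplexPair",
    "StructureError",
    "CHOTHIA_RADII",
    "DEFAULT_RADIUS",
    "read_structure",
    "write_structure",
    "split_complex",
    "assign_radii",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3", "SOL"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common variants still treated as polymer
    "MSE", "SEC", "PYL", "HSD", "HSE", "HSP",
}

#: Chothia/Naccess-style heavy-atom van der Waals radii (Å), keyed by element.
CHOTHIA_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Fallback radius (Å) for elements missing from the chosen table.
DEFAULT_RADIUS = 1.80

RADIUS_SETS = {"chothia": CHOTHIA_RADII}


class StructureError(ValueError):
    """Raised for unreadable, empty or ambiguous structure inputs."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: np.ndarray
    vdw_radius: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise StructureError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.serial}: element symbol is empty")


@dataclass
class Residue:
    chain_id: str
    residue_number: int
    residue_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)

    @property
    def label(self) -> str:
        """Human-readable identity, e.g. ``Lys-890``."""
        return f"{self.residue_name.capitalize()}-{self.residue_number}"

    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_NAMES

    def is_polymer(self) -> bool:
        return self.residue_name.upper() in STANDARD_AMINO_ACIDS


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.sort()
        serials = [a.serial for a in self.atoms()]
        if len(serials) != len(set(serials)):
            raise StructureError(f"{self.source_id or 'structure'}: duplicate atom serials")

    def sort(self) -> None:
        self.residues.sort(key=lambda r: (r.chain_id, r.residue_number, r.residue_name))

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coordinates(self) -> np.ndarray:
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.vstack([a.coordinates for a in self.atoms()])

    def radii(self) -> np.ndarray:
        out = []
        for a in self.atoms():
            if a.vdw_radius is None:
                raise StructureError(f"atom {a.serial} has no van der Waals radius assigned")
            out.append(a.vdw_radius)
        return np.asarray(out, dtype=float)


@dataclass
class ComplexPair:
    """A docked complex split into its protein and ligand halves."""

    protein: Structure
    ligand: Structure
    complex: Structure

    def __post_init__(self) -> None:
        if self.protein.n_atoms + self.ligand.n_atoms != self.complex.n_atoms:
            raise StructureError("complex atom count != protein + ligand atoms")
        p = {a.serial for a in self.protein.atoms()}
        l = {a.serial for a in self.ligand.atoms()}
        if p & l:
            raise StructureError("protein and ligand share atom serials")


def _pick_altloc(bio_atom):
    """Resolve a possibly disordered Bio.PDB atom: highest occupancy, tie → altloc 'A'."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = list(bio_atom.child_dict.values())
    best = max(children, key=lambda a: (a.get_occupancy() or 0.0, a.get_altloc() == "A"))
    return best


def read_structure(
    path: str | Path,
    *,
    keep_waters: bool = False,
    keep_hydrogens: bool = False,
    source_id: str | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Every ATOM/HETATM record becomes one :class:`Atom`; alternate locations
    are resolved by occupancy (tie-break altloc 'A'). Waters and hydrogens
    are dropped by default — interface analyses here operate on heavy atoms,
    matching the conventions of surface-area and contact programs.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            model = parser.get_structure(path.stem, str(path))[0]
    except Exception as exc:  # pragma: no cover - malformed input
        raise StructureError(f"could not parse PDB file {path}: {exc}") from exc

    residues: list[Residue] = []
    for chain in model:
        for bio_res in chain:
            resname = bio_res.get_resname().strip()
            if not keep_waters and resname.upper() in WATER_NAMES:
                continue
            het, resnum, _icode = bio_res.get_id()
            atoms = []
            for name, bio_atom in bio_res.child_dict.items():
                bio_atom = _pick_altloc(bio_atom)
                element = (bio_atom.element or "").strip().upper() or name.strip()[0]
                if not keep_hydrogens and element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        serial=int(bio_atom.get_serial_number()),
                        name=name.strip(),
                        element=element,
                        residue_name=resname,
                        chain_id=chain.id,
                        residue_number=int(resnum),
                        coordinates=np.asarray(bio_atom.get_coord(), dtype=float),
                    )
                )
            if atoms:
                residues.append(Residue(chain.id, int(resnum), resname, atoms))

    if not residues:
        raise StructureError(f"{path}: no atoms left after filtering")
    # guard against duplicate serials from sloppy files: renumber if needed
    serials = [a.serial for r in residues for a in r.atoms]
    if len(serials) != len(set(serials)):
        logger.warning("%s: duplicate atom serials; renumbering sequentially", path)
        for i, atom in enumerate((a for r in residues for a in r.atoms), start=1):
            atom.serial = i
    return Structure(residues=residues, source_id=source_id or path.stem)


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a structure as fixed-column PDB ATOM/HETATM records."""
    path = Path(path)
    lines = []
    for res in s.residues:
        record = "ATOM  " if res.is_polymer() else "HETATM"
        for a in res.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.coordinates
            lines.append(
                f"{record}{a.serial:>5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
                f"{a.chain_id:1s}{a.residue_number:>4d}{'':4s}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"{'':10s}{a.element:>2s}"
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _matches(res: Residue, selector) -> bool:
    if isinstance(selector, str):
        return res.residue_name.upper() == selector.upper()
    chain, number = selector
    return res.chain_id == chain and res.residue_number == int(number)


def split_complex(
    s: Structure,
    ligand_selector,
    *,
    include_hetero: bool = False,
    include_waters: bool = False,
) -> ComplexPair:
    """Split a docked complex into protein and ligand.

    ``ligand_selector`` is either a residue name (e.g. ``"LIG"``) or a
    ``(chain_id, residue_number)`` pair and must match exactly one residue.
    The protein half keeps polymer residues; other heteroatom residues and
    waters are dropped unless the corresponding flag re-includes them.
    """
    matched = [r for r in s.residues if _matches(r, ligand_selector)]
    if len(matched) != 1:
        raise StructureError(
            f"ligand selector {ligand_selector!r} matched {len(matched)} residues; need exactly 1"
        )
    ligand_res = matched[0]
    protein_res = []
    for r in s.residues:
        if r is ligand_res:
            continue
        if r.is_water() and not include_waters:
            continue
        if not r.is_polymer() and not r.is_water() and not include_hetero:
            continue
        protein_res.append(r)
    protein = Structure(residues=protein_res, source_id=f"{s.source_id}:protein")
    ligand = Structure(residues=[ligand_res], source_id=f"{s.source_id}:ligand")
    complex_s = Structure(residues=protein_res + [ligand_res], source_id=s.source_id)
    return ComplexPair(protein=protein, ligand=ligand, complex=complex_s)


def assign_radii(s: Structure, radius_set: str | dict = "chothia") -> Structure:
    """Assign van der Waals radii by element; unknown elements get 1.80 Å.

    Returns the same structure (mutated in place) for chaining.
    """
    table = RADIUS_SETS[radius_set] if isinstance(radius_set, str) else radius_set
    for atom in s.atoms():
        radius = table.get(atom.element.upper())
        if radius is None:
            logger.warning(
                "element %r (atom %d) not in radius table; using default %.2f Å",
                atom.element, atom.serial, DEFAULT_RADIUS,
            )
            radius = DEFAULT_RADIUS
        atom.vdw_radius = radius
    return s
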