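"""Hierarchical protein structure container and PDB input/output.

A :class:`Structure` is an ordered list of :class:`Residue` objects (each an
ordered list of :class:`Atom`), plus a separate list of ligand residues
(HETATM groups).  Author residue numbering, chain identifiers and insertion
codes are preserved verbatim: downstream analyses cite residues by the
numbers deposited with the template structure, so nothing is ever renumbered
silently.

Parsing and serialisation are delegated to :mod:`gemmi`; this module only
converts between gemmi's model and the lightweight containers used by the
modeling pipeline.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SiteCatalog",
    "FormatError",
    "read_structure",
    "write_structure",
    "extract_sequence",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class FormatError(ValueError):
    """Raised when a file contains no parsable structural records."""


@dataclass
class Atom:
    """A single heavy atom with Cartesian coordinates in Angstroms."""

    name: str
    element: str
    coord: np.ndarray
    altloc: str = ""
    is_ligand_atom: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite triple")


@dataclass
class Residue:
    """An amino-acid residue or ligand group, keyed by author numbering."""

    chain_id: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain_id}{self.number}{self.icode} ({self.name}) has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def is_ligand(self) -> bool:
        return any(a.is_ligand_atom for a in self.atoms)

    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class Structure:
    """Ordered protein residues plus ligand groups."""

    residues: list[Residue] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        if not self.residues and not self.ligands:
            raise ValueError("Structure requires at least one residue")
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues + self.ligands:
            if r.id in seen:
                raise ValueError(f"duplicate residue id {r.id}")
            seen.add(r.id)

    # -- lookup ----------------------------------------------------------

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def chain(self, chain_id: str) -> list[Residue]:
        found = [r for r in self.residues if r.chain_id == chain_id]
        if not found:
            raise KeyError(f"no chain {chain_id!r}")
        return found

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.chain_id == chain_id and r.number == number and r.icode == icode:
                return r
        raise KeyError(f"no residue {chain_id}/{number}{icode}")

    def get_ligand(self, name: str) -> Residue:
        for r in self.ligands:
            if r.name == name:
                return r
        raise KeyError(f"no ligand {name!r}")

    # -- bulk coordinates -------------------------------------------------

    def all_atoms(self) -> list[Atom]:
        """All atoms in stable order: protein residues first, then ligands."""
        out: list[Atom] = []
        for r in self.residues:
            out.extend(r.atoms)
        for r in self.ligands:
            out.extend(r.atoms)
        return out

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.all_atoms()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        atoms = self.all_atoms()
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, c in zip(atoms, coords):
            a.coord = c.copy()

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


@dataclass
class SiteCatalog:
    """Map from a functional role label to a residue address.

    Roles name the residues the analyses revolve around, e.g.
    ``catalytic_asp_1`` / ``catalytic_asp_2`` for the editing-pocket
    aspartates, ``bn2_site`` for the CP1 glycine, ``suppressor_site`` for a
    hinge residue, ``pocket_site`` for anticodon-pocket positions.
    """

    entries: dict[str, tuple[str, int]] = field(default_factory=dict)

    def resolve(self, s: Structure, role: str) -> Residue:
        if role not in self.entries:
            raise KeyError(f"no site role {role!r}")
        chain_id, number = self.entries[role]
        return s.get_residue(chain_id, number)

    def validate(self, s: Structure) -> None:
        for role in self.entries:
            self.resolve(s, role)


# ---------------------------------------------------------------------------
# PDB input / output (gemmi-backed)
# ---------------------------------------------------------------------------


def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name (ties: first seen)."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in res:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occ > best[a.name].occ:
            best[a.name] = a
    return [best[n] for n in order]


def read_structure(
    path: str,
    keep_hydrogens: bool = False,
    keep_waters: bool = False,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first model of a multi-model file is used.  HETATM groups become
    ligand residues; waters and hydrogens are dropped unless requested.
    Alternate locations collapse to the highest-occupancy conformer.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise IOError(f"cannot read structure file {path!r}: {exc}") from exc

    residues: list[Residue] = []
    ligands: list[Residue] = []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for gres in chain:
                if not keep_waters and gres.name in WATER_NAMES:
                    continue
                is_het = gres.het_flag == "H" or gres.name not in THREE_TO_ONE
                atoms = []
                for ga in _pick_altloc(gres):
                    elem = ga.element.name.upper()
                    if not keep_hydrogens and elem in ("H", "D"):
                        continue
                    atoms.append(
                        Atom(
                            name=ga.name,
                            element=elem or "C",
                            coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                            altloc="",
                            is_ligand_atom=is_het,
                        )
                    )
                if not atoms:
                    continue
                res = Residue(
                    chain_id=chain.name,
                    number=gres.seqid.num,
                    icode=gres.seqid.icode.strip(),
                    name=gres.name,
                    atoms=atoms,
                )
                (ligands if is_het else residues).append(res)
    if not residues and not ligands:
        raise FormatError(f"no ATOM/HETATM records parsed from {path!r}")
    return Structure(residues=residues, ligands=ligands, title=st.name or "")


def write_structure(s: Structure, path: str) -> None:
    """Write a :class:`Structure` as PDB (coordinates to 3 decimals)."""
    st = gemmi.Structure()
    st.name = s.title or "pocketmod model"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def add(res: Residue, het: bool) -> None:
        if res.chain_id not in chains:
            chains[res.chain_id] = gemmi.Chain(res.chain_id)
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
        gres.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*np.round(a.coord, 3))
            ga.occ = 1.0
            gres.add_atom(ga)
        chains[res.chain_id].add_residue(gres)

    for res in s.residues:
        add(res, het=False)
    for res in s.ligands:
        add(res, het=True)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path!r}: {exc}") from exc


def extract_sequence(s: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain's protein residues (unknowns map to X)."""
    chain = s.chain(chain_id)  # raises KeyError for a missing/empty chain
    return "".join(r.one_letter() for r in chain)
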