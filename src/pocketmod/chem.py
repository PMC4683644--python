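"""Internal chemistry helpers: ideal residue geometry, torsions, topology.

Idealized heavy-atom coordinates and intra-residue connectivity for the 20
standard amino acids come from the chemical component dictionary bundled
with :mod:`biotite`.  On top of that this module provides

* side-chain grafting (replace a residue's side chain with idealized
  geometry for a new amino-acid type, keeping the backbone fixed),
* chi-torsion measurement and assignment,
* NeRF (natural extension reference frame) atom placement for building
  ideal backbones and chain extensions,
* a bond graph over a whole structure for nonbonded-exclusion lists,
* per-element Lennard-Jones parameters and van der Waals radii.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import biotite.structure.info as _bs_info

from .structio import Atom, Residue, Structure, ONE_TO_THREE

BACKBONE_ATOMS = ("N", "CA", "C")
BACKBONE_WITH_O = ("N", "CA", "C", "O")

# Ideal peptide internal coordinates (Engh & Huber-like values, Angstrom/deg)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

# sigma (A), epsilon (energy units) per element; r_min,ii = 2^(1/6) * sigma
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "C": (3.03, 0.10),
    "N": (2.76, 0.10),
    "O": (2.71, 0.10),
    "S": (3.21, 0.20),
    "P": (3.21, 0.20),
    "H": (2.00, 0.01),
}

VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}

# Side-chain chi torsion definitions (heavy atoms); proline's ring chi
# angles are not sampled.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


class ParameterizationError(ValueError):
    """An element with no Lennard-Jones parameters was encountered."""


def lj_for_element(element: str) -> tuple[float, float]:
    try:
        return LJ_PARAMS[element.upper()]
    except KeyError:
        raise ParameterizationError(f"no LJ parameters for element {element!r}")


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), 1.7)


# ---------------------------------------------------------------------------
# Ideal residue templates (from the bundled component dictionary)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def ideal_residue(resname: str) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray, tuple[tuple[int, int], ...]]:
    """Heavy-atom names, elements, ideal coordinates, and bonds for a residue.

    OXT and hydrogens are stripped; bonds are index pairs into the retained
    atom list.
    """
    arr = _bs_info.residue(resname)
    if arr is None:
        raise KeyError(f"no ideal geometry for residue {resname!r}")
    keep = [
        i
        for i in range(arr.array_length())
        if arr.element[i] not in ("H", "D") and arr.atom_name[i] != "OXT"
    ]
    remap = {old: new for new, old in enumerate(keep)}
    names = tuple(arr.atom_name[i] for i in keep)
    elements = tuple(arr.element[i].upper() for i in keep)
    coords = np.array([arr.coord[i] for i in keep], dtype=float)
    bonds = []
    for a, b, _ in arr.bonds.as_array():
        if a in remap and b in remap:
            i, j = remap[a], remap[b]
            bonds.append((min(i, j), max(i, j)))
    return names, elements, coords, tuple(sorted(set(bonds)))


@lru_cache(maxsize=64)
def residue_bonds_by_name(resname: str) -> tuple[tuple[str, str], ...]:
    names, _, _, bonds = ideal_residue(resname)
    return tuple((names[i], names[j]) for i, j in bonds)


@lru_cache(maxsize=256)
def chi_moving_atoms(resname: str, chi_index: int) -> frozenset[str]:
    """Atom names displaced when chi ``chi_index`` (0-based) rotates.

    Everything connected to the distal axis atom without passing back
    through the proximal axis atom, side-chain side only.
    """
    names, _, _, bonds = ideal_residue(resname)
    adj: dict[str, set[str]] = {n: set() for n in names}
    for i, j in bonds:
        adj[names[i]].add(names[j])
        adj[names[j]].add(names[i])
    _, ax_prox, ax_dist, _ = CHI_ATOMS[resname][chi_index]
    seen = {ax_prox, ax_dist}
    stack = [ax_dist]
    moving: set[str] = set()
    while stack:
        cur = stack.pop()
        for nb in sorted(adj.get(cur, ())):
            if nb not in seen:
                seen.add(nb)
                moving.add(nb)
                stack.append(nb)
    return frozenset(moving)


# ---------------------------------------------------------------------------
# Torsion geometry
# ---------------------------------------------------------------------------


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def rotate_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate points about an axis through ``origin`` (Rodrigues)."""
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    p = points - origin
    cos, sin = np.cos(theta), np.sin(theta)
    rotated = (
        p * cos
        + np.cross(axis, p) * sin
        + np.outer(np.dot(p, axis), axis) * (1.0 - cos)
    )
    return rotated + origin


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom D bonded to C, given chain A-B-C.

    ``bond`` = |CD|, ``angle_deg`` = angle B-C-D, ``dihedral_deg`` = torsion
    A-B-C-D.
    """
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.cos(phi) * np.sin(theta),
            bond * np.sin(phi) * np.sin(theta),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Superposition (used internally; public API lives in geometry)
# ---------------------------------------------------------------------------


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation/translation mapping ``moving`` onto ``target``.

    Returns ``(R, t)`` with the convention ``y = x @ R.T + t``; R is a
    proper rotation.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    h = (moving - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ct - rot @ cm
    return rot, trans


# ---------------------------------------------------------------------------
# Side-chain construction
# ---------------------------------------------------------------------------


def graft_sidechain(res: Residue, new_name: str) -> None:
    """Mutate ``res`` in place to amino-acid type ``new_name``.

    Backbone N/CA/C/O coordinates are untouched; side-chain heavy atoms are
    rebuilt with idealized geometry, positioned by superposing the ideal
    residue's N/CA/C onto the existing backbone.
    """
    if new_name not in ONE_TO_THREE.values():
        raise KeyError(f"not a standard amino acid: {new_name!r}")
    names, elements, coords, _ = ideal_residue(new_name)
    idx = {n: i for i, n in enumerate(names)}
    for bb in BACKBONE_ATOMS:
        if bb not in idx or not res.has_atom(bb):
            raise ValueError(f"backbone atom {bb} missing for grafting onto {res.id}")
    rot, trans = kabsch(
        np.array([coords[idx[bb]] for bb in BACKBONE_ATOMS]),
        np.array([res.atom(bb).coord for bb in BACKBONE_ATOMS]),
    )
    placed = coords @ rot.T + trans

    backbone = [a for a in res.atoms if a.name in BACKBONE_WITH_O]
    side = [
        Atom(name=n, element=e, coord=placed[i])
        for i, (n, e) in enumerate(zip(names, elements))
        if n not in BACKBONE_WITH_O
    ]
    res.name = new_name
    res.atoms = backbone + side


def get_chi_angles(res: Residue) -> list[float]:
    defs = CHI_ATOMS.get(res.name, [])
    out = []
    for quad in defs:
        if not all(res.has_atom(n) for n in quad):
            break
        out.append(dihedral(*(res.atom(n).coord for n in quad)))
    return out


def set_chi_angles(res: Residue, angles: tuple[float, ...] | list[float]) -> None:
    """Set side-chain chi torsions (degrees), rotating distal atoms."""
    defs = CHI_ATOMS.get(res.name, [])
    for k, target in enumerate(angles):
        if k >= len(defs):
            break
        quad = defs[k]
        if not all(res.has_atom(n) for n in quad):
            break
        current = dihedral(*(res.atom(n).coord for n in quad))
        delta = target - current
        origin = res.atom(quad[1]).coord
        axis = res.atom(quad[2]).coord - origin
        moving = chi_moving_atoms(res.name, k)
        for a in res.atoms:
            if a.name in moving:
                a.coord = rotate_about_axis(a.coord[None, :], origin, axis, delta)[0]


# ---------------------------------------------------------------------------
# Whole-structure bond topology
# ---------------------------------------------------------------------------

PEPTIDE_BOND_MAX = 2.5  # A; C(i)-N(i+1) sanity check


def infer_ligand_bonds(res: Residue) -> list[tuple[int, int]]:
    """Distance-based bonds within a ligand/unknown residue."""
    coords = res.coords()
    bonds = []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            limit = 0.6 * (vdw_radius(res.atoms[i].element) + vdw_radius(res.atoms[j].element))
            if np.linalg.norm(coords[i] - coords[j]) < max(limit, 1.8):
                bonds.append((i, j))
    return bonds


def build_bond_graph(s: Structure) -> list[tuple[int, int]]:
    """Bonds as global atom-index pairs over ``s.all_atoms()`` order.

    Standard residues use dictionary connectivity; ligands use distance
    inference; consecutive protein residues in the same chain get a peptide
    C-N bond when geometrically plausible.
    """
    bonds: list[tuple[int, int]] = []
    offset = 0
    offsets: list[int] = []
    for res in s.residues + s.ligands:
        offsets.append(offset)
        local = {a.name: i for i, a in enumerate(res.atoms)}
        if res.name in ONE_TO_THREE.values():
            for n1, n2 in residue_bonds_by_name(res.name):
                if n1 in local and n2 in local:
                    bonds.append((offset + local[n1], offset + local[n2]))
        else:
            for i, j in infer_ligand_bonds(res):
                bonds.append((offset + i, offset + j))
        offset += len(res.atoms)

    for k in range(len(s.residues) - 1):
        r1, r2 = s.residues[k], s.residues[k + 1]
        if r1.chain_id != r2.chain_id:
            continue
        if r1.has_atom("C") and r2.has_atom("N"):
            if np.linalg.norm(r1.atom("C").coord - r2.atom("N").coord) <= PEPTIDE_BOND_MAX:
                bonds.append((offsets[k] + [a.name for a in r1.atoms].index("C"),
                              offsets[k + 1] + [a.name for a in r2.atoms].index("N")))
    return bonds


def exclusion_table(n_atoms: int, bonds: list[tuple[int, int]]) -> dict[tuple[int, int], float]:
    """Nonbonded scale factors: 1-2 and 1-3 pairs 0.0, 1-4 pairs 0.2.

    Keys are ``(i, j)`` with ``i < j``; absent pairs have scale 1.
    """
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    table: dict[tuple[int, int], float] = {}

    def put(i: int, j: int, scale: float) -> None:
        if i == j:
            return
        key = (min(i, j), max(i, j))
        # closer topological relationships win
        if key not in table or scale < table[key]:
            table[key] = scale

    for i in adj:
        for j in adj[i]:
            put(i, j, 0.0)  # 1-2
            for k in adj[j]:
                if k != i:
                    put(i, k, 0.0)  # 1-3
                    for m in adj[k]:
                        if m != i and m != j:
                            put(i, m, 0.2)  # 1-4
    return table
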