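"""Synthetic fixtures with analytically known ground truth.

Real inputs to the modeling pipeline are crystal structures and database
sequences.  This module generates miniature stand-ins — ideal-geometry
helices and strands, edit scenarios (substitutions, one deletion, one
insertion), rigid planted ligands, and pocket sterics fixtures — whose
expected outcomes are computed by direct formula at generation time, so
every pipeline stage can be exercised and checked without any download.

The fixtures test mechanics, not biology: they make no attempt to imitate
a real aminoacyl-tRNA-synthetase fold.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import chem
from .geometry import ScissileBondDef
from .modelbuild import GapSpec, InsertionSpec
from .structio import Atom, ONE_TO_THREE, Residue, Structure, write_structure

__all__ = ["Scenario", "make_toy_template", "make_scenario", "SCENARIO_KINDS"]

SCENARIO_KINDS = (
    "substitution",
    "deletion",
    "insertion",
    "ligand",
    "mutation_displacement",
    "pocket",
)

_FOLD_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}

# default residue pool for generated sequences: compact, unambiguous types
_SEQ_POOL = "AVLISTDEKF"


@dataclass
class Scenario:
    """A generated fixture plus its analytically derived ground truth."""

    kind: str
    seed: int
    template: Structure
    target_seq: str | None = None
    expected_substitutions: list[tuple[str, int]] = field(default_factory=list)
    expected_gaps: list[GapSpec] = field(default_factory=list)
    expected_insertions: list[InsertionSpec] = field(default_factory=list)
    structures: dict[str, Structure] = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def write(self, out_dir: str) -> None:
        """Emit PDB fixtures plus a JSON ground-truth sidecar."""
        os.makedirs(out_dir, exist_ok=True)
        write_structure(self.template, os.path.join(out_dir, "template.pdb"))
        for name, s in self.structures.items():
            write_structure(s, os.path.join(out_dir, f"{name}.pdb"))
        sidecar = {
            "kind": self.kind,
            "seed": self.seed,
            "target_seq": self.target_seq,
            "ground_truth": self.ground_truth,
        }
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# Ideal-backbone construction
# ---------------------------------------------------------------------------


def _build_backbone(n_res: int, torsions: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """NeRF chain of N/CA/C/O coordinates from per-residue (phi, psi)."""
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([chem.BOND_N_CA, 0.0, 0.0])
    ang = np.radians(chem.ANGLE_N_CA_C)
    c0 = ca0 + chem.BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        phi, psi = torsions[i]
        _, psi_prev = torsions[i - 1]
        prev = coords[-1]
        n = chem.place_atom(prev["N"], prev["CA"], prev["C"],
                            chem.BOND_C_N, chem.ANGLE_CA_C_N, psi_prev)
        ca = chem.place_atom(prev["CA"], prev["C"], n,
                             chem.BOND_N_CA, chem.ANGLE_C_N_CA, chem.OMEGA)
        c = chem.place_atom(prev["C"], n, ca,
                            chem.BOND_CA_C, chem.ANGLE_N_CA_C, phi)
        coords.append({"N": n, "CA": ca, "C": c})
    for i, bb in enumerate(coords):
        psi = torsions[i][1]
        bb["O"] = chem.place_atom(bb["N"], bb["CA"], bb["C"],
                                  chem.BOND_C_O, chem.ANGLE_CA_C_O, psi + 180.0)
    return coords


def make_toy_template(
    n_res: int,
    fold: str = "helix",
    seed: int = 0,
    sequence: str | None = None,
    chain_id: str = "A",
    jitter: float = 0.0,
) -> Structure:
    """Ideal-geometry toy protein (helix, strand, or half-and-half mixed).

    Canonical bond lengths and angles throughout; side chains grafted with
    idealized internal coordinates.  Deterministic for a given seed (the
    seed draws the sequence when none is supplied and any coordinate
    jitter).
    """
    if n_res < 4:
        raise ValueError("n_res must be >= 4")
    rng = np.random.default_rng(seed)
    if fold in _FOLD_TORSIONS:
        torsions = [_FOLD_TORSIONS[fold]] * n_res
    elif fold == "mixed":
        half = n_res // 2
        torsions = [_FOLD_TORSIONS["helix"]] * half + [_FOLD_TORSIONS["strand"]] * (n_res - half)
    else:
        raise ValueError(f"unknown fold {fold!r}")
    if sequence is None:
        sequence = "".join(rng.choice(list(_SEQ_POOL)) for _ in range(n_res))
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")

    backbone = _build_backbone(n_res, torsions)
    residues = []
    for i, bb in enumerate(backbone):
        res = Residue(
            chain_id=chain_id,
            number=i + 1,
            name="GLY",
            atoms=[
                Atom(name=n, element=n[0], coord=bb[n].copy())
                for n in ("N", "CA", "C", "O")
            ],
        )
        aa = sequence[i].upper()
        if aa in ONE_TO_THREE and aa != "G":
            chem.graft_sidechain(res, ONE_TO_THREE[aa])
        residues.append(res)
    s = Structure(residues=residues, title=f"toy-{fold}-{n_res}")
    if jitter > 0:
        coords = s.coords()
        s.set_coords(coords + rng.normal(0.0, jitter, coords.shape))
    return s


# ---------------------------------------------------------------------------
# Ligand construction
# ---------------------------------------------------------------------------

# rigid synthetic adenylate stand-in; C1-O1 is the scissile bond
_LIGAND_ATOMS = [
    ("C1", "C", np.array([0.0, 0.0, 0.0])),
    ("O1", "O", np.array([1.40, 0.0, 0.0])),
    ("O2", "O", np.array([-0.65, 1.05, 0.0])),
    ("C2", "C", np.array([-0.80, -1.25, 0.0])),
    ("N1", "N", np.array([-2.10, -1.15, 0.65])),
    ("P1", "P", np.array([2.55, 0.85, 0.35])),
]

SCISSILE = ScissileBondDef(ligand_name="VAD", atom_a="C1", atom_b="O1")


def make_ligand(center: np.ndarray, chain_id: str = "L", number: int = 1) -> Residue:
    """Synthetic rigid adenylate analog centered at ``center``."""
    center = np.asarray(center, dtype=float)
    return Residue(
        chain_id=chain_id,
        number=number,
        name=SCISSILE.ligand_name,
        atoms=[
            Atom(name=n, element=e, coord=center + off, is_ligand_atom=True)
            for n, e, off in _LIGAND_ATOMS
        ],
    )


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _transform_structure(s: Structure, rot: np.ndarray, trans: np.ndarray) -> Structure:
    out = s.copy()
    out.set_coords(out.coords() @ rot.T + trans)
    return out


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def make_scenario(kind: str, seed: int = 0) -> Scenario:
    """Generate one fixture family; ground truth is computed analytically
    from the generated coordinates (no pipeline code involved)."""
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}; choose from {SCENARIO_KINDS}")
    return _MAKERS[kind](seed)


def _scenario_substitution(seed: int) -> Scenario:
    seq = "AVLSTIDEKLAF"
    template = make_toy_template(len(seq), "helix", seed=seed, sequence=seq)
    target = list(seq)
    target[3] = "D"  # S -> D
    target[7] = "L"  # E -> L
    target_seq = "".join(target)
    return Scenario(
        kind="substitution",
        seed=seed,
        template=template,
        target_seq=target_seq,
        expected_substitutions=[("A", 4), ("A", 8)],
        ground_truth={"n_substitutions": 2, "identity_percent": 100.0 * 10 / 12},
    )


def _scenario_deletion(seed: int) -> Scenario:
    seq = "AVLSTIDEKLAFVTSE"
    template = make_toy_template(len(seq), "helix", seed=seed, sequence=seq)
    target_seq = seq[:7] + seq[10:]  # delete residues 8-10 (1-based)
    gap = GapSpec(stationary=("A", 7), mobile=("A", 11))
    return Scenario(
        kind="deletion",
        seed=seed,
        template=template,
        target_seq=target_seq,
        expected_gaps=[gap],
        ground_truth={
            "deleted_span": [8, 10],
            "deleted_length": 3,
            # both flanks carry identical ideal internal geometry, so the
            # harmonic minimum over rigid motions closes the gap exactly
            "expected_closure_rmsd": 0.0,
        },
    )


def _scenario_insertion(seed: int) -> Scenario:
    seq = "AVLSTIDEKLAFVTS"
    full = make_toy_template(len(seq), "helix", seed=seed, sequence=seq)
    template = full.copy()
    removed = template.residues.pop(7)  # residue 8 (1-based); target re-inserts it
    for i, r in enumerate(template.residues):
        r.number = i + 1
    ins = InsertionSpec(anchor_n=("A", 7), anchor_c=("A", 8), inserted_sequence=seq[7])
    return Scenario(
        kind="insertion",
        seed=seed,
        template=template,
        target_seq=seq,
        expected_insertions=[ins],
        structures={"fragment_source": full},
        ground_truth={
            "inserted_length": 1,
            "expected_junction_rmsd": 0.0,
            "planted_residue_ca": removed.atom("CA").coord.tolist(),
        },
    )


def _scenario_ligand(seed: int) -> Scenario:
    rng = np.random.default_rng(seed)
    seq = "AVLSTIDEKLAF"
    model = make_toy_template(len(seq), "helix", seed=seed, sequence=seq)
    domain = [("A", n) for n in range(4, 10)]
    ca_mid = np.mean([model.get_residue("A", n).atom("CA").coord for n in range(4, 10)], axis=0)
    pose_in_model = ca_mid + np.array([4.0, 1.0, -2.0])

    rot = _rotation(rng.normal(size=3), float(rng.uniform(15, 60)))
    trans = rng.uniform(-8, 8, size=3)
    donor = _transform_structure(model, rot, trans)
    donor.ligands.append(
        Residue(
            chain_id="L",
            number=1,
            name=SCISSILE.ligand_name,
            atoms=[
                Atom(name=a.name, element=a.element,
                     coord=a.coord @ rot.T + trans, is_ligand_atom=True)
                for a in make_ligand(pose_in_model).atoms
            ],
        )
    )
    return Scenario(
        kind="ligand",
        seed=seed,
        template=model,
        structures={"donor": donor},
        ground_truth={
            "domain": [list(d) for d in domain],
            "planted_rotation": rot.tolist(),
            "planted_translation": trans.tolist(),
            "planted_pose": [
                (np.asarray(pose_in_model) + off).tolist() for _, _, off in _LIGAND_ATOMS
            ],
        },
    )


def _scenario_mutation_displacement(seed: int) -> Scenario:
    seq = "AVLSTIDEKLAFVT"
    wt = make_toy_template(len(seq), "helix", seed=seed, sequence=seq)
    site = ("A", 6)
    ca6 = wt.get_residue(*site).atom("CA").coord
    lig_center = ca6 + np.array([6.0, 2.0, 1.0])
    wt.ligands.append(make_ligand(lig_center))
    shift = np.array([2.0, 0.0, 0.0])
    shifted = wt.copy()
    lig = shifted.get_ligand(SCISSILE.ligand_name)
    for a in lig.atoms:
        a.coord = a.coord + shift

    def midpoint(center: np.ndarray) -> np.ndarray:
        offs = {n: off for n, _, off in _LIGAND_ATOMS}
        return center + 0.5 * (offs["C1"] + offs["O1"])

    d_wt = float(np.linalg.norm(ca6 - midpoint(lig_center)))
    d_shift = float(np.linalg.norm(ca6 - midpoint(lig_center + shift)))
    return Scenario(
        kind="mutation_displacement",
        seed=seed,
        template=wt,
        structures={"wild_type": wt, "shifted": shifted},
        ground_truth={
            "site": list(site),
            "planted_shift": 2.0,
            "wt_probe_distance": d_wt,
            "shifted_probe_distance": d_shift,
        },
    )


def _scenario_pocket(seed: int) -> Scenario:
    rng = np.random.default_rng(seed)
    del rng  # geometry is fully planted; the seed only tags the fixture

    def pocket_structure(ring_radius: float, extra_inward: bool) -> Structure:
        residues = []
        n_sites = 6
        for k in range(n_sites):
            ang = 2 * np.pi * k / n_sites
            center = ring_radius * np.array([np.cos(ang), np.sin(ang), 0.0])
            outward = center / np.linalg.norm(center)
            atoms = [
                Atom("N", "N", center + 1.2 * outward + np.array([0, 0, 0.5])),
                Atom("CA", "C", center),
                Atom("C", "C", center + 1.2 * outward - np.array([0, 0, 0.5])),
                Atom("O", "O", center + 2.2 * outward),
            ]
            if extra_inward:
                atoms.append(Atom("CB", "C", center - 3.0 * outward))
            residues.append(Residue("A", k + 1, "GLY" if not extra_inward else "LEU", atoms))
        s = Structure(residues=residues, title="toy-pocket")
        s.ligands.append(
            Residue(
                "P", 1, "PRB",
                atoms=[
                    Atom("C1", "C", np.array([0.0, 0.0, 0.0]), is_ligand_atom=True),
                    Atom("C2", "C", np.array([1.2, 0.0, 0.0]), is_ligand_atom=True),
                ],
            )
        )
        return s

    small = pocket_structure(6.0, extra_inward=False)
    bulky = pocket_structure(6.0, extra_inward=True)

    def count_clashes(s: Structure) -> int:
        probe = s.get_ligand("PRB")
        n = 0
        for res in s.residues:
            for a in res.atoms:
                for b in probe.atoms:
                    vsum = chem.vdw_radius(a.element) + chem.vdw_radius(b.element)
                    if vsum - np.linalg.norm(a.coord - b.coord) > 1e-9:
                        n += 1
        return n

    return Scenario(
        kind="pocket",
        seed=seed,
        template=small,
        structures={"small": small, "bulky": bulky},
        ground_truth={
            "pocket_sites": [["A", k] for k in range(1, 7)],
            "probe": "PRB",
            "clash_count_small": count_clashes(small),
            "clash_count_bulky": count_clashes(bulky),
        },
    )


_MAKERS = {
    "substitution": _scenario_substitution,
    "deletion": _scenario_deletion,
    "insertion": _scenario_insertion,
    "ligand": _scenario_ligand,
    "mutation_displacement": _scenario_mutation_displacement,
    "pocket": _scenario_pocket,
}
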