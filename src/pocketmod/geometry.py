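"""Quantitative structure analysis: superposition, probe distances, sterics.

This module produces the numbers the modeling pipeline exists for: how far
a residue of interest sits from the scissile bond of the bound adenylate
substrate, how far two mutation sites are from each other, and how crowded
a binding pocket is.  It also carries the small genomic-interval utility
used to size deletion lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .structio import Residue, SiteCatalog, Structure

__all__ = [
    "ScissileBondDef",
    "GeometryReport",
    "ClashReport",
    "GenomicInterval",
    "kabsch_superpose",
    "apply_transform",
    "backbone_rmsd",
    "scissile_distance",
    "site_distance",
    "pocket_clash",
    "interval_length",
    "geometry_report",
]


@dataclass(frozen=True)
class ScissileBondDef:
    """Names the two bonded ligand atoms whose midpoint is the reference.

    For a valyl-adenylate the bond of interest joins the valine carbonyl
    carbon to the bridging oxygen of the adenylate; ligand dictionaries
    differ in atom naming, so the pair is configuration, not convention.
    """

    ligand_name: str
    atom_a: str
    atom_b: str

    def midpoint(self, s: Structure) -> np.ndarray:
        lig = s.get_ligand(self.ligand_name)
        return 0.5 * (lig.atom(self.atom_a).coord + lig.atom(self.atom_b).coord)


@dataclass
class GeometryReport:
    """Probe distances (A) for one model, plus deltas versus a reference."""

    label: str
    probe_distances: dict[tuple[str, str], float]
    scissile_definition: ScissileBondDef
    deltas: dict[tuple[str, str], float] = field(default_factory=dict)
    superposition_rmsd: float = 0.0


@dataclass
class ClashReport:
    """Steric analysis of a pocket against a probe group."""

    pocket_residues: list[tuple[str, int]]
    overlaps: list[tuple[str, str, float]]  # (pocket atom, probe atom, overlap A)
    clash_count: int
    occupied_volume: float  # A^3, grid proxy
    free_volume: float  # A^3, grid proxy within the pocket bounding box


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, inclusive nucleotide interval (both endpoints counted)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")


def interval_length(iv: GenomicInterval) -> int:
    """Length in base pairs of a 1-based inclusive interval."""
    return iv.end - iv.start + 1


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired point sets.

    Returns ``(R, t, rmsd)`` with ``y = x @ R.T + t`` and ``det(R) = +1``.
    Requires at least three non-collinear points.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(moving) < 3:
        raise ValueError("superposition requires >= 3 points")
    centered = moving - moving.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, trans = chem.kabsch(moving, target)
    fitted = moving @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rot.T + trans


def backbone_rmsd(model: Structure, reference: Structure,
                  superpose: bool = True) -> float:
    """CA RMSD over residues shared by author (chain, number, icode) id.

    One round of Kabsch superposition precedes the measurement unless
    ``superpose`` is disabled.
    """
    ref_ca = {r.id: r.atom("CA").coord for r in reference.residues if r.has_atom("CA")}
    pairs = [
        (r.atom("CA").coord, ref_ca[r.id])
        for r in model.residues
        if r.has_atom("CA") and r.id in ref_ca
    ]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 shared CA atoms")
    mov = np.array([p[0] for p in pairs])
    tgt = np.array([p[1] for p in pairs])
    if superpose:
        _, _, rmsd = kabsch_superpose(mov, tgt)
        return rmsd
    return float(np.sqrt(np.mean(np.sum((mov - tgt) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Probe distances
# ---------------------------------------------------------------------------

# carboxyl(ate) carbon per residue type for the "carboxyl" probe rule
_CARBOXYL_CARBON = {"ASP": "CG", "GLU": "CD"}
_CARBOXYL_GROUP = {"ASP": ("CG", "OD1", "OD2"), "GLU": ("CD", "OE1", "OE2")}


def _probe_atoms(res: Residue, probe_rule: str) -> list[np.ndarray]:
    if probe_rule == "CA":
        return [res.atom("CA").coord]
    if probe_rule == "carboxyl":
        if res.name not in _CARBOXYL_CARBON:
            raise KeyError(f"residue {res.name} at {res.id} has no carboxyl probe")
        return [res.atom(_CARBOXYL_CARBON[res.name]).coord]
    if probe_rule == "carboxyl_min":
        if res.name not in _CARBOXYL_GROUP:
            raise KeyError(f"residue {res.name} at {res.id} has no carboxyl probe")
        return [res.atom(n).coord for n in _CARBOXYL_GROUP[res.name] if res.has_atom(n)]
    raise ValueError(f"unknown probe rule {probe_rule!r}")


def scissile_distance(s: Structure, site: Residue | tuple[str, int],
                      probe_rule: str, scissile: ScissileBondDef) -> float:
    """Distance (A) from a site's probe atom to the scissile-bond midpoint.

    ``probe_rule`` is ``"CA"`` (alpha carbon), ``"carboxyl"`` (carboxyl
    carbon of Asp/Glu), or ``"carboxyl_min"`` (minimum over the carboxyl
    group's heavy atoms).
    """
    res = s.get_residue(*site) if isinstance(site, tuple) else site
    mid = scissile.midpoint(s)
    return min(float(np.linalg.norm(p - mid)) for p in _probe_atoms(res, probe_rule))


def site_distance(s: Structure, site_a: tuple[str, int], site_b: tuple[str, int],
                  atom_rule: str = "CA") -> float:
    """Distance between representative atoms (default CA) of two sites."""
    ra = s.get_residue(*site_a)
    rb = s.get_residue(*site_b)
    return float(np.linalg.norm(ra.atom(atom_rule).coord - rb.atom(atom_rule).coord))


# ---------------------------------------------------------------------------
# Pocket sterics
# ---------------------------------------------------------------------------


def pocket_clash(
    s: Structure,
    pocket_sites: list[tuple[str, int]],
    probe: str | list[tuple[str, int]],
    grid_spacing: float = 0.5,
    padding: float = 2.0,
    radius_scale: float = 1.0,
    vdw_radii: dict[str, float] | None = None,
) -> ClashReport:
    """Steric overlap of a pocket against a probe ligand or residue group.

    An overlap is recorded for every pocket/probe atom pair closer than the
    sum of their van der Waals radii.  The volume proxy counts grid cells
    (``grid_spacing`` A) in the padded pocket bounding box that fall inside
    any atom sphere (occupied) or none (free); ``radius_scale`` inflates or
    deflates all probe radii.
    """
    radii = dict(chem.VDW_RADII)
    if vdw_radii:
        radii.update(vdw_radii)

    pocket_res = [s.get_residue(c, n) for c, n in pocket_sites]
    if isinstance(probe, str):
        probe_res = [s.get_ligand(probe)]
    else:
        probe_res = [s.get_residue(c, n) for c, n in probe]
    probe_atoms = [(r, a) for r in probe_res for a in r.atoms]
    if not probe_atoms:
        raise ValueError("empty probe selection")
    pocket_atoms = [(r, a) for r in pocket_res for a in r.atoms]

    overlaps: list[tuple[str, str, float]] = []
    for rp, ap in pocket_atoms:
        for rq, aq in probe_atoms:
            d = float(np.linalg.norm(ap.coord - aq.coord))
            vsum = radii.get(ap.element.upper(), 1.7) + radius_scale * radii.get(aq.element.upper(), 1.7)
            if vsum - d > 1e-9:
                overlaps.append(
                    (f"{rp.chain_id}{rp.number}:{ap.name}", f"{rq.name}:{aq.name}", vsum - d)
                )

    pk = np.array([a.coord for _, a in pocket_atoms])
    lo = pk.min(axis=0) - padding
    hi = pk.max(axis=0) + padding
    axes = [np.arange(lo[d] + grid_spacing / 2, hi[d], grid_spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    occupied = np.zeros(len(grid), dtype=bool)
    for group, scale in ((pocket_atoms, 1.0), (probe_atoms, radius_scale)):
        for _, a in group:
            rad = scale * radii.get(a.element.upper(), 1.7)
            d2 = np.sum((grid - a.coord) ** 2, axis=1)
            occupied |= d2 <= rad * rad
    cell = grid_spacing ** 3
    return ClashReport(
        pocket_residues=list(pocket_sites),
        overlaps=overlaps,
        clash_count=len(overlaps),
        occupied_volume=float(occupied.sum()) * cell,
        free_volume=float((~occupied).sum()) * cell,
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def geometry_report(
    models: dict[str, Structure],
    sites: SiteCatalog,
    probes: list[tuple[str, str]],
    scissile: ScissileBondDef,
    reference: str = "wild_type",
) -> dict[str, GeometryReport]:
    """Per-model probe-distance reports with deltas against a reference.

    ``probes`` lists (site role, probe rule) pairs; roles resolve through
    the site catalog; missing probe atoms (e.g. a carboxyl rule on a
    glycine) are propagated as errors for the model that lacks them, except
    that a carboxyl probe on the reference model is skipped when the
    reference residue genuinely has no carboxyl (the wild-type glycine
    case) — the delta is then reported only for models that do.
    """
    if reference not in models:
        raise KeyError(f"reference model {reference!r} not among models")
    reports: dict[str, GeometryReport] = {}
    ref_dist: dict[tuple[str, str], float] = {}
    for label, model in models.items():
        distances: dict[tuple[str, str], float] = {}
        for role, rule in probes:
            res = sites.resolve(model, role)
            try:
                distances[(role, rule)] = scissile_distance(model, res, rule, scissile)
            except KeyError:
                if label == reference:
                    continue  # reference lacks this probe chemistry
                raise
        reports[label] = GeometryReport(
            label=label,
            probe_distances=distances,
            scissile_definition=scissile,
        )
        if label == reference:
            ref_dist = distances
    for label, rep in reports.items():
        rep.deltas = {
            key: rep.probe_distances[key] - ref_dist[key]
            for key in rep.probe_distances
            if key in ref_dist
        }
    return reports
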