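"""Point-mutation modeling: fixed-backbone design and flexible refinement.

A mutation is introduced in two levels of rigor.  *Fixed-backbone* design
renames the residue, rebuilds its side chain with idealized geometry and
picks the best rotamer by whole-structure energy — no backbone coordinate
moves.  *Flexible-backbone* optimization then applies small phi/psi
perturbations to residues around the site, followed by gradient
minimization, iterating while the energy keeps improving.  Throughout the
flexible stage the bound ligand (and any tRNA group) stays under strong
harmonic restraints: it can move, but motion is heavily penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import chem
from .energy import (
    EnergyModel,
    HarmonicRestraint,
    MCParams,
    RotamerLibrary,
    ScoreConfig,
    atom_indices,
    minimize,
    sample_rotamers,
)
from .structio import ONE_TO_THREE, Residue, Structure

__all__ = [
    "MutationSpec",
    "FlexReport",
    "apply_mutation",
    "iterate_flexible",
    "ligand_restraints",
    "read_mutation_table",
]


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution in one-letter codes at an author position."""

    chain_id: str
    position: int
    from_aa: str
    to_aa: str
    label: str = ""

    def validate(self, s: Structure) -> Residue:
        res = s.get_residue(self.chain_id, self.position)
        if res.one_letter() != self.from_aa.upper():
            raise ValueError(
                f"mutation {self.label or self}: residue {self.chain_id}{self.position} "
                f"is {res.one_letter()}, not {self.from_aa}"
            )
        return res


@dataclass
class FlexReport:
    """Trace of the iterative flexible-backbone optimization."""

    energies: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = True
    max_restrained_displacement: float = 0.0


def ligand_restraints(s: Structure, k: float = 50.0) -> list[HarmonicRestraint]:
    """Strong positional tethers on every ligand atom at its current pose."""
    out = []
    gi = 0
    for res in s.residues + s.ligands:
        for a in res.atoms:
            if res.is_ligand:
                out.append(HarmonicRestraint(gi, a.coord.copy(), k))
            gi += 1
    return out


def _backbone_restraints(s: Structure, k: float = 1.0) -> list[HarmonicRestraint]:
    # weak CA tethers keep phi/psi jitter (which has a chain-length lever
    # arm) from drifting distal regions during minimization
    return [
        HarmonicRestraint(i, s.all_atoms()[i].coord.copy(), k)
        for i in atom_indices(s, atom_names=("CA",))
    ]


def _perturb_phi_psi(s: Structure, res: Residue, dphi: float, dpsi: float) -> None:
    chain = s.chain(res.chain_id)
    idx = chain.index(res)
    downstream = [a for r in chain[idx + 1 :] for a in r.atoms]
    if res.has_atom("N") and res.has_atom("CA"):
        origin = res.atom("N").coord
        axis = res.atom("CA").coord - origin
        movers = [a for a in res.atoms if a.name not in ("N",)] + downstream
        keep = {id(res.atom("CA"))}
        for a in movers:
            if id(a) in keep:
                continue
            a.coord = chem.rotate_about_axis(a.coord[None, :], origin, axis, dphi)[0]
    if res.has_atom("CA") and res.has_atom("C"):
        origin = res.atom("CA").coord
        axis = res.atom("C").coord - origin
        movers = [a for a in res.atoms if a.name == "O"] + downstream
        for a in movers:
            a.coord = chem.rotate_about_axis(a.coord[None, :], origin, axis, dpsi)[0]


def iterate_flexible(
    s: Structure,
    cfg: ScoreConfig,
    restraints: list[HarmonicRestraint],
    site: tuple[str, int],
    seed: int = 0,
    shell_radius: float = 8.0,
    jitter_deg: float = 3.0,
    tol: float = 1e-3,
    max_iter: int = 50,
    backbone_k: float = 1.0,
) -> tuple[Structure, FlexReport]:
    """Iterate (backbone jitter -> minimization) while energy improves.

    ``restraints`` must include the positional terms for the ligand/tRNA
    group.  Residues whose CA lies within ``shell_radius`` of the mutation
    site CA are jittered by uniform phi/psi perturbations of up to
    ``jitter_deg``.  Terminates when an iteration improves the energy by
    less than ``tol``; the best iterate is always returned.
    """
    rng = np.random.default_rng(seed)
    current = s.copy()
    all_restraints = list(restraints) + _backbone_restraints(current, k=backbone_k)
    model = EnergyModel(current, cfg, all_restraints)
    energy = model.total(current.coords())
    report = FlexReport(energies=[energy])

    site_res = current.get_residue(*site)
    site_ca = site_res.atom("CA").coord.copy()
    shell = [
        r
        for r in current.chain(site[0])
        if r.has_atom("CA") and np.linalg.norm(r.atom("CA").coord - site_ca) <= shell_radius
    ]
    shell_ids = [(r.chain_id, r.number, r.icode) for r in shell]

    restrained_targets = {r.atom_index: r.target for r in restraints}
    best = current
    best_e = energy
    for it in range(max_iter):
        trial = best.copy()
        for cid, num, icode in shell_ids:
            r = trial.get_residue(cid, num, icode)
            _perturb_phi_psi(
                trial,
                r,
                float(rng.uniform(-jitter_deg, jitter_deg)),
                float(rng.uniform(-jitter_deg, jitter_deg)),
            )
        trial = minimize(trial, cfg, all_restraints, movable=None, max_iter=100)
        e_trial = EnergyModel(trial, cfg, all_restraints).total(trial.coords())
        report.iterations = it + 1
        report.energies.append(e_trial)
        improvement = best_e - e_trial
        if e_trial < best_e:
            best, best_e = trial, e_trial
        if improvement < tol:
            break
    else:
        report.converged = False

    coords = best.coords()
    if restrained_targets:
        report.max_restrained_displacement = max(
            float(np.linalg.norm(coords[i] - t)) for i, t in restrained_targets.items()
        )
    return best, report


def apply_mutation(
    s: Structure,
    m: MutationSpec,
    mode: str,
    cfg: ScoreConfig,
    lib: RotamerLibrary,
    mc: MCParams,
    ligand_k: float = 50.0,
) -> Structure:
    """Model a point mutation in ``fixed`` or ``flexible`` mode.

    Fixed mode changes only the mutated residue's side-chain atoms (backbone
    equality is exact); flexible mode additionally relaxes the backbone
    around the site under strong ligand restraints and never ends with a
    higher energy than the fixed-mode result.
    """
    if mode not in ("fixed", "flexible"):
        raise ValueError(f"unknown mode {mode!r}")
    m.validate(s)
    out = s.copy()
    res = out.get_residue(m.chain_id, m.position)
    if m.to_aa.upper() == m.from_aa.upper():
        return out
    chem.graft_sidechain(res, ONE_TO_THREE[m.to_aa.upper()])
    restraints = ligand_restraints(out, k=ligand_k)
    out = sample_rotamers(out, [(m.chain_id, m.position)], cfg, lib, mc, restraints)
    if mode == "fixed":
        return out
    flexible, _ = iterate_flexible(
        out, cfg, ligand_restraints(out, k=ligand_k), site=(m.chain_id, m.position),
        seed=mc.seed,
    )
    return flexible


def read_mutation_table(path: str) -> list[MutationSpec]:
    """Read a tab-separated mutation list: label, chain, position, from, to."""
    specs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, chain, pos, faa, taa = line.split("\t")
            specs.append(MutationSpec(chain, int(pos), faa, taa, label=label))
    if not specs:
        raise ValueError(f"no mutations in {path!r}")
    return specs
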