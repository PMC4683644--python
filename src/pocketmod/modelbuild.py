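"""Template-based model construction.

The pipeline turns a template structure plus a target sequence into a
completed comparative model in the order the protocol prescribes:

1. *threading* — rename aligned residues to the target identities with
   idealized side-chain geometry, leaving the backbone untouched;
2. *ramped repacking* — rotamer sampling and minimization under a
   repulsive-weight ramp that starts nearly soft and ends at 60% of the
   standard repulsion, so large substitutions can be introduced without
   locking in clashes;
3. *deletion-gap closure* — a sacrificial overlap glycine is extended from
   the mobile flank and harmonically forced onto the stationary flank; the
   harmonic minimum over rigid motions of the mobile segment is the Kabsch
   superposition, which is applied directly, the overlap removed, and the
   chain re-bonded;
4. *insertion by fragment assembly* — target-only stretches are built from
   a library of short (3/9-residue) backbone fragments; the fragment whose
   ends satisfy both anchor junctions with the best energy (ties broken by
   RMSD to the template, then library order) is grafted in;
5. *ligand transfer* — the substrate is placed by superposing a donor
   structure's binding domain onto the model and rigidly carrying the
   ligand across;
6. *refinement* — minimization under template backbone restraints while
   the repulsive weight ramps to its full value.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import substitution_matrices as _submat

from . import chem
from .align import Alignment, global_align
from .energy import (
    EnergyModel,
    HarmonicRestraint,
    MCParams,
    RampSchedule,
    RotamerLibrary,
    ScoreConfig,
    atom_indices,
    default_rotamer_library,
    minimize,
    sample_rotamers,
)
from .geometry import backbone_rmsd, kabsch_superpose
from .structio import Atom, ONE_TO_THREE, Residue, Structure

__all__ = [
    "GapSpec",
    "InsertionSpec",
    "Fragment",
    "FragmentLibrary",
    "BuildReport",
    "BuildConfig",
    "ThreadResult",
    "ConsistencyError",
    "ClosureError",
    "InsertionError",
    "thread_sequence",
    "ramped_repack",
    "close_deletion_gap",
    "build_fragment_library",
    "insert_fragment",
    "transfer_ligand",
    "refine",
    "build_model",
    "clash_count",
]


class ConsistencyError(ValueError):
    """Alignment, sequence, and template disagree."""


class ClosureError(RuntimeError):
    def __init__(self, rmsd: float, tolerance: float):
        super().__init__(f"gap closure reached {rmsd:.3f} A (tolerance {tolerance} A)")
        self.rmsd = rmsd


class InsertionError(RuntimeError):
    def __init__(self, message: str, best_rmsd: float | None = None):
        super().__init__(message)
        self.best_rmsd = best_rmsd


@dataclass(frozen=True)
class GapSpec:
    """Flanks of a region deleted from the template.

    ``stationary`` keeps its coordinates; the segment on the ``mobile``
    side is rigidly moved during closure.  Which flank is stationary is a
    modeling judgment exposed as data, defaulting to the N-terminal side.
    """

    stationary: tuple[str, int]
    mobile: tuple[str, int]
    overlap_name: str = "GLY"


@dataclass(frozen=True)
class InsertionSpec:
    """A target-only stretch to be built between two anchor residues."""

    anchor_n: tuple[str, int]
    anchor_c: tuple[str, int]
    inserted_sequence: str

    def __post_init__(self) -> None:
        if not self.inserted_sequence:
            raise ValueError("inserted_sequence must be nonempty")


@dataclass
class Fragment:
    """Backbone geometry of a short consecutive peptide window."""

    length: int
    sequence: str
    backbone: list[dict[str, np.ndarray]]  # per residue: N/CA/C(/O) coords
    source_tag: str


@dataclass
class FragmentLibrary:
    fragments: list[Fragment]

    def of_length(self, length: int) -> list[Fragment]:
        return [f for f in self.fragments if f.length == length]

    def ranked(self, query: str) -> list[Fragment]:
        """Fragments of the query's length, by descending BLOSUM62 similarity.

        Ties keep library order.
        """
        mat = _submat.load("BLOSUM62")
        scored = []
        for idx, f in enumerate(self.of_length(len(query))):
            s = sum(mat[a, b] for a, b in zip(query.upper(), f.sequence.upper()))
            scored.append((-float(s), idx, f))
        scored.sort(key=lambda t: (t[0], t[1]))
        return [f for _, _, f in scored]


@dataclass
class BuildReport:
    backbone_rmsd_to_template: float = 0.0
    stage_energies: dict[str, float] = field(default_factory=dict)
    residual_clash_count: int = 0
    seed: int = 0
    stage_seconds: dict[str, float] = field(default_factory=dict)
    closure_rmsds: list[float] = field(default_factory=list)
    junction_rmsds: list[float] = field(default_factory=list)
    ligand_fit_rmsd: float | None = None

    def __post_init__(self) -> None:
        if self.backbone_rmsd_to_template < 0:
            raise ValueError("RMSD must be non-negative")


@dataclass
class ThreadResult:
    structure: Structure
    substituted: list[tuple[str, int]]
    gaps: list[GapSpec]
    insertions: list[InsertionSpec]


# ---------------------------------------------------------------------------
# Threading
# ---------------------------------------------------------------------------


def thread_sequence(
    template: Structure,
    aln: Alignment,
    target_seq: str,
    chain_id: str | None = None,
) -> ThreadResult:
    """Impose the target sequence on the template backbone.

    Aligned, nonidentical positions get the target identity with idealized
    side-chain geometry (backbone untouched); template-only positions are
    removed and reported as :class:`GapSpec`; target-only stretches are
    reported as :class:`InsertionSpec` for fragment assembly.
    """
    chain_id = chain_id or template.chain_ids()[0]
    chain = template.chain(chain_id)
    tmpl_seq = "".join(r.one_letter() for r in chain)
    if aln.seq_a != tmpl_seq:
        raise ConsistencyError("alignment sequence A does not match template chain")
    if aln.seq_b != target_seq.upper():
        raise ConsistencyError("alignment sequence B does not match target sequence")

    s = template.copy()
    schain = s.chain(chain_id)

    substituted: list[tuple[str, int]] = []
    to_delete: list[int] = []
    gaps: list[GapSpec] = []
    insertions: list[InsertionSpec] = []

    del_run: list[int] = []
    ins_run: list[int] = []
    last_template_idx: int | None = None

    def flush_deletion() -> None:
        nonlocal del_run
        if del_run:
            first, last = del_run[0], del_run[-1]
            if first > 0 and last < len(schain) - 1:
                gaps.append(
                    GapSpec(
                        stationary=(chain_id, schain[first - 1].number),
                        mobile=(chain_id, schain[last + 1].number),
                    )
                )
            to_delete.extend(del_run)
            del_run = []

    def flush_insertion(next_template_idx: int | None) -> None:
        nonlocal ins_run
        if ins_run:
            seq = "".join(target_seq[j] for j in ins_run)
            if last_template_idx is not None and next_template_idx is not None:
                insertions.append(
                    InsertionSpec(
                        anchor_n=(chain_id, schain[last_template_idx].number),
                        anchor_c=(chain_id, schain[next_template_idx].number),
                        inserted_sequence=seq,
                    )
                )
            ins_run = []

    for i, j in aln.pairs:
        if i is not None and j is not None:
            flush_deletion()
            flush_insertion(i)
            res = schain[i]
            if tmpl_seq[i] != target_seq[j]:
                chem.graft_sidechain(res, ONE_TO_THREE.get(target_seq[j].upper(), "GLY"))
                substituted.append((chain_id, res.number))
            last_template_idx = i
        elif i is not None:
            flush_insertion(i)
            del_run.append(i)
        else:
            flush_deletion()
            ins_run.append(j)
    flush_deletion()
    flush_insertion(None)

    doomed = {id(schain[k]) for k in to_delete}
    s.residues = [r for r in s.residues if id(r) not in doomed]
    return ThreadResult(structure=s, substituted=substituted, gaps=gaps, insertions=insertions)


# ---------------------------------------------------------------------------
# Ramped repacking
# ---------------------------------------------------------------------------


def ramped_repack(
    s: Structure,
    positions: list[tuple[str, int]],
    schedule: RampSchedule,
    cfg: ScoreConfig,
    lib: RotamerLibrary,
    mc: MCParams,
    restraints: list[HarmonicRestraint] | None = None,
) -> Structure:
    """Rotamer sampling + side-chain minimization under a repulsion ramp.

    The best of the pipeline's final state and the input, scored at the
    schedule's final weight, is returned, so repacking never worsens the
    structure under the target score.
    """
    if not positions:
        return s.copy()
    current = s.copy()
    for stage_i, (weight, cycles) in enumerate(schedule.stages):
        stage_cfg = replace(cfg, repulsive_weight=weight)
        for cyc in range(cycles):
            stage_mc = replace(mc, seed=(mc.seed + 1000 * stage_i + cyc) % (2**31))
            current = sample_rotamers(current, positions, stage_cfg, lib, stage_mc, restraints)
            residues = [current.get_residue(c, n) for c, n in positions]
            side_atoms = [
                i
                for i in atom_indices(current, residues=residues)
                if current.all_atoms()[i].name not in chem.BACKBONE_WITH_O
            ]
            if side_atoms:
                current = minimize(current, stage_cfg, restraints, movable=side_atoms, max_iter=50)
    final_cfg = replace(cfg, repulsive_weight=schedule.final_weight)
    model_in = EnergyModel(s, final_cfg, restraints)
    model_out = EnergyModel(current, final_cfg, restraints)
    if model_out.total(current.coords()) <= model_in.total(s.coords()):
        return current
    return s.copy()


# ---------------------------------------------------------------------------
# Deletion-gap closure
# ---------------------------------------------------------------------------

_EXT_PHI = -57.0
_EXT_PSI = -47.0


def _extend_nterm(res: Residue) -> dict[str, np.ndarray]:
    """Ideal backbone of a virtual residue preceding ``res``."""
    n, ca, c = (res.atom(x).coord for x in ("N", "CA", "C"))
    prev_c = chem.place_atom(c, ca, n, chem.BOND_C_N, chem.ANGLE_C_N_CA, _EXT_PHI)
    prev_ca = chem.place_atom(ca, n, prev_c, chem.BOND_CA_C, chem.ANGLE_CA_C_N, chem.OMEGA)
    prev_n = chem.place_atom(n, prev_c, prev_ca, chem.BOND_N_CA, chem.ANGLE_N_CA_C, _EXT_PSI)
    return {"N": prev_n, "CA": prev_ca, "C": prev_c}


def _extend_cterm(res: Residue) -> dict[str, np.ndarray]:
    """Ideal backbone of a virtual residue following ``res``."""
    n, ca, c = (res.atom(x).coord for x in ("N", "CA", "C"))
    nxt_n = chem.place_atom(n, ca, c, chem.BOND_C_N, chem.ANGLE_CA_C_N, _EXT_PSI)
    nxt_ca = chem.place_atom(ca, c, nxt_n, chem.BOND_N_CA, chem.ANGLE_C_N_CA, chem.OMEGA)
    nxt_c = chem.place_atom(c, nxt_n, nxt_ca, chem.BOND_CA_C, chem.ANGLE_N_CA_C, _EXT_PHI)
    return {"N": nxt_n, "CA": nxt_ca, "C": nxt_c}


def close_deletion_gap(
    s: Structure,
    gap: GapSpec,
    cfg: ScoreConfig,
    tolerance: float = 0.3,
    relief_schedule: RampSchedule | None = None,
) -> tuple[Structure, float]:
    """Close a deletion gap by superposing an overlap residue onto the
    stationary flank.

    A virtual overlap glycine is extended from the mobile flank with ideal
    peptide geometry; the rigid motion of the mobile segment that minimizes
    the harmonic tether between the overlap backbone and the stationary
    flank backbone is their Kabsch superposition, which is applied, after
    which the overlap is discarded and the chain is bonded.  Returns the
    closed structure and the closure RMSD (raises :class:`ClosureError`
    above tolerance).
    """
    out = s.copy()
    stat = out.get_residue(*gap.stationary)
    mob = out.get_residue(*gap.mobile)
    chain = out.chain(gap.stationary[0])
    i_stat = chain.index(stat)
    i_mob = chain.index(mob)
    if abs(i_stat - i_mob) == 1:
        a = stat if i_stat < i_mob else mob
        b = mob if i_stat < i_mob else stat
        if np.linalg.norm(a.atom("C").coord - b.atom("N").coord) <= chem.PEPTIDE_BOND_MAX:
            return out, 0.0  # nothing was deleted between already-bonded flanks

    if i_stat < i_mob:
        mobile_res = chain[i_mob:]
        overlap = _extend_nterm(mob)
    else:
        mobile_res = chain[: i_mob + 1]
        overlap = _extend_cterm(mob)

    names = ("N", "CA", "C")
    moving = np.array([overlap[x] for x in names])
    target = np.array([stat.atom(x).coord for x in names])
    rot, trans, rmsd = kabsch_superpose(moving, target)
    if rmsd > tolerance:
        raise ClosureError(rmsd, tolerance)
    for res in mobile_res:
        for a in res.atoms:
            a.coord = a.coord @ rot.T + trans

    if relief_schedule is not None:
        lo = max(0, min(i_stat, i_mob) - 1)
        hi = min(len(chain), max(i_stat, i_mob) + 2)
        local = chain[lo:hi]
        movable = atom_indices(out, residues=local)
        restraints = [
            HarmonicRestraint(i, out.all_atoms()[i].coord.copy(), cfg.restraint_k)
            for i in atom_indices(out, residues=local, atom_names=chem.BACKBONE_ATOMS)
        ]
        for weight, cycles in relief_schedule.stages:
            for _ in range(cycles):
                out = minimize(out, replace(cfg, repulsive_weight=weight),
                               restraints, movable=movable, max_iter=50)
    return out, rmsd


# ---------------------------------------------------------------------------
# Fragment assembly
# ---------------------------------------------------------------------------


def build_fragment_library(
    sources: list[Structure],
    lengths: tuple[int, ...] = (3, 9),
) -> FragmentLibrary:
    """Extract all consecutive backbone windows of the given lengths."""
    frags: list[Fragment] = []
    for src in sources:
        for chain_id in src.chain_ids():
            chain = src.chain(chain_id)
            # split at chain breaks
            segments: list[list[Residue]] = [[]]
            for k, res in enumerate(chain):
                if segments[-1]:
                    prev = segments[-1][-1]
                    if (
                        not prev.has_atom("C")
                        or not res.has_atom("N")
                        or np.linalg.norm(prev.atom("C").coord - res.atom("N").coord)
                        > chem.PEPTIDE_BOND_MAX
                    ):
                        segments.append([])
                segments[-1].append(res)
            for seg in segments:
                for length in lengths:
                    for start in range(0, len(seg) - length + 1):
                        window = seg[start : start + length]
                        if not all(
                            r.has_atom("N") and r.has_atom("CA") and r.has_atom("C")
                            for r in window
                        ):
                            continue
                        frags.append(
                            Fragment(
                                length=length,
                                sequence="".join(r.one_letter() for r in window),
                                backbone=[
                                    {
                                        n: r.atom(n).coord.copy()
                                        for n in chem.BACKBONE_WITH_O
                                        if r.has_atom(n)
                                    }
                                    for r in window
                                ],
                                source_tag=f"{src.title or 'src'}:{chain_id}:{window[0].number}",
                            )
                        )
    if not frags:
        raise InsertionError("no valid fragment windows in sources")
    return FragmentLibrary(frags)


def _insertion_number(anchor: Residue, k: int) -> tuple[int, str]:
    # author numbering is never disturbed: inserted residues reuse the
    # N-anchor number with insertion codes A, B, C, ...
    return anchor.number, chr(ord("A") + k)


def insert_fragment(
    s: Structure,
    ins: InsertionSpec,
    lib: FragmentLibrary,
    cfg: ScoreConfig,
    mc: MCParams,
    template: Structure | None = None,
    tolerance: float = 0.3,
) -> tuple[Structure, float]:
    """Build an inserted stretch from the best library fragment.

    Candidate fragments span the insertion plus both anchors (length
    ``len(inserted_sequence) + 2``); each is rigidly fitted on its two end
    residues onto the anchor backbones.  Candidates whose junction RMSD is
    within tolerance are scored by total energy, with ties broken by CA
    RMSD to the template over non-inserted residues, then library order.
    Returns the structure with the insertion grafted and the winning
    junction RMSD.
    """
    length = len(ins.inserted_sequence)
    candidates = lib.of_length(length + 2)
    if not candidates:
        raise InsertionError(f"library has no fragments of length {length + 2}")

    anchor_n = s.get_residue(*ins.anchor_n)
    anchor_c = s.get_residue(*ins.anchor_c)
    names = ("N", "CA", "C")
    target = np.array(
        [anchor_n.atom(x).coord for x in names] + [anchor_c.atom(x).coord for x in names]
    )

    best: tuple[float, float, int] | None = None
    best_result: tuple[Structure, float] | None = None
    best_junction = np.inf
    for idx, frag in enumerate(candidates):
        moving = np.array(
            [frag.backbone[0][x] for x in names] + [frag.backbone[-1][x] for x in names]
        )
        rot, trans, junction_rmsd = kabsch_superpose(moving, target)
        best_junction = min(best_junction, junction_rmsd)
        if junction_rmsd > tolerance:
            continue
        candidate = s.copy()
        c_anchor_n = candidate.get_residue(*ins.anchor_n)
        chain = candidate.chain(ins.anchor_n[0])
        pos_in_chain = chain.index(c_anchor_n)
        insert_at = candidate.residues.index(chain[pos_in_chain]) + 1
        new_residues = []
        for k in range(length):
            bb = frag.backbone[k + 1]
            number, icode = _insertion_number(c_anchor_n, k)
            atoms = [
                Atom(name=n, element=n[0], coord=bb[n] @ rot.T + trans)
                for n in chem.BACKBONE_WITH_O
                if n in bb
            ]
            res = Residue(
                chain_id=ins.anchor_n[0],
                number=number,
                icode=icode,
                name="GLY",
                atoms=atoms,
            )
            aa = ins.inserted_sequence[k].upper()
            if aa in ONE_TO_THREE and aa != "G":
                chem.graft_sidechain(res, ONE_TO_THREE[aa])
            new_residues.append(res)
        candidate.residues[insert_at:insert_at] = new_residues

        energy = EnergyModel(candidate, cfg).lj(candidate.coords())
        tmpl_rmsd = 0.0
        if template is not None:
            try:
                tmpl_rmsd = backbone_rmsd(candidate, template)
            except ValueError:
                tmpl_rmsd = 0.0
        key = (energy, tmpl_rmsd, idx)
        if best is None or key < best:
            best = key
            best_result = (candidate, junction_rmsd)

    if best_result is None:
        raise InsertionError(
            f"no fragment satisfies both anchors within {tolerance} A "
            f"(best junction RMSD {best_junction:.3f} A)",
            best_rmsd=float(best_junction),
        )
    return best_result


# ---------------------------------------------------------------------------
# Ligand transfer
# ---------------------------------------------------------------------------


def transfer_ligand(
    model: Structure,
    donor: Structure,
    donor_domain: list[tuple[str, int]],
    model_domain: list[tuple[str, int]],
    ligand_name: str,
) -> tuple[Structure, float]:
    """Rigidly carry a ligand from a donor structure into the model.

    The Kabsch transform fitted on the paired domain backbones (N/CA/C) is
    applied to the ligand atoms; internal ligand geometry is preserved
    exactly.  Returns the model with the ligand appended and the domain
    superposition RMSD.
    """
    if len(donor_domain) != len(model_domain) or not donor_domain:
        raise ValueError("domain selections must be nonempty and matched in length")
    lig = donor.get_ligand(ligand_name)

    names = ("N", "CA", "C")
    moving = []
    target = []
    for (dc, dn), (mc_, mn) in zip(donor_domain, model_domain):
        dres = donor.get_residue(dc, dn)
        mres = model.get_residue(mc_, mn)
        for x in names:
            moving.append(dres.atom(x).coord)
            target.append(mres.atom(x).coord)
    rot, trans, rmsd = kabsch_superpose(np.array(moving), np.array(target))

    out = model.copy()
    new_lig = Residue(
        chain_id=lig.chain_id,
        number=lig.number,
        icode=lig.icode,
        name=lig.name,
        atoms=[
            Atom(
                name=a.name,
                element=a.element,
                coord=a.coord @ rot.T + trans,
                is_ligand_atom=True,
            )
            for a in lig.atoms
        ],
    )
    existing = {r.id for r in out.residues + out.ligands}
    if new_lig.id in existing:
        new_lig.number = max(r.number for r in out.residues + out.ligands) + 1
    out.ligands.append(new_lig)
    return out, rmsd


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------


def clash_count(s: Structure, overlap_threshold: float = 0.4) -> int:
    """Nonbonded heavy-atom pairs overlapping by more than the threshold.

    Overlap is (vdW radius sum - distance); bonded, 1-3 and 1-4 pairs are
    not counted.
    """
    atoms = s.all_atoms()
    coords = s.coords()
    bonds = chem.build_bond_graph(s)
    table = chem.exclusion_table(len(atoms), bonds)
    from scipy.spatial import cKDTree

    pairs = cKDTree(coords).query_pairs(4.5, output_type="ndarray")
    count = 0
    for i, j in pairs:
        if (min(i, j), max(i, j)) in table:
            continue
        vsum = chem.vdw_radius(atoms[i].element) + chem.vdw_radius(atoms[j].element)
        if vsum - np.linalg.norm(coords[i] - coords[j]) > overlap_threshold:
            count += 1
    return count


def refine(
    s: Structure,
    template: Structure,
    cfg: ScoreConfig,
    schedule: RampSchedule | None = None,
    seed: int = 0,
) -> tuple[Structure, BuildReport]:
    """Constrained full refinement against the template.

    All residues present in the template (matched by author id) are
    harmonically restrained to the template backbone; ligand atoms are
    restrained to their current pose; minimization proceeds under the
    refinement repulsion ramp.
    """
    schedule = schedule or RampSchedule.refinement()
    out = s.copy()
    atoms = out.all_atoms()
    template_bb = {
        (r.id, a.name): a.coord
        for r in template.residues
        for a in r.atoms
        if a.name in chem.BACKBONE_WITH_O
    }
    restraints: list[HarmonicRestraint] = []
    gi = 0
    for res in out.residues + out.ligands:
        for a in res.atoms:
            if res.is_ligand:
                restraints.append(HarmonicRestraint(gi, a.coord.copy(), cfg.restraint_k))
            else:
                key = (res.id, a.name)
                if key in template_bb:
                    restraints.append(
                        HarmonicRestraint(gi, np.asarray(template_bb[key], float).copy(), cfg.restraint_k)
                    )
            gi += 1

    report = BuildReport(seed=seed)
    for weight, cycles in schedule.stages:
        stage_cfg = replace(cfg, repulsive_weight=weight)
        t0 = time.perf_counter()
        for _ in range(cycles):
            out = minimize(out, stage_cfg, restraints, movable=list(range(len(atoms))))
        model = EnergyModel(out, stage_cfg, restraints)
        report.stage_energies[f"refine_w{weight:g}"] = model.total(out.coords())
        report.stage_seconds[f"refine_w{weight:g}"] = time.perf_counter() - t0
    report.backbone_rmsd_to_template = backbone_rmsd(out, template)
    report.residual_clash_count = clash_count(out)
    return out, report


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class BuildConfig:
    """Everything the end-to-end build needs, reproducible from the seed."""

    seed: int = 0
    chain_id: str | None = None
    score: ScoreConfig = field(default_factory=ScoreConfig)
    substitution_schedule: RampSchedule = field(default_factory=RampSchedule.substitution)
    refinement_schedule: RampSchedule = field(default_factory=RampSchedule.refinement)
    closure_tolerance: float = 0.3
    junction_tolerance: float = 0.3
    fragment_lengths: tuple[int, ...] = (3, 9)
    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: str = "BLOSUM62"
    mc_steps: int = 500


def build_model(
    template: Structure,
    target_seq: str,
    config: BuildConfig,
    fragment_sources: list[Structure] | None = None,
    ligand_donor: Structure | None = None,
    donor_domain: list[tuple[str, int]] | None = None,
    model_domain: list[tuple[str, int]] | None = None,
    ligand_name: str | None = None,
) -> tuple[Structure, BuildReport]:
    """Run the full construction pipeline: thread, repack, close, insert,
    transfer, refine.  Deterministic for a fixed config and inputs."""
    lib = default_rotamer_library()
    mc = MCParams(seed=config.seed, steps=config.mc_steps)
    report = BuildReport(seed=config.seed)
    timings = report.stage_seconds

    t0 = time.perf_counter()
    aln = global_align(
        "".join(r.one_letter() for r in template.chain(config.chain_id or template.chain_ids()[0])),
        target_seq,
        matrix=config.matrix,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
    )
    threaded = thread_sequence(template, aln, target_seq, chain_id=config.chain_id)
    timings["thread"] = time.perf_counter() - t0
    current = threaded.structure

    t0 = time.perf_counter()
    current = ramped_repack(
        current, threaded.substituted, config.substitution_schedule, config.score, lib, mc
    )
    report.stage_energies["post_repack"] = EnergyModel(
        current, replace(config.score, repulsive_weight=config.substitution_schedule.final_weight)
    ).lj(current.coords())
    timings["repack"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    for gap in threaded.gaps:
        current, rmsd = close_deletion_gap(
            current, gap, config.score, tolerance=config.closure_tolerance
        )
        report.closure_rmsds.append(rmsd)
    timings["close_gaps"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if threaded.insertions:
        if fragment_sources is None:
            raise InsertionError("insertions present but no fragment sources supplied")
        frag_lib = build_fragment_library(fragment_sources, lengths=config.fragment_lengths)
        for ins in threaded.insertions:
            current, junction = insert_fragment(
                current,
                ins,
                frag_lib,
                replace(config.score, repulsive_weight=config.substitution_schedule.final_weight),
                mc,
                template=template,
                tolerance=config.junction_tolerance,
            )
            report.junction_rmsds.append(junction)
    timings["insertions"] = time.perf_counter() - t0

    if ligand_donor is not None:
        t0 = time.perf_counter()
        if not (donor_domain and model_domain and ligand_name):
            raise ValueError("ligand transfer requires domain selections and a ligand name")
        current, fit = transfer_ligand(current, ligand_donor, donor_domain, model_domain, ligand_name)
        report.ligand_fit_rmsd = fit
        timings["ligand_transfer"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    current, refine_report = refine(
        current, template, config.score, schedule=config.refinement_schedule, seed=config.seed
    )
    timings["refine"] = time.perf_counter() - t0
    report.backbone_rmsd_to_template = refine_report.backbone_rmsd_to_template
    report.residual_clash_count = refine_report.residual_clash_count
    report.stage_energies.update(refine_report.stage_energies)
    return current, report
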