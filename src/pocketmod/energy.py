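"""Simplified all-heavy-atom scoring, rotamer sampling, and minimization.

The score is a deliberately small stand-in for a full molecular-mechanics
function: a 12-6 Lennard-Jones potential split at its minimum into an
attractive and a repulsive part, with the repulsive part multiplied by a
tunable weight, plus harmonic coordinate restraints.  Scaling the repulsive
weight from near zero up to its full value is what lets the modeling
pipeline introduce drastic sequence changes softly and then anneal clashes
away — the central trick of the construction protocol.

No electrostatics, solvation, hydrogens, or torsional potentials: the
modeling conclusions this package supports rest on sterics and on harmonic
constraints, and both are captured here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix, lil_matrix
from scipy.spatial import cKDTree

from . import chem
from .structio import Residue, Structure

__all__ = [
    "ScoreConfig",
    "RampSchedule",
    "RotamerLibrary",
    "MCParams",
    "HarmonicRestraint",
    "EnergyModel",
    "lj_energy",
    "restraint_energy",
    "total_energy",
    "minimize",
    "sample_rotamers",
    "atom_indices",
    "default_rotamer_library",
]

_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


@dataclass
class ScoreConfig:
    """Parameters of the simplified energy function.

    ``lj_params`` maps element symbols to (sigma in A, epsilon in energy
    units); ``repulsive_weight`` in [0, 1] scales the repulsive branch of
    the split potential; bonded and 1-3 neighbor pairs are excluded and
    1-4 pairs damped by ``scale_14``; interactions beyond ``cutoff``
    contribute zero.
    """

    lj_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(chem.LJ_PARAMS)
    )
    repulsive_weight: float = 1.0
    cutoff: float = 10.0
    scale_14: float = 0.2
    restraint_k: float = 10.0
    exhaustive_threshold: int = 512

    def __post_init__(self) -> None:
        for elem, (sigma, eps) in self.lj_params.items():
            if sigma <= 0 or eps < 0:
                raise ValueError(f"bad LJ parameters for {elem}: {(sigma, eps)}")
        if self.repulsive_weight < 0:
            raise ValueError("repulsive_weight must be >= 0")


@dataclass
class RampSchedule:
    """Ordered (repulsive_weight, cycles) stages with non-decreasing weights."""

    stages: list[tuple[float, int]]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("schedule requires at least one stage")
        weights = [w for w, _ in self.stages]
        if any(b < a for a, b in zip(weights, weights[1:])):
            raise ValueError("repulsive weights must be non-decreasing")
        if any(c < 1 for _, c in self.stages):
            raise ValueError("cycles must be >= 1")

    @property
    def final_weight(self) -> float:
        return self.stages[-1][0]

    @classmethod
    def substitution(cls) -> "RampSchedule":
        """Soft-start ramp ending at 60% repulsion, for sequence threading."""
        return cls([(0.02, 1), (0.1, 1), (0.25, 1), (0.6, 1)])

    @classmethod
    def refinement(cls) -> "RampSchedule":
        """Continuation ramp ending at full repulsion, for final refinement."""
        return cls([(0.8, 1), (1.0, 1)])


@dataclass
class RotamerLibrary:
    """Backbone-independent side-chain rotamers: resname -> chi tuples (deg)."""

    rotamers: dict[str, list[tuple[float, ...]]]

    def for_residue(self, resname: str) -> list[tuple[float, ...]]:
        return self.rotamers.get(resname, [()])


def default_rotamer_library(chi_values: tuple[float, ...] = (-60.0, 60.0, 180.0),
                            max_rotamers: int = 27) -> RotamerLibrary:
    """Combinatorial chi library over ``chi_values``, capped per residue.

    Residues with more than three chi angles enumerate chi1-chi3 and hold
    the remainder at 180 degrees, keeping the cap deterministic.
    """
    lib: dict[str, list[tuple[float, ...]]] = {"GLY": [()], "ALA": [()], "PRO": [()]}
    for resname, chis in chem.CHI_ATOMS.items():
        n_free = min(len(chis), 3)
        combos = [
            tuple(c) + (180.0,) * (len(chis) - n_free)
            for c in itertools.product(chi_values, repeat=n_free)
        ]
        lib[resname] = combos[:max_rotamers]
    return RotamerLibrary(lib)


@dataclass
class MCParams:
    """Metropolis sampling parameters; the seed is mandatory."""

    seed: int
    steps: int = 500
    kT_schedule: list[float] = field(
        default_factory=lambda: list(np.geomspace(3.0, 0.3, 8))
    )

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if any(t <= 0 for t in self.kT_schedule):
            raise ValueError("temperatures must be > 0")


@dataclass
class HarmonicRestraint:
    """Harmonic tether of one atom (global index) to a target coordinate."""

    atom_index: int
    target: np.ndarray
    k: float

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)


def atom_indices(
    s: Structure,
    residues: list[Residue] | None = None,
    atom_names: tuple[str, ...] | None = None,
    include_ligands: bool = False,
) -> list[int]:
    """Global indices (``s.all_atoms()`` order) for a residue/atom selection."""
    wanted = None if residues is None else {id(r) for r in residues}
    out: list[int] = []
    i = 0
    for res in s.residues + s.ligands:
        for a in res.atoms:
            ok = wanted is None or id(res) in wanted
            if res.is_ligand and not include_ligands and wanted is None:
                ok = False
            if ok and (atom_names is None or a.name in atom_names):
                out.append(i)
            i += 1
    return out


class EnergyModel:
    """Evaluates the split-LJ + restraint energy and its gradient.

    Topology (elements, bonds, exclusions) is fixed at construction; only
    coordinates vary between evaluations.
    """

    def __init__(self, s: Structure, cfg: ScoreConfig,
                 restraints: list[HarmonicRestraint] | None = None) -> None:
        self.cfg = cfg
        self.restraints = list(restraints or [])
        atoms = s.all_atoms()
        self.n = len(atoms)
        sigma = np.empty(self.n)
        eps = np.empty(self.n)
        for i, a in enumerate(atoms):
            try:
                sigma[i], eps[i] = cfg.lj_params[a.element.upper()]
            except KeyError:
                raise chem.ParameterizationError(
                    f"no LJ parameters for element {a.element!r} (atom {a.name})"
                )
        self.sigma = sigma
        self.eps = eps
        bonds = chem.build_bond_graph(s)
        table = chem.exclusion_table(self.n, bonds)
        sp = lil_matrix((self.n, self.n))
        for (i, j), scale in table.items():
            penalty = 1.0 - (scale if scale > 0 else 0.0)
            if scale == 0.0:
                penalty = 1.0
            elif scale == 0.2:
                penalty = 1.0 - cfg.scale_14
            sp[i, j] = penalty
        self._scale_deficit: csr_matrix = sp.tocsr()

    # -- pair terms ------------------------------------------------------

    def _pairs(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(self.cfg.cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return np.empty((0,), int), np.empty((0,), int)
        return pairs[:, 0], pairs[:, 1]

    def _pair_params(self, ii: np.ndarray, jj: np.ndarray):
        sig = 0.5 * (self.sigma[ii] + self.sigma[jj])
        e = np.sqrt(self.eps[ii] * self.eps[jj])
        scale = 1.0 - np.asarray(self._scale_deficit[ii, jj]).ravel()
        return sig, e, scale

    def lj(self, coords: np.ndarray, repulsive_weight: float | None = None) -> float:
        w = self.cfg.repulsive_weight if repulsive_weight is None else repulsive_weight
        ii, jj = self._pairs(coords)
        if len(ii) == 0:
            return 0.0
        sig, e, scale = self._pair_params(ii, jj)
        r = np.maximum(np.linalg.norm(coords[ii] - coords[jj], axis=1), 0.1)
        rm = _SIXTH_ROOT_2 * sig
        sr6 = (sig / r) ** 6
        ljv = 4.0 * e * (sr6 * sr6 - sr6)
        inside = r < rm
        attr = np.where(inside, -e, ljv)
        rep = np.where(inside, ljv + e, 0.0)
        return float(np.sum(scale * (attr + w * rep)))

    def restraint(self, coords: np.ndarray) -> float:
        total = 0.0
        for rst in self.restraints:
            d = coords[rst.atom_index] - rst.target
            total += rst.k * float(d @ d)
        return total

    def total(self, coords: np.ndarray, repulsive_weight: float | None = None) -> float:
        return self.lj(coords, repulsive_weight) + self.restraint(coords)

    def gradient(self, coords: np.ndarray, repulsive_weight: float | None = None) -> np.ndarray:
        w = self.cfg.repulsive_weight if repulsive_weight is None else repulsive_weight
        grad = np.zeros_like(coords)
        ii, jj = self._pairs(coords)
        if len(ii):
            sig, e, scale = self._pair_params(ii, jj)
            diff = coords[ii] - coords[jj]
            r = np.maximum(np.linalg.norm(diff, axis=1), 0.1)
            rm = _SIXTH_ROOT_2 * sig
            sr6 = (sig / r) ** 6
            dlj = 4.0 * e * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            dEdr = scale * np.where(r < rm, w * dlj, dlj)
            unit = diff / r[:, None]
            contrib = dEdr[:, None] * unit
            np.add.at(grad, ii, contrib)
            np.add.at(grad, jj, -contrib)
        for rst in self.restraints:
            grad[rst.atom_index] += 2.0 * rst.k * (coords[rst.atom_index] - rst.target)
        return grad


# ---------------------------------------------------------------------------
# Public scoring entry points
# ---------------------------------------------------------------------------


def lj_energy(s: Structure, cfg: ScoreConfig) -> float:
    """Split Lennard-Jones energy of a structure under ``cfg``."""
    return EnergyModel(s, cfg).lj(s.coords())


def restraint_energy(coords: np.ndarray, targets: np.ndarray, k: float) -> float:
    """Sum of ``k * d^2`` displacements between paired coordinate sets."""
    coords = np.asarray(coords, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if coords.shape != targets.shape:
        raise ValueError("coords and targets must have the same shape")
    d = coords - targets
    return float(k * np.sum(d * d))


def total_energy(s: Structure, cfg: ScoreConfig,
                 restraints: list[HarmonicRestraint] | None = None,
                 repulsive_weight: float | None = None) -> float:
    model = EnergyModel(s, cfg, restraints)
    return model.total(s.coords(), repulsive_weight)


# ---------------------------------------------------------------------------
# Gradient minimization (steepest descent with backtracking)
# ---------------------------------------------------------------------------


def minimize(
    s: Structure,
    cfg: ScoreConfig,
    restraints: list[HarmonicRestraint] | None = None,
    movable: list[int] | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    max_step: float = 0.5,
) -> Structure:
    """Locally minimize the total energy over a movable atom selection.

    Only atoms in ``movable`` (global indices; default all) are displaced;
    fixed atoms are bit-identical on output.  The best iterate is returned,
    so the result's energy never exceeds the input's.
    """
    model = EnergyModel(s, cfg, restraints)
    x = s.coords()
    mask = np.zeros(len(x), dtype=bool)
    if movable is None:
        mask[:] = True
    else:
        if len(movable) == 0:
            raise ValueError("movable selection is empty")
        mask[np.asarray(movable, dtype=int)] = True

    energy = model.total(x)
    if not np.isfinite(energy):
        raise FloatingPointError("non-finite energy at start of minimization")
    best_x, best_e = x.copy(), energy
    for _ in range(max_iter):
        g = model.gradient(x)
        g[~mask] = 0.0
        gmax = float(np.abs(g).max())
        if gmax < 1e-12:
            break
        g2 = float(np.sum(g * g))
        alpha = min(1.0, max_step / gmax)
        improved = False
        while alpha > 1e-12:
            x_trial = x - alpha * g
            e_trial = model.total(x_trial)
            if e_trial <= energy - 1e-4 * alpha * g2:
                x, energy = x_trial, e_trial
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
        improvement = best_e - energy
        if energy < best_e:
            best_x, best_e = x.copy(), energy
        if improvement < tol:
            break

    out = s.copy()
    coords = out.coords()
    coords[mask] = best_x[mask]
    out.set_coords(coords)
    return out


# ---------------------------------------------------------------------------
# Rotamer sampling
# ---------------------------------------------------------------------------


def _apply_rotamer(res: Residue, chis: tuple[float, ...]) -> None:
    if chis:
        chem.set_chi_angles(res, chis)


def sample_rotamers(
    s: Structure,
    positions: list[tuple[str, int]],
    cfg: ScoreConfig,
    lib: RotamerLibrary,
    mc: MCParams,
    restraints: list[HarmonicRestraint] | None = None,
) -> Structure:
    """Optimize side-chain rotamers at ``positions`` (chain, resnum) pairs.

    Small combinatorial spaces (up to ``cfg.exhaustive_threshold`` states)
    are enumerated exhaustively, guaranteeing the global library optimum;
    larger spaces use Metropolis sampling with the ``mc`` temperature
    schedule.  The best-energy configuration visited is returned.
    Positions without side-chain torsions are silent no-ops.
    """
    out = s.copy()
    residues = [out.get_residue(c, n) for c, n in positions]
    options = [lib.for_residue(r.name) for r in residues]
    active = [(r, opts) for r, opts in zip(residues, options) if opts and opts != [()]]
    if not active:
        return out

    model = EnergyModel(out, cfg, restraints)

    def score() -> float:
        return model.total(out.coords())

    n_states = 1
    for _, opts in active:
        n_states *= len(opts)
        if n_states > cfg.exhaustive_threshold:
            break

    if n_states <= cfg.exhaustive_threshold:
        best_e = np.inf
        best_combo = None
        for combo in itertools.product(*(range(len(o)) for _, o in active)):
            for (r, opts), ci in zip(active, combo):
                _apply_rotamer(r, opts[ci])
            e = score()
            if e < best_e - 1e-12:
                best_e, best_combo = e, combo
        for (r, opts), ci in zip(active, best_combo):
            _apply_rotamer(r, opts[ci])
        return out

    rng = np.random.default_rng(mc.seed)
    state = [0] * len(active)
    for (r, opts), ci in zip(active, state):
        _apply_rotamer(r, opts[ci])
    energy = score()
    best_e, best_state = energy, list(state)
    per_stage = max(1, mc.steps // len(mc.kT_schedule))
    step = 0
    for kT in mc.kT_schedule:
        for _ in range(per_stage):
            step += 1
            pi = int(rng.integers(len(active)))
            r, opts = active[pi]
            ri = int(rng.integers(len(opts)))
            if ri == state[pi]:
                continue
            old = state[pi]
            _apply_rotamer(r, opts[ri])
            e_new = score()
            if e_new <= energy or rng.random() < np.exp(-(e_new - energy) / kT):
                state[pi] = ri
                energy = e_new
                if energy < best_e:
                    best_e, best_state = energy, list(state)
            else:
                _apply_rotamer(r, opts[old])
    for (r, opts), ci in zip(active, best_state):
        _apply_rotamer(r, opts[ci])
    return out
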