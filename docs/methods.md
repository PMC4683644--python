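# Methods

This note documents the models, numerical choices, and limitations behind
`pocketmod`. It covers what the code computes and why the defaults are what
they are; every empirical statement here is something the test suite or
`scripts/acceptance.py` computes at run time.

## The energy model

The score is intentionally minimal: conclusions the pipeline supports rest
on sterics and on harmonic constraints, so those are the only physics
included.

For a heavy-atom pair *(i, j)* at distance *r*, with Lorentz–Berthelot
combination σ = (σᵢ+σⱼ)/2 and ε = √(εᵢεⱼ), the 12-6 potential
V(r) = 4ε[(σ/r)¹² − (σ/r)⁶] is split at its minimum r\_m = 2^{1/6}σ:

- attractive branch: −ε for r < r\_m, V(r) otherwise;
- repulsive branch: V(r) + ε for r < r\_m, 0 otherwise.

The pair energy is `attractive + w · repulsive`, where the repulsive weight
*w* ∈ [0, 1] is the pipeline's central dial: introducing drastic sequence
changes at *w* ≈ 0 and ramping upward anneals clashes instead of locking
them in. Per-element parameters (σ in Å, ε in arbitrary energy units):
C (3.03, 0.10), N (2.76, 0.10), O (2.71, 0.10), S/P (3.21, 0.20),
H (2.00, 0.01) — σ chosen so that r\_m equals the sum of van der Waals
radii. Interactions beyond a 10 Å cutoff are zero. Bonded and 1-3 pairs
are excluded; 1-4 pairs are damped to 20% because ideal backbone geometry
places 1-4 heavy atoms inside r\_m, and without damping even an ideal
template would be self-repulsive. No electrostatics, solvation, hydrogens,
or torsional terms; energies are not comparable to any production force
field, only to each other.

Harmonic restraints contribute k·d² per tethered atom (k in energy/Å²).
Defaults: k = 10 for template/backbone restraints during refinement and
closure, k = 50 for ligand/tRNA tethers during mutation modeling ("can
move, but heavily penalized"), k = 1 for the weak Cα tethers that
accompany flexible-backbone optimization (below).

## Minimization and sampling

Gradient minimization is steepest descent with a backtracking line search
(Armijo factor 1e-4, initial step capped at 0.5 Å displacement), analytic
gradients, convergence when an iteration improves the energy by < 1e-4,
at most 200 iterations. The best iterate is returned, so minimization
never raises the energy, and atoms outside the movable selection are
bit-identical on output.

Rotamers are backbone-independent χ-angle combinations over {−60°, 60°,
180°}, capped at 27 per residue type; residues with four χ angles
enumerate χ1–χ3 and hold χ4 at 180°. Side-chain geometry comes from the
chemical component dictionary bundled with biotite, grafted onto the
existing backbone by superposing ideal N/CA/C. When the combinatorial
space of a packing problem has ≤ 512 states it is enumerated exhaustively
(ties broken by enumeration order), which makes the small problems the
pipeline actually faces provably optimal within the library; larger
spaces fall back to Metropolis sampling with a geometric kT schedule
(3.0 → 0.3, 8 stages, 500 steps by default, seed mandatory), returning
the best state visited.

## Construction pipeline choices

**Repulsion ramps.** Substitution stage: w = 0.02, 0.1, 0.25, 0.6
("drastically reduced", then raised to ~60% of standard). Refinement
stage: w = 0.8, 1.0. Repacking compares its result against its input at
the final stage weight and keeps the better one, so the ramp can only
help.

**Gap closure.** One flank of a deletion is stationary, the other mobile
(configurable; default stationary = N-terminal side). A virtual overlap
glycine is extended from the mobile flank with ideal peptide internal
coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; extension torsions
−57°/−47°). Because the harmonic energy between the overlap backbone and
the stationary flank backbone is, over rigid motions of the mobile
segment, minimized exactly by their Kabsch superposition, closure applies
that superposition in closed form rather than iterating; an optional
clash-relief minimization under a repulsion ramp follows. Glycine is used
as the overlap residue because it is maximally permissive. Closure
tolerance: 0.3 Å backbone RMSD (sub-bond-length accuracy); exceeding it
raises an error carrying the achieved RMSD.

**Insertions.** Candidate fragments span the inserted stretch plus both
anchors; each is rigidly fitted on its two end residues onto the anchor
backbones (junction tolerance 0.3 Å). Selection is an exhaustive scan of
the library — at the library sizes this pipeline uses, enumeration is
cheaper and strictly stronger than stochastic search — ranked by total
energy, then CA RMSD to the template, then library order. Ranking of
fragments by sequence similarity uses BLOSUM62 sums.

**Ligand transfer** is rigid by construction: the Kabsch transform fitted
on paired domain backbones is applied to the ligand atoms, so intra-ligand
distances are preserved to numerical precision.

**Refinement** restrains all template-matched backbone atoms (N/CA/C/O,
matched by author chain/number/insertion code) to the template and ligand
atoms to their pose, then minimizes everything under the refinement ramp.
Backbone RMSD to template is CA-only after one round of Kabsch
superposition, no outlier rejection.

**Residue numbering** is author numbering throughout — sites are cited by
deposited numbers — and inserted residues take the N-anchor's number with
insertion codes A, B, C so no existing residue is ever renumbered.

## Mutation modeling

Fixed-backbone design grafts the new side chain and picks the best
rotamer at full repulsion; no backbone coordinate changes (the tests
assert exact equality). Flexible-backbone optimization then iterates:
jitter φ/ψ by uniform ±3° on residues whose Cα lies within 8 Å of the
site, minimize everything, accept on improvement, stop when an iteration
improves by < 1e-3 (max 50 iterations). A φ/ψ rotation moves the entire
downstream chain, so minimization includes weak (k = 1) Cα tethers to the
pre-mutation model — the local-response control that a full refinement
protocol provides implicitly — alongside the strong (k = 50) ligand
tethers. Because iteration starts from the fixed-backbone result and only
accepts improvements, the flexible result's energy never exceeds the
fixed result's under the same objective. Double mutants are built
sequentially: the pocket substitution first, then the suppressor, each on
the previous model.

## Geometry analyses

The scissile-bond reference point is the midpoint of the bond between the
two configured ligand atoms (for a valyl-adenylate: the valine carbonyl
carbon and the bridging oxygen); ligand dictionaries differ in atom
naming, so the pair is configuration. The "carboxyl" probe is the
carboxyl(ate) carbon (CG for Asp, CD for Glu), with a `carboxyl_min` mode
that takes the minimum over the carboxyl group's heavy atoms — reported
alongside where the choice matters. Site-to-site distances default to
Cα–Cα. Pocket sterics report every pocket/probe atom pair whose distance
is below the van der Waals radius sum (overlap = sum − distance) and a
volume proxy counted on a 0.5 Å grid over the padded pocket bounding box;
a `radius_scale` knob inflates probe radii for sensitivity scans.
Genomic intervals are 1-based inclusive (length = end − start + 1),
matching printed lesion spans; BED-style output would convert to 0-based
half-open on write.

## Synthetic fixtures and what they show

The generator emits ideal-geometry helices/strands (canonical bond
lengths and angles, Cα–Cα ≈ 3.8 Å) with grafted idealized side chains,
plus one scenario family per pipeline stage: substitutions, a 3-residue
deletion, a 1-residue insertion whose exact geometry exists in the
fragment source, a ligand planted under a known rigid transform, a planted
2 Å ligand shift with directly computed probe distances, and small/bulky
pocket variants with pair-counted clash numbers. Every ground-truth value
is computed by direct formula from the generated coordinates at generation
time, never by the pipeline being tested. Default problem sizes (8–17
residues) are the package's chosen desk scale: large enough that packing,
closure, and insertion are nondegenerate, small enough that exhaustive
oracles are exact.

What passing these fixtures does *not* show: anything about real
conformational preferences. The fixtures have ideal geometry, a single
chain, no solvent, and a toy ligand; agreement there validates the
mechanics (superposition, closure algebra, combinatorial optimality,
rigidity, determinism), not the energy function's realism. Reproduction
of published pocket distances requires the real template, donor, and
target sequence, and carries the tolerance one expects of a simplified
steric score.

## Known limitations

- The score has no electrostatics or solvation; polar-specific effects
  (e.g. suppression mechanisms that act through solvent exposure rather
  than sterics) are invisible to it.
- Proline's ring is not closed after grafting and its φ is jittered like
  any other residue's.
- Fragment insertion requires spatially separated anchors; it cannot open
  a geometrically closed site to make room (no loop remodeling beyond the
  fragment protocol).
- First model only for multi-model files; no symmetry expansion; no
  automated template search.
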