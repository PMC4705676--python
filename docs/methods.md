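# Methods

## Model

A structure is a hierarchy of chains, residues and atoms with coordinates
in Å.  The user's mobility declaration partitions all atoms into rigid
bodies connected by torsion joints:

* Every residue not named in a flexible selection is rigid.  Contiguous
  rigid stretches (including side chains of flexible residues) collapse
  into single bodies.
* A flexible protein residue contributes φ (N–Cα) and ψ (Cα–C) as free
  torsions; ω is kept planar.  A flexible nucleotide contributes the
  backbone torsions α (P–O5′), β (O5′–C5′), γ (C5′–C4′), ε (C3′–O3′),
  ζ (O3′–P of the next residue) and the glycosidic χ (C1′–N9/N1); the
  sugar pucker is fixed.  This torsion set is this package's own choice
  of what "residue-level flexibility" means; a `single-bond` selection
  level can free any named bond (e.g. a side-chain bond) instead.
* Welds merge two segments' bodies into one (used, e.g., to keep
  ribosomal proteins attached to their subunit's rRNA).  A weld that
  would close a kinematic loop is an error.
* The covalent bond graph is inferred from interatomic distances
  (covalent-radius sums × 1.25).  A nominally rotatable bond that lies in
  a ring (e.g. proline φ) is dropped with a warning, since cutting it
  would not detach anything.  Chain breaks split the tree into separate
  components, each with its own free 6-DOF root body.

The state vector ("generalized coordinates") is one translation +
quaternion per component plus one angle per joint.  Forward kinematics
applies joint rotations root-outward about the current bond axes, then
the free poses; a state equal to the reference reproduces the reference
coordinates bit-for-bit.  Because all motion is rigid-plus-torsional,
bond lengths, bond angles and intra-body distances are conserved exactly
(the test suite checks < 1e-6 Å drift across whole trajectories).

## Potential

All terms are in kJ/mol, coordinates in Å; every term is non-negative and
zero when satisfied.

| term | form | defaults |
|---|---|---|
| threading springs | ½ F w |x − t|² per matched atom | F = 30 kJ mol⁻¹ Å⁻², w = 1 |
| collision spheres | ½ k (R − r)² for r < R, foreign-body atoms only | k = 100 kJ mol⁻¹ Å⁻² |
| physics-zone repulsion | ε (1 − r/σᵢⱼ)² for r < σᵢⱼ | ε = 10 kJ/mol, σ from per-element contact radii sums |
| distance restraints | ½ k (r − d₀)² | Watson–Crick pairs: 2–3 restraints at 2.8–3.0 Å, k = F |

The nonbonded repulsion is evaluated only among atoms of the *physics
zone* — every atom within a radius (default 10 Å) of any flexible-residue
atom — and skips pairs in the same rigid body (their distance can never
change) and pairs three or fewer covalent bonds apart.  Pair search uses
a KD-tree rebuilt at each evaluation; a brute-force double loop is the
test oracle.  The repulsive soft-sphere form is a deliberate
simplification of a full MD force field: in this engine the physics zone
exists to prevent clashes, while covalent geometry is already guaranteed
by the kinematics.  This is the package's largest physical
simplification and the main reason no thermodynamic interpretation of
the trajectories is offered.

Gradients of every term are analytic and exact; finite-difference checks
(step 1e-5 Å Cartesian, 1e-6 rad generalized) are part of the test suite
at relative tolerances 1e-5 and 1e-4.

## Correspondence

Chains are matched by a global affine-gap alignment (Gotoh's algorithm)
with BLOSUM62 for protein and +2/−1 for nucleic acids, gap open −10 and
gap extend −1 (a gap of length L costs open + L·extend).  These scoring
defaults are documented choices, overridable per run.  Ties are broken
deterministically in the traceback: aligned pair, then gap in the second
sequence, then gap in the first, resolved from the right end.  The
dynamic program is verified against exhaustive enumeration of all global
alignments for sequence lengths ≤ 6.  A manual residue map (two-column
text format) replaces the alignment where the user needs full control,
e.g. to force correct register of an mRNA.

Springs attach per matched residue under one of two atom policies:
`representative` (Cα for protein; P, or C1′ at the 5′ end, for nucleic
acids — the default, smooth and cheap for domain-scale morphs) or
`all-shared-atoms` (every atom name present in both residues — stiffer
register control).  Target points are the partner atoms' coordinates in
the final structure after rigid pre-alignment and stay fixed during a
stage.

## Optimization and convergence

The final structure is first superposed onto the initial frame of
reference (weighted Kabsch over the representative atoms of the
designated alignment chains), so all emitted frames live in the initial
structure's coordinate frame; frame 0 is the untouched initial
structure.

Descent is preconditioned nonlinear conjugate gradient: the gradient is
scaled by the diagonal Gauss–Newton curvature of the spring term (which
equalizes the very different natural scales of translations and
torsions), combined with a Polak–Ribière conjugate term restricted to
descent directions, and accepted through an Armijo backtracking line
search, so the total energy is non-increasing at every accepted step.
Plain steepest descent was evaluated first and crawled through the
strongly coupled subspace spanned by near-parallel hinge torsion axes,
plateauing far from the minimum; the conjugate term resolves exactly
that coupling while keeping the monotone, deterministic behavior that
the stop rule needs.  A trust cap limits the largest per-step atomic
displacement (default 0.5 Å) so the trajectory is a smooth quasi-static
path rather than a jump to the target; a frame is emitted every 5
accepted steps (≤ 2.5 Å atomic motion between frames).

The run stops at the first frame ending a window (default 5 frames) of
consecutive frame-to-frame total-energy differences below a threshold
(default 50 kJ/mol), or at `max_steps`/`max_wall_time`.  The threshold is
user-set because its natural scale grows with system size.  If the line
search stalls at machine precision the engine keeps emitting (flat)
frames, so the plateau rule still fires and the result carries a
`stalled` diagnostic — this is the behavior wanted for deliberately
under-flexibilized runs, where the morph should stop gracefully at its
best reachable state.  An optional seeded overdamped-noise mode exists
for exploration and is off by default; with it enabled, monotonicity is
no longer guaranteed.

Multi-state transitions chain stages: each stage morphs the previous
result onto the next state, and per-stage specs may drop chains, rigidly
translate a chain (to mimic factor binding or release), change welds or
add restraints.  A stage failure aborts the chain and returns partial
results.

## Scoring

`score_trajectory` establishes one common residue set by gapped
alignment of the intermediate and final structures to the initial
structure, computes per-frame representative-atom RMSD profiles against
both references (superposing each frame), and reports the improvement
percentage (rounded to integer percent for presentation).  No iterative
pruning of badly fitting atom pairs is applied — all matched
representative atoms enter every RMSD — because pruning makes values
hard to reproduce; sRMSD is available where interdomain motion should be
emphasized.

## Synthetic toys

`make_two_domain_case` builds an idealized extended polypeptide
(ideal bond lengths/angles, Cα–Cα 3.8 Å) of two 8-residue domains joined
by a 2-residue hinge, rotates the distal domain about the hinge φ bond
by θ via the package's own forward kinematics (so the final structure is
exactly reachable in the declared torsion subspace), and constructs the
held-out intermediate at θ/2 (optionally with seeded 0.05 Å jitter).  An
off-path variant tilts the intermediate about a perpendicular axis to
emulate intermediates that deviate from the direct interpolation
pathway; there the expected outcome is "closer than either endpoint",
not exact recovery.  The interface collision sphere is constructed
geometrically — centered on the chord midpoint of the most distal Cα and
sized to half that point's clearance from the true rotational sweep — so
by construction the straight-line interpolation penetrates it while the
hinge path never enters it.

What the toys do not emulate: real side chains, sequence diversity
(poly-Ala makes gap placement in self-alignments degenerate),
crystallographic noise, multi-chain interfaces, or intermediates with
intradomain rearrangement.  Passing the toy benchmarks therefore
demonstrates the correctness of the kinematics, energetics, optimizer
and scoring machinery — not force-field accuracy on real proteins.

Test and acceptance problem sizes are deliberately small (18-residue,
90-atom toys; 5-point clouds; sequences ≤ 6 for exhaustive oracles), the
scale at which exact independent oracles (brute-force enumeration,
finite differences, multi-start rotation search, all-pairs scans) are
feasible.

## Numerical choices

* Altloc resolution keeps the highest-occupancy conformer (ties: first
  altloc letter); hydrogens stripped and waters dropped by default; ions
  and ligands kept rigid.
* Angles wrapped to (−π, π]; root orientation updates via quaternion
  exponential map.
* Kabsch superposition rejects degenerate (collinear) point sets, where
  the optimal rotation is not unique.
* Energies reported per frame as a term-wise table; trajectories are
  multi-model PDB (MODEL blocks numbered from 1, coordinates to 0.001 Å).
* Identical inputs and seed give bit-identical trajectories.
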