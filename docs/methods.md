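# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Coordinate model and I/O

Structures are ordered atom lists (serial, atom name, residue name, chain,
residue number, position in Å); trajectories are frame stacks over one
topology with strictly increasing times in ns. The one mandatory format is
the fixed-width PDB dialect with `MODEL`/`ENDMDL` framing — small, diffable
and exactly reproducible at the format's 0.001 Å precision. The reader is
strict by design: malformed numeric fields raise an error naming the line,
a model whose atom count disagrees with the topology raises an error naming
the model, insertion codes are rejected (absent from the systems this was
built for), and only the first alternate location of an atom is kept.
Residue numbers are taken verbatim from the file; author numbering such as
P81 or P618 is never rewritten.

Selections use a small total grammar (`resid a-b`, `resname`, `name`,
`chain`, `heavy`, `ca`, `solvent`, `all`, with `and`/`or`/`not` and
parentheses). Resolution against a structure is deterministic, ordered by
file order, and an empty match is an error — every selection the analyses
need is non-empty by construction. Protein selections can exclude water
and counter-ions via `... and not solvent`; nothing is excluded silently.

## Geometry kernels

Superposition is the Kabsch least-squares fit via SVD with an explicit
reflection guard (the determinant-corrected branch), returning a proper
rotation and the minimized RMSD. Degenerate point sets — fewer than three
points, collinear or coincident — are errors rather than silent answers,
because the rotation is not unique there. "Geometric center" is always the
unweighted mean of coordinates, never mass-weighted.

Vector angles are computed as `atan2(‖u×v‖, u·v)`, which is mathematically
identical to the arccos of the clamped normalized dot product but
numerically stable at 0° and 180°; with arccos alone, double-precision
rounding already costs ~1e-6 degrees at θ = 0, which would dominate the
noise-free recovery error. Angles are reported in degrees.

Loop RMSD against a reference fits the transform on an alignment selection
(by default the Cα atoms of the Lec rigid parts, excluding the mobile loop)
and measures RMSD over the loop selection only. Which atom class the loop
RMSD uses (Cα default) and what counts as "rigid parts" are configuration
keys, not constants.

## Orientation angles

Both compared vectors emanate from the *reference* hinge center: the
reference vector runs from the hinge's heavy-atom center to the domain-body
center in the reference structure; the frame vector runs from that same
reference hinge center to the body center of the frame after superposition
on the alignment selection. Using the frame's own hinge center instead is
available as an option (`frame_hinge_origin`), but the shared-origin form
is the default because the construction that defines the angle draws both
vectors from the reference hinge. The same alignment selection is used for
whichever reference the series is computed against.

## State classification

A frame qualifies for a state when its loop RMSD is **≤ 4.0 Å** (boundary
inclusive). Exactly one qualifier → that state. A frame qualifying for
both S1 and S1′ is called S1′ — the intermediate absorbs its overlap with
the starting state. Multi-qualifier combinations beyond that pair are not
governed by any stated rule, so the package resolves them by smallest RMSD
after applying the S1/S1′ absorption; this keeps classification total,
deterministic, and threshold-monotone (raising the threshold can never
unassign a frame). Per-state statistics use the sample SD (n−1) and report
absent values (NaN) rather than zeros for empty or single-frame states;
unassigned frames are excluded from weighted statistics but counted in the
denominators of fractions.

Transitions are read off the call sequence with a dwell filter: a change of
call counts only when the new state persists for at least `min_dwell`
assigned frames (default 5), and unassigned frames neither start nor break
a dwell. The dwell filter is the reproducible analogue of reading
transitions off smoothed time series.

## Energetics

Group–group interaction energy is the sum over inter-group atom pairs of a
switched 12-6 Lennard-Jones term (`ε_ij = √(ε_i ε_j)`,
`Rmin_ij = Rmin_i/2 + Rmin_j/2`) and a switched Coulomb term with
`C = 332.0636 kcal·Å/(mol·e²)` and unit dielectric. The switching function
is the standard C¹ polynomial, 1 at or below `r_on = 10 Å` and 0 at or
beyond `r_off = 12 Å`. The same switch is applied to both terms by default
(`switch_elec=False` gives plain truncation at `r_off` instead).
Electrostatics are deliberately pairwise-and-switched rather than Ewald:
a lattice sum is a property of a periodic simulation box, while a
*group* interaction energy in post-analysis needs a finite-range pairwise
definition — the dissociation criterion ("interaction reaching zero") is
only meaningful that way. Intra-group terms and bonded exclusions never
arise because groups are required to be disjoint. Summation order is
canonicalized by the groups' first atom indices, so E(A,B) and E(B,A) are
bitwise identical.

Hinge energy tables average in two stages: the time average within each
trajectory first, then mean ± SD across trajectories; with a single
trajectory the SD is reported as absent, never zero.

## Forced unbinding

The force axis is the unit vector from the fixed atom to the pulled atom in
frame 0 and is held constant — pulling happens along a single lab-frame
vector. Molecular extension is the pulled atom's displacement along that
axis (zero at frame 0 by construction); complex separation is the
ligand-center minus binding-domain-center difference projected on the axis
(the binding domain, not the whole receptor — the measure should not move
when distal domains stretch); the marker-pair alternative (e.g. fucose to
calcium) is a plain Euclidean center distance.

Dissociation time is the first frame where |total interaction energy| ≤
`zero_tol` and stays there for `persistence` consecutive frames (defaults
0.5 kcal/mol and 5 frames; a run truncated by the end of the trace counts
if all its frames qualify). Both knobs are configuration keys; the event is
monotone in `zero_tol` by construction. The run summary also reports
per-component (vdW-only, electrostatic-only) event frames alongside the
total-energy event, but the criterion proper is the total —
the two components reach zero together once every pair is past the cutoff.
Force profiles are analysis inputs (an SMD log), not recomputed from
coordinates; the peak feature takes the global maximum with ties going to
the earliest frame.

## Synthetic generator

The generator emulates the analysis-relevant phenomenology of a
four-module receptor + ligand system with one Cα pseudo-atom per residue
and the real system's residue numbering (loop 81–89, hinges 120/121 and
159/160, EGF 122–141, ligand ending at 618), so published selection
strings read identically on toy and real systems. Defaults: 30-atom Lec
rigid core (a helix, so alignment is well-conditioned), 9-atom loop,
20-atom EGF body (122–141), 30-atom CR1 and CR2, two-atom hinges, 10-atom
ligand, 200 frames at 0.05 ns — large enough to exercise every selection,
small enough for sub-second tests.

The three loop reference conformations are uniform translations of the
base loop, pairwise 14, 14 and ≈ 19.8 Å RMSD apart — comfortably beyond
twice the 4.0 Å threshold, so programmed state sequences are recoverable
frame-exactly, and linear blends give exactly linear RMSD ramps.

Equilibration frames compose rotations distal-first: CR1 (and everything
beyond) rotates about the EGF-CR1 hinge center, then everything distal to
the Lec-EGF hinge — including the already-rotated CR1 — rotates about the
Lec-EGF hinge. Each rotation axis is chosen perpendicular to its reference
orientation vector, so the recovered angle equals the programmed angle
exactly for θ in [0°, 180°]. Isotropic Gaussian coordinate noise (default
σ = 0, set explicitly per experiment) and a per-frame random global rigid
motion (default on, so alignment is genuinely exercised) are applied last.

Dissociation runs have two phases. First, intramolecular extension: the
lectin block and the bound ligand translate together along the force axis
(hinge opening), so extension grows while separation and contact energy
stay put. Then separation: the ligand alone creeps away by a few Å and, in
the step into the programmed event frame, jumps past the 12 Å cutoff
clearance and keeps receding. The jump is deliberate: a smooth geometric
decay would place the detector's first-crossing frame at the mercy of
`zero_tol`, whereas the controlled break makes the energy exactly zero from
the event frame on and leaves it tens of kcal/mol away from zero before it,
so the programmed frame is recovered for any sane tolerance. Constant-force
runs log their constant force; constant-velocity runs log
`spring × (cantilever lag)` with a piecewise-linear lag profile peaking at
the programmed force peak. No per-frame global rigid motion is applied in
dissociation mode — extension and separation are lab-frame quantities whose
stated invariance is only under translations perpendicular to the axis.

Every run emits a machine-readable ground-truth log (schedules, per-frame
blend factors, analytically expected state calls and transition frames,
event frame, peak force/extension). Recovery tests read only the log. All
randomness flows from one `numpy.random.default_rng(seed)`; outputs are
byte-identical across runs for a fixed seed.

What the generator does **not** emulate: thermal fluctuations with
physical correlation structure, force-field realism, solvent, or the time
scales of the real systems. Passing the recovery suite therefore shows the
*analysis* is correct and invariant, not that any biological number is
reproduced; absolute energies and times of the real complexes are
simulation outputs and out of scope here.

## Validation suite

`allostery.validation` holds the self-checks the acceptance tests and
`scripts/acceptance.py` share: superposition against a 100,000-rotation
brute-force oracle (200 random ≤ 8-point instances; the rotation set is
generated once and shared), orientation recovery noise-free and at
σ = 0.3 Å on a 30-atom-body variant (20 seeds), frame-exact state-machine
recovery plus explicit boundary/tie probes, energetics identities
(switch boundaries, exact-rational mid-point value, C¹ finite-difference
slopes at 1e-5 Å, LJ minimum, Coulomb closed form, double-sum
additivity/symmetry on 50 random toys kept at chemically sane ≥ 1.5 Å
contacts), cf/cv unbinding recovery, rigid-motion invariance, and a
two-run byte-identity determinism check through the CLI. Problem sizes are
chosen so the whole suite runs in well under a minute on one CPU.

## Known limitations

* PDB fixed-width output limits coordinate round-trips to 0.001 Å; metrics
  recovered through files inherit ~1e-2° / ~1e-3 Å noise ceilings.
* The classification tie rule is only defined for the S1/S1′ pair; other
  overlaps use smallest-RMSD as a package convention.
* mmCIF, binary trajectory formats, topology/bond perception,
  Ewald electrostatics, and any free-energy or Markov-state modelling of
  the transitions are out of scope.
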