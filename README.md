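# allostery

Trajectory analysis of interdomain allostery in multi-domain adhesion
receptors — written for the P-selectin / PSGL-1 system, applicable to any
chain in which a distal domain reorients about a two-residue hinge while a
binding-pocket loop interconverts among reference conformations.

Selectins hold leukocytes against blood flow through catch bonds: the
P-selectin lectin (Lec) domain binds the PSGL-1 sulfoglycopeptide, and the
affinity of that pocket tracks the orientation of the adjacent EGF domain
and the conformation of the Lec-domain *R*3 loop (residues P81–D89), which
switches between an unligated state **S1**, an equilibration intermediate
**S1′**, and a ligated state **S2**. Molecular-dynamics studies of this
system produce long coordinate trajectories; this package implements the
analysis layer that turns those trajectories into the standard observables,
plus a synthetic-trajectory generator with exact ground truth so the whole
pipeline can be validated at desk scale.

## What it computes

* **Domain orientation** — the angle between two vectors that share their
  origin at the geometric center of the heavy atoms of a two-residue hinge
  (Lec-EGF: A120/S121; EGF-CR1: C159/G160) and point to the geometric
  center of the oriented domain body (EGF: C122–T141; CR1: E161–L217), in
  the reference structure and in each frame after least-squares
  superposition on the rigid proximal domain (Kabsch, proper rotations
  only).
* **Loop-state classification** — per-frame *R*3-loop RMSD against each
  reference state after alignment on the Lec rigid parts; a frame qualifies
  for a state when RMSD ≤ 4.0 Å (boundary inclusive); S1/S1′ dual
  qualifiers are called S1′; remaining ambiguities resolve by smallest
  RMSD. Per-state fractions, energy-weighted mean ± SD statistics and
  dwell-filtered transition detection follow.
* **Nonbond energetics** — group–group interaction energy as switched
  Lennard-Jones plus switched Coulomb (`C = 332.0636 kcal·Å/(mol·e²)`,
  Lorentz–Berthelot combination) with the standard C¹ switching polynomial
  between `r_on = 10 Å` and `r_off = 12 Å`; receptor–ligand profiles and
  two-stage-averaged hinge energy tables.
* **Forced unbinding** — molecular extension (pulled-atom displacement
  along the fixed→pulled force axis), complex separation (domain-center
  distance projected on the axis, or marker-pair Euclidean distance),
  dissociation time (first persistent frame with |E| at zero), and force
  peak features for constant-force (300 pN) and constant-velocity
  (0.01 Å/ps, 70 pN/Å spring) protocols.

Inputs are plain multi-model PDB trajectories, a CSV nonbond parameter
table (`residue_name,atom_name,charge_e,epsilon_kcal,rmin_half_A`), and a
YAML run configuration; selections use a small documented grammar
(`chain A and resid 81-89 and heavy`). Units throughout: Å, ns, kcal/mol,
pN, degrees.

## Worked example

Generate a synthetic equilibration run (EGF hinge opening over 2.5–8 ns, a
programmed S1→S1′ loop switch, per-frame random rigid motions) and classify
its loop states:

```sh
allostery synth --mode equilibration --seed 11 --out run/
allostery classify --config run/config.yaml --out cls/
```

`cls/states_summary.json`:

```json
{
 "n_frames": 200,
 "threshold_A": 4.0,
 "fractions": {"S1": 0.525, "S1'": 0.43, "S2": 0.0},
 "transitions": [["S1", "S1'", 114]]
}
```

52.5 % of frames sit in the unligated S1 state, 43 % in the intermediate
S1′, and the one persistent transition S1→S1′ is detected at frame 114 —
exactly where the generator's ground-truth log
(`run/groundtruth.json`) programmed the loop blend to cross the 4.0 Å rule.
The per-frame table shows the evidence: at 0 ns the loop is 0.0 Å from S1
and 14 Å from the others; mid-blend (5.25 ns) it is > 4 Å from every
reference and the frame is `unassigned`; by 6.5 ns it is 0.0 Å from S1′.

```text
 time_ns  rmsd_S1_A  rmsd_S1p_A  rmsd_S2_A        call
    0.00   0.000805   13.999801  13.999694          S1
    5.25   4.199940    9.800060  14.616272  unassigned
    6.50  13.999866    0.000849  19.799158         S1'
```

The same pattern works for `orient` (angle series), `energy`
(receptor–ligand profile), `unbind` (`--mode cf|cv`; event + peak summary)
and `report` (mean ± SD across replicate run summaries).

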