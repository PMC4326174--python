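"""Self-validation suite: end-to-end property checks with known ground truth.

Each routine here builds its own inputs (synthetic systems, random point
sets), runs the corresponding analysis path, and returns the measured
quantities — recovery errors, oracle gaps, invariance deviations, exactness
flags.  The pytest acceptance tests assert on these numbers and the
``scripts/acceptance.py`` entry point reports them, so both run literally
the same computations.

All randomness flows from a caller-supplied seed.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np

from .conformation import OrientationDefinition, ReferenceState, classify_frames, loop_rmsd_series
from .energetics import (COULOMB_KCAL_A_PER_E2, CutoffScheme, EnergyProfile,
                         group_energy_series, pair_energy, switching)
from .geometry import rmsd, superpose
from .structio import Selection, Trajectory
from .synthetic import (SyntheticSpec, ToyTopology, build_toy,
                        generate_dissociation, generate_equilibration)
from .unbinding import (PullingSetup, dissociation_time, extension_series,
                        force_axis, force_profile_features, separation_series)

__all__ = [
    "check_superpose_oracle",
    "check_orientation_recovery",
    "check_state_recovery",
    "check_energetics",
    "check_unbinding_recovery",
    "check_invariance",
    "check_determinism",
]


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform random rotation matrices (QR decomposition of Gaussians)."""
    M = rng.normal(size=(n, 3, 3))
    Q, R = np.linalg.qr(M)
    signs = np.sign(np.einsum("nii->ni", R))
    Q = Q * signs[:, None, :]
    det = np.linalg.det(Q)
    Q[det < 0, :, 0] *= -1
    return Q


def check_superpose_oracle(seed: int, n_instances: int = 200,
                           n_rotations: int = 100_000,
                           max_points: int = 8) -> dict:
    """Brute-force oracle for the Kabsch kernel.

    For random small point-set pairs, the analytic least-RMSD proper
    superposition must never be beaten (beyond 1e-6 Å) by the best of
    ``n_rotations`` random rotations with centroid matching.  Returns the
    worst (most positive) value of ``kabsch_rmsd − best_random_rmsd`` and
    the number of violations.
    """
    rng = np.random.default_rng(seed)
    rotations = _random_rotations(rng, n_rotations)  # shared across instances
    worst_gap = -np.inf
    violations = 0
    for _ in range(n_instances):
        n = int(rng.integers(4, max_points + 1))
        mobile = rng.normal(scale=3.0, size=(n, 3))
        true_rot = _random_rotations(rng, 1)[0]
        target = (mobile @ true_rot.T + rng.uniform(-5, 5, 3)
                  + rng.normal(scale=0.4, size=(n, 3)))
        _, kabsch = superpose(mobile, target)
        mc = mobile - mobile.mean(axis=0)
        tc = target - target.mean(axis=0)
        # rmsd for every random rotation, centroids matched
        rotated = np.einsum("rij,nj->rni", rotations, mc)
        d2 = np.mean(np.sum((rotated - tc[None]) ** 2, axis=-1), axis=-1)
        best = float(np.sqrt(d2.min()))
        gap = kabsch - best
        worst_gap = max(worst_gap, gap)
        if gap > 1e-6:
            violations += 1
    return {"worst_gap_A": float(worst_gap), "violations": violations,
            "n_instances": n_instances, "n_rotations": n_rotations}


def _egf_orientation(system, traj: Trajectory) -> np.ndarray:
    sel = system.selections
    odef = OrientationDefinition(
        hinge_sel=Selection(sel["hinge1"]), body_sel=Selection(sel["egf"]),
        align_sel=Selection(sel["lec_rigid"]), reference=system.structure)
    from .conformation import orientation_series
    return orientation_series(traj, odef)


def check_orientation_recovery(seed: int, n_noise_seeds: int = 20) -> dict:
    """Programmed piecewise-linear hinge schedules against recovered angles.

    Noise-free: max |recovered − programmed| over a schedule spanning
    [0°, 170°] with per-frame random global rigid motions.  Noisy: mean
    absolute error with σ = 0.3 Å isotropic coordinate noise on a toy with a
    30-atom oriented body, averaged over ``n_noise_seeds`` generator seeds.
    """
    schedule = [(0.0, 0.0), (2.0, 0.0), (7.0, 170.0), (10.0, 40.0)]
    system = build_toy(seed=seed)
    spec = SyntheticSpec(seed=seed, mode="equilibration", theta_schedule=schedule)
    traj, truth = generate_equilibration(system, spec)
    angles = _egf_orientation(system, traj)
    noise_free_max = float(np.max(np.abs(angles - np.asarray(truth.theta_egf_deg))))

    maes = []
    topo30 = ToyTopology(egf_size=30)
    for k in range(n_noise_seeds):
        s = build_toy(topo30, seed=seed + 1000 + k)
        sp = SyntheticSpec(seed=seed + 1000 + k, mode="equilibration",
                           theta_schedule=schedule, sigma_A=0.3)
        tr, tru = generate_equilibration(s, sp)
        a = _egf_orientation(s, tr)
        maes.append(float(np.mean(np.abs(a - np.asarray(tru.theta_egf_deg)))))
    return {"noise_free_max_err_deg": noise_free_max,
            "noisy_mae_deg": float(np.mean(maes)),
            "n_noise_seeds": n_noise_seeds}


def check_state_recovery(seed: int) -> dict:
    """Programmed S1 → S1' → S2 sequences recovered frame-exactly.

    Also verifies the boundary-inclusive rule (RMSD exactly 4.0 Å is
    assigned) and the S1/S1' tie rule (dual qualifiers called S1') on
    constructed evidence.
    """
    system = build_toy(seed=seed)
    spec = SyntheticSpec(seed=seed, mode="equilibration",
                         theta_schedule=[(0.0, 0.0), (10.0, 60.0)],
                         loop_schedule=[(0, "S1"), (70, "S1'"), (140, "S2")],
                         loop_blend_frames=20)
    traj, truth = generate_equilibration(system, spec)
    sel = system.selections
    refs = [ReferenceState(lab, system.references[lab],
                           Selection(sel["lec_rigid"]), Selection(sel["loop"]))
            for lab in ("S1", "S1'", "S2")]
    series = loop_rmsd_series(traj, refs)
    calls = classify_frames(series, threshold=4.0)
    mismatches = sum(c.call != e for c, e in zip(calls, truth.expected_calls))

    import pandas as pd
    probe = pd.DataFrame({"S1": [4.0, 3.5, 5.0], "S1'": [6.0, 3.8, 6.0],
                          "S2": [7.0, 9.0, 7.0]})
    probe_calls = [c.call for c in classify_frames(probe, threshold=4.0)]
    boundary_ok = probe_calls[0] == "S1"          # exactly 4.0 Å qualifies
    tie_ok = probe_calls[1] == "S1'"              # dual qualifier → S1'
    unassigned_ok = probe_calls[2] == "unassigned"
    return {"frame_mismatches": int(mismatches), "n_frames": len(calls),
            "boundary_inclusive_ok": bool(boundary_ok),
            "tie_rule_ok": bool(tie_ok), "no_qualifier_ok": bool(unassigned_ok)}


def check_energetics(seed: int, n_random: int = 50) -> dict:
    """Switching boundaries and smoothness, LJ minimum, additivity, symmetry.

    The C¹ check compares one-sided finite-difference slopes (1e-5 Å
    spacing) at both switch boundaries; the switch value at 11 Å is checked
    against exact rational evaluation of the polynomial; group-energy
    additivity and symmetry are checked against a direct per-pair double-sum
    oracle on random toys.
    """
    scheme = CutoffScheme(10.0, 12.0)
    s_on = float(switching(10.0, scheme))
    s_off = float(switching(12.0, scheme))

    h = 1e-5
    slope_gaps = []
    for r0 in (scheme.r_on, scheme.r_off):
        left = (switching(r0, scheme) - switching(r0 - h, scheme)) / h
        right = (switching(r0 + h, scheme) - switching(r0, scheme)) / h
        slope_gaps.append(abs(float(left) - float(right)))
    c1_gap = max(slope_gaps)

    # exact rational evaluation of the switch polynomial at r = 11 Å
    r2, on2, off2 = Fraction(121), Fraction(100), Fraction(144)
    s_exact = (off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2) / (off2 - on2) ** 3
    s_mid_err = abs(float(switching(11.0, scheme)) - float(s_exact))

    # LJ pair at its minimum returns -epsilon
    eps_i, eps_j, rh = 0.21, 0.12, 2.0
    vdw, elec = pair_energy(np.zeros(3), np.array([2 * rh, 0, 0]),
                            (0.0, eps_i, rh), (0.0, eps_j, rh), scheme)
    lj_min_err = abs(vdw + np.sqrt(eps_i * eps_j))
    # Coulomb closed form at 5 Å, unit charges, no LJ
    _, elec5 = pair_energy(np.zeros(3), np.array([5.0, 0, 0]),
                           (1.0, 0.0, 1.0), (1.0, 0.0, 1.0), scheme)
    coulomb_err = abs(elec5 - COULOMB_KCAL_A_PER_E2 / 5.0)

    # additivity and symmetry on random toy configurations vs double-sum oracle
    rng = np.random.default_rng(seed)
    add_gap = 0.0
    sym_gap = 0.0
    oracle_gap = 0.0
    for _ in range(n_random):
        na, nb = 6, 5
        # keep contacts at chemically sane distances (>= 1.5 Å) so the LJ
        # r^-12 term stays within float range and comparisons are meaningful
        while True:
            ca = rng.uniform(-8, 8, (na, 3))
            cb = rng.uniform(-8, 8, (nb, 3)) + np.array([6.0, 0, 0])
            if np.min(np.linalg.norm(ca[:, None] - cb[None], axis=-1)) >= 1.5:
                break
        pa = [(rng.uniform(-0.5, 0.5), rng.uniform(0, 0.3), rng.uniform(1, 2.5))
              for _ in range(na)]
        pb = [(rng.uniform(-0.5, 0.5), rng.uniform(0, 0.3), rng.uniform(1, 2.5))
              for _ in range(nb)]
        # direct double sum — the independent oracle
        vdw_o = elec_o = 0.0
        for i in range(na):
            for j in range(nb):
                v, e = pair_energy(ca[i], cb[j], pa[i], pb[j], scheme)
                vdw_o += v
                elec_o += e
        traj, params = _pair_toy(ca, cb, pa, pb)
        prof_ab = group_energy_series(traj, "chain A", "chain B", params, scheme)
        prof_ba = group_energy_series(traj, "chain B", "chain A", params, scheme)
        oracle_gap = max(oracle_gap, abs(prof_ab.total[0] - (vdw_o + elec_o)))
        sym_gap = max(sym_gap, abs(prof_ab.total[0] - prof_ba.total[0]))
        # additivity over a disjoint split of group A
        e1 = group_energy_series(traj, "chain A and resid 1-3", "chain B",
                                 params, scheme).total[0]
        e2 = group_energy_series(traj, "chain A and resid 4-6", "chain B",
                                 params, scheme).total[0]
        add_gap = max(add_gap, abs((e1 + e2) - prof_ab.total[0]))
    return {"switch_at_r_on": s_on, "switch_at_r_off": s_off,
            "c1_slope_gap": float(c1_gap), "switch_mid_err": float(s_mid_err),
            "lj_min_err": float(lj_min_err), "coulomb_err": float(coulomb_err),
            "oracle_gap_kcal": float(oracle_gap),
            "symmetry_gap_kcal": float(sym_gap),
            "additivity_gap_kcal": float(add_gap)}


def _pair_toy(ca, cb, pa, pb):
    """Two small groups as a one-frame trajectory with per-atom parameters.

    Each atom gets a unique residue name so the (residue_name, atom_name)
    parameter key can carry distinct random parameters per atom.
    """
    from .structio import AtomRecord, NonbondParamTable, Structure
    atoms = []
    rows = {}
    serial = 1
    for chain, coords, params in (("A", ca, pa), ("B", cb, pb)):
        for i, pos in enumerate(coords):
            resn = f"{chain}{i:02d}"
            atoms.append(AtomRecord(serial, "CA", resn, chain, i + 1, pos, "C"))
            rows[(resn, "CA")] = params[i]
            serial += 1
    s = Structure(atoms, label="pairtoy")
    return Trajectory(s, [s.coords], [0.0]), NonbondParamTable(rows)


def check_unbinding_recovery(seed: int) -> dict:
    """Programmed dissociation event, force peak, and separation onset.

    Runs both constant-force and constant-velocity synthetic pulls and
    compares the analysis pipeline's outputs with the generator's log.
    """
    out = {}
    for mode in ("cf", "cv"):
        system = build_toy(seed=seed)
        spec = SyntheticSpec(seed=seed, mode=mode)
        traj, force, truth = generate_dissociation(system, spec)
        sel = system.selections
        setup = PullingSetup(Selection(sel["fixed"]), Selection(sel["pulled"]),
                             mode=mode)
        axis = force_axis(setup, traj)
        ext = extension_series(traj, setup)
        sep = separation_series(traj, sel["lec_rigid"], sel["ligand"], axis)
        profile = group_energy_series(traj, sel["receptor"], sel["ligand"],
                                      system.params)
        event = dissociation_time(profile, zero_tol=0.5, persistence=5,
                                  extension=ext, separation=sep)
        event_frame = event.frame_index if event is not None else -1
        # separation-phase onset: first frame where separation leaves frame-0 value
        moved = np.flatnonzero(np.abs(sep - sep[0]) > 1e-9)
        onset_frame = int(moved[0]) if moved.size else -1
        peak_force, peak_ext = force_profile_features(force, ext)
        out[mode] = {
            "event_frame_err": int(abs(event_frame - truth.event_frame)),
            "ext_max_err_A": float(np.max(np.abs(ext - np.asarray(truth.extension_A)))),
            "onset_frame_err": int(abs(onset_frame - truth.onset_frame)),
            "onset_extension_err_A": float(abs(ext[onset_frame] - truth.onset_extension_A)),
            "peak_force_err_pN": float(abs(peak_force - truth.peak_force_pN)),
            "peak_extension_err_A": float(abs(peak_ext - truth.peak_extension_A)),
        }
    return out


def check_invariance(seed: int, n_motions: int = 20) -> dict:
    """Metrics under per-frame random global rigid motions.

    Orientation and loop-RMSD series are computed on the same programmed
    trajectory with and without per-frame rigid motions; group energies are
    compared frame-by-frame under a rigid motion of all coordinates;
    separation/extension are checked under translations perpendicular to the
    pulling axis.
    """
    system = build_toy(seed=seed)
    sel = system.selections
    kw = dict(mode="equilibration",
              theta_schedule=[(0.0, 10.0), (10.0, 120.0)],
              loop_schedule=[(0, "S1"), (100, "S2")])
    spec_plain = SyntheticSpec(seed=seed, global_motion=False, **kw)
    spec_moved = SyntheticSpec(seed=seed, global_motion=True, **kw)
    traj_plain, _ = generate_equilibration(system, spec_plain)
    traj_moved, _ = generate_equilibration(system, spec_moved)

    ang_gap = float(np.max(np.abs(_egf_orientation(system, traj_plain)
                                  - _egf_orientation(system, traj_moved))))
    refs = [ReferenceState(lab, system.references[lab],
                           Selection(sel["lec_rigid"]), Selection(sel["loop"]))
            for lab in ("S1", "S1'", "S2")]
    r_plain = loop_rmsd_series(traj_plain, refs).to_numpy()
    r_moved = loop_rmsd_series(traj_moved, refs).to_numpy()
    rmsd_gap = float(np.max(np.abs(r_plain - r_moved)))

    # energy invariance: rigid motion of every frame
    rng = np.random.default_rng(seed + 7)
    prof = group_energy_series(traj_plain, sel["receptor"], sel["ligand"],
                               system.params)
    energy_gap = 0.0
    for _ in range(n_motions):
        Q = _random_rotations(rng, 1)[0]
        t = rng.uniform(-30, 30, 3)
        moved = Trajectory(traj_plain.topology,
                           [f @ Q.T + t for f in traj_plain.frames],
                           traj_plain.times)
        p2 = group_energy_series(moved, sel["receptor"], sel["ligand"],
                                 system.params)
        energy_gap = max(energy_gap, float(np.max(np.abs(p2.total - prof.total))))

    # separation/extension invariance under perpendicular translations
    dspec = SyntheticSpec(seed=seed, mode="cf")
    dtraj, _, _ = generate_dissociation(system, dspec)
    setup = PullingSetup(Selection(sel["fixed"]), Selection(sel["pulled"]), mode="cf")
    axis = force_axis(setup, dtraj)
    perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    shifted = Trajectory(dtraj.topology,
                         [f + 11.0 * perp for f in dtraj.frames], dtraj.times)
    ext_gap = float(np.max(np.abs(extension_series(dtraj, setup)
                                  - extension_series(shifted, setup))))
    sep_gap = float(np.max(np.abs(
        separation_series(dtraj, sel["lec_rigid"], sel["ligand"], axis)
        - separation_series(shifted, sel["lec_rigid"], sel["ligand"], axis))))
    return {"orientation_gap_deg": ang_gap, "loop_rmsd_gap_A": rmsd_gap,
            "energy_gap_kcal": energy_gap, "extension_gap_A": ext_gap,
            "separation_gap_A": sep_gap}


def check_determinism(seed: int, tmp_dir: str | Path) -> dict:
    """Two identical synth + analysis pipeline runs must be byte-identical."""
    from click.testing import CliRunner
    from .cli import main as cli_main
    tmp_dir = Path(tmp_dir)
    digests = []
    for rep in ("a", "b"):
        base = tmp_dir / rep
        runner = CliRunner()
        r = runner.invoke(cli_main, ["synth", "--mode", "equilibration",
                                     "--seed", str(seed), "--out", str(base / "synth")])
        assert r.exit_code == 0, r.output
        for cmd in ("orient", "classify"):
            r = runner.invoke(cli_main, [cmd, "--config",
                                         str(base / "synth" / "config.yaml"),
                                         "--out", str(base / cmd)])
            assert r.exit_code == 0, r.output
        import hashlib
        h = hashlib.sha256()
        for f in sorted((base / "orient").glob("*.csv")) + \
                 sorted((base / "classify").glob("*.csv")) + \
                 sorted((base / "synth").glob("*.pdb")):
            h.update(f.read_bytes())
        digests.append(h.hexdigest())
    return {"identical": int(digests[0] == digests[1])}
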