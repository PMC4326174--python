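"""Synthetic multi-domain trajectories with fully known ground truth.

The generator emulates the architecture the analyses are built for — a
four-module receptor chain (lectin rigid core + mobile 9-residue loop,
Lec-EGF hinge, EGF body, EGF-CR1 hinge, CR1, CR1-CR2 hinge, CR2) plus a
short bound ligand — as point clouds of one Cα pseudo-atom per residue.
Residue numbering mirrors the real system (loop 81–89, hinge 120/121, EGF
122–141, hinge 159/160, CR1 from 161, ligand ending at residue 618) so that
the published selection expressions read naturally.

Three generation modes:

* ``equilibration`` — the EGF body (and everything distal to it) rotates
  about the Lec-EGF hinge center following a piecewise-linear angle schedule
  θ(t); optionally CR1 rotates about the EGF-CR1 hinge by its own schedule;
  the loop interconverts among three reference conformations that are
  mutually ≥ 10 Å RMSD apart; every frame optionally receives isotropic
  Gaussian coordinate noise and a random global rigid motion (so alignment
  is genuinely exercised).

* ``cf`` / ``cv`` — forced dissociation: an intramolecular-extension phase
  (the lectin block and the bound ligand translate together along the
  fixed→pulled axis, i.e. hinge opening) precedes a separation phase in
  which the ligand alone departs; the receptor–ligand contact is broken past
  the 12 Å cutoff in the step into the programmed event frame, so the
  interaction energy is exactly zero from that frame on.  A constant-force
  run logs its constant force; a constant-velocity run logs
  spring × (cantilever lag), mimicking a steered-MD force log.

Every output is accompanied by a machine-readable ground-truth log (exact
angle schedules, per-frame loop blend factors and expected state calls,
transition frames, programmed event frame and force-peak).  Recovery tests
read only this log.  Determinism: all randomness flows from one
``numpy.random.default_rng(seed)``.

These trajectories are geometric constructions, not physical dynamics: no
thermal correlation, no realistic force fields, no solvent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structio import (AtomRecord, NonbondParamTable, Selection, Structure,
                       Trajectory)

__all__ = [
    "ToyTopology",
    "ToySystem",
    "SyntheticSpec",
    "GroundTruth",
    "build_toy",
    "generate_equilibration",
    "generate_dissociation",
]

STATE_LABELS = ("S1", "S1'", "S2")

#: uniform translation offsets (Å) of the loop in each reference conformation;
#: pairwise distances 14, 14 and 14√2 ≈ 19.8 Å, all ≥ 10 Å.
_LOOP_OFFSETS = {
    "S1": np.array([0.0, 0.0, 0.0]),
    "S1'": np.array([0.0, 14.0, 0.0]),
    "S2": np.array([0.0, 0.0, -14.0]),
}


@dataclass(frozen=True)
class ToyTopology:
    """Region sizes (atoms = residues) and the derived residue layout."""

    lec_size: int = 30
    loop_size: int = 9
    egf_size: int = 20
    cr1_size: int = 30
    cr2_size: int = 30
    ligand_size: int = 10

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        """Inclusive residue ranges, mirroring the real numbering."""
        loop = (81, 81 + self.loop_size - 1)          # 81-89 by default
        lec = (90, 90 + self.lec_size - 1)            # 90-119
        hinge1 = (120, 121)
        egf = (122, 122 + self.egf_size - 1)          # 122-141
        hinge2 = (159, 160)
        cr1 = (161, 161 + self.cr1_size - 1)          # 161-190
        hinge3 = (cr1[1] + 1, cr1[1] + 2)
        cr2 = (hinge3[1] + 1, hinge3[1] + self.cr2_size)
        ligand = (619 - self.ligand_size, 618)        # 609-618
        return {"loop": loop, "lec_rigid": lec, "hinge1": hinge1, "egf": egf,
                "hinge2": hinge2, "cr1": cr1, "hinge3": hinge3, "cr2": cr2,
                "ligand": ligand}

    @property
    def selections(self) -> dict[str, str]:
        """Published selection expressions for every region."""
        r = self.regions
        sels = {name: f"chain A and resid {lo}-{hi}" for name, (lo, hi) in r.items()
                if name != "ligand"}
        sels["ligand"] = f"chain B and resid {r['ligand'][0]}-{r['ligand'][1]}"
        sels["receptor"] = "chain A"
        sels["pulled"] = f"chain B and resid {r['ligand'][1]}"
        sels["fixed"] = f"chain A and resid {r['cr2'][1]}"
        return sels


@dataclass
class ToySystem:
    """A built toy: base structure, loop reference states, parameters, truth."""

    topology: ToyTopology
    structure: Structure                   # loop in the S1 conformation
    references: dict[str, Structure]       # S1 / S1' / S2 full structures
    params: NonbondParamTable
    index_sets: dict[str, np.ndarray]      # region name → atom indices
    selections: dict[str, str]


def _region_atoms(topo: ToyTopology, rng: np.random.Generator) -> tuple[list[AtomRecord], dict[str, np.ndarray]]:
    regions = topo.regions
    atoms: list[AtomRecord] = []
    index_sets: dict[str, np.ndarray] = {}
    serial = 1

    def add(name: str, chain: str, resname: str, coords: np.ndarray) -> None:
        nonlocal serial
        lo, hi = regions[name]
        n = hi - lo + 1
        assert coords.shape == (n, 3)
        start = len(atoms)
        for j in range(n):
            atoms.append(AtomRecord(serial, "CA", resname, chain, lo + j,
                                    coords[j], element="C"))
            serial += 1
        index_sets[name] = np.arange(start, start + n)

    # lectin rigid core: a helix of radius 6 Å spanning z in [-5, 5]
    n = topo.lec_size
    phi = 2 * np.pi * np.arange(n) / 10.0
    lec = np.column_stack([6 * np.cos(phi), 6 * np.sin(phi),
                           np.linspace(-5, 5, n)])
    lec += rng.normal(0, 0.3, lec.shape)
    # mobile loop, S1 conformation: an arc to the +x side of the core
    j = np.arange(topo.loop_size)
    loop = np.column_stack([8.0 + 1.2 * j, 0.8 * np.sin(j), np.zeros_like(j, dtype=float)])
    loop += rng.normal(0, 0.2, loop.shape)

    def cloud(center: np.ndarray, size: int, spread: float) -> np.ndarray:
        return center + rng.normal(0, spread, (size, 3))

    add("loop", "A", "ALA", loop)
    add("lec_rigid", "A", "ALA", lec)
    add("hinge1", "A", "ALA", np.array([[0, 0, 7.0], [0, 0, 9.0]]) + rng.normal(0, 0.1, (2, 3)))
    add("egf", "A", "ALA", cloud(np.array([0, 0, 23.0]), topo.egf_size, 2.5))
    add("hinge2", "A", "ALA", np.array([[0, 0, 30.0], [0, 0, 32.0]]) + rng.normal(0, 0.1, (2, 3)))
    add("cr1", "A", "ALA", cloud(np.array([0, 0, 46.0]), topo.cr1_size, 2.5))
    add("hinge3", "A", "ALA", np.array([[0, 0, 53.0], [0, 0, 55.0]]) + rng.normal(0, 0.1, (2, 3)))
    add("cr2", "A", "ALA", cloud(np.array([0, 0, 69.0]), topo.cr2_size, 2.5))
    add("ligand", "B", "LIG", cloud(np.array([-10.0, 0, 0]), topo.ligand_size, 1.2))
    return atoms, index_sets


def build_toy(topo: ToyTopology = ToyTopology(), seed: int = 0) -> ToySystem:
    """Deterministically build the toy system for a given seed.

    The three loop reference conformations are the base loop under uniform
    translations that put them pairwise ≥ 10 Å RMSD apart, so the 4.0 Å
    state rule separates them cleanly.  The parameter table assigns mildly
    attractive receptor/ligand charges (+0.10 e vs −0.15 e) and a soft LJ
    well (ε = 0.12 kcal/mol, Rmin/2 = 1.2 Å) so that bound-contact energies
    are far from zero while steric blowup is impossible at the toy's contact
    distances.
    """
    rng = np.random.default_rng(seed)
    atoms, index_sets = _region_atoms(topo, rng)
    base = Structure(atoms, label="toy")

    references: dict[str, Structure] = {}
    for label in STATE_LABELS:
        coords = base.coords
        coords[index_sets["loop"]] += _LOOP_OFFSETS[label]
        references[label] = base.with_coords(coords, label=f"ref_{label}")
    # the base structure carries the S1 loop by construction
    params = NonbondParamTable({
        ("ALA", "CA"): (0.10, 0.12, 1.2),
        ("LIG", "CA"): (-0.15, 0.12, 1.2),
    })
    return ToySystem(topo, references["S1"], references, params,
                     index_sets, topo.selections)


@dataclass
class SyntheticSpec:
    """What to generate: schedules, noise, pulling protocol.

    ``theta_schedule`` / ``theta_cr1_schedule`` are piecewise-linear
    breakpoints ``[(time_ns, angle_deg), ...]``; ``loop_schedule`` is a list
    of ``(frame, state)`` switch points (the first entry must be frame 0),
    each switch blending linearly over ``loop_blend_frames`` frames.
    """

    seed: int = 0
    mode: str = "equilibration"            # equilibration | cf | cv
    n_frames: int = 200
    dt_ns: float = 0.05
    sigma_A: float = 0.0                   # isotropic coordinate noise
    global_motion: bool = True             # random per-frame rigid motion
    theta_schedule: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 0.0), (2.5, 0.0), (8.0, 95.0), (10.0, 95.0)])
    theta_cr1_schedule: list[tuple[float, float]] | None = None
    loop_schedule: list[tuple[int, str]] = field(
        default_factory=lambda: [(0, "S1"), (100, "S1'")])
    loop_blend_frames: int = 20
    # forced-dissociation protocol
    force_pN: float = 300.0
    velocity_A_per_ps: float = 0.01
    spring_pN_per_A: float = 70.0
    onset_frame: int = 80                  # start of the separation phase
    event_frame: int = 140                 # first zero-energy frame
    intra_extension_A: float = 8.0         # hinge-opening travel before separation
    creep_A: float = 4.0                   # ligand creep before the break
    clearance_A: float = 30.0              # relative jump that breaks all contacts
    peak_force_pN: float = 210.0
    peak_frame: int = 40


@dataclass
class GroundTruth:
    """Machine-readable log of everything the generator programmed."""

    mode: str
    seed: int
    times_ns: list[float]
    selections: dict[str, str]
    # equilibration
    theta_egf_deg: list[float] | None = None
    theta_cr1_deg: list[float] | None = None
    loop_lambda: list[float] | None = None
    expected_calls: list[str] | None = None
    transitions: list[list] | None = None          # [from, to, frame]
    loop_pair_rmsd_A: dict[str, float] | None = None
    # dissociation
    axis: list[float] | None = None
    extension_A: list[float] | None = None
    # separation change vs frame 0, measured lectin-domain center → ligand center
    separation_offset_A: list[float] | None = None
    onset_frame: int | None = None
    onset_extension_A: float | None = None
    event_frame: int | None = None
    force_pN: list[float] | None = None
    peak_force_pN: float | None = None
    peak_frame: int | None = None
    peak_extension_A: float | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    t = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _perpendicular_axis(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to v (deterministic choice)."""
    v = np.asarray(v, dtype=float)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, v)) > 0.9 * np.linalg.norm(v):
        trial = np.array([0.0, 1.0, 0.0])
    w = np.cross(v, trial)
    return w / np.linalg.norm(w)


def _random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random proper rotation (QR of a Gaussian matrix) + translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20, 20, 3)
    return Q, t


def _loop_blend(spec: SyntheticSpec) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Per-frame (from_state, to_state) and blend factor λ in [0, 1]."""
    if not spec.loop_schedule or spec.loop_schedule[0][0] != 0:
        raise ValueError("loop_schedule must start at frame 0")
    w = max(spec.loop_blend_frames, 1)
    pairs: list[tuple[str, str]] = []
    lam = np.zeros(spec.n_frames)
    current = spec.loop_schedule[0][1]
    sched = dict(spec.loop_schedule[1:])
    from_s, to_s, start = current, current, 0
    for i in range(spec.n_frames):
        if i in sched and sched[i] != current:
            from_s, to_s, start = current, sched[i], i
            current = sched[i]
        if from_s == to_s:
            pairs.append((current, current))
        else:
            x = min((i - start + 1) / w, 1.0)
            if x >= 1.0:
                from_s = to_s
                pairs.append((to_s, to_s))
            else:
                pairs.append((from_s, to_s))
                lam[i] = x
    return pairs, lam


def _expected_call(from_state: str, to_state: str, lam: float,
                   threshold: float = 4.0) -> str:
    """Analytic state call for a blended loop (uniform-translation states)."""
    if from_state == to_state:
        return from_state
    d = float(np.linalg.norm(_LOOP_OFFSETS[to_state] - _LOOP_OFFSETS[from_state]))
    d_from = lam * d
    d_to = (1.0 - lam) * d
    quals = []
    if d_from <= threshold:
        quals.append((d_from, from_state))
    if d_to <= threshold:
        quals.append((d_to, to_state))
    if not quals:
        return "unassigned"
    if len(quals) == 2 and {from_state, to_state} == {"S1", "S1'"}:
        return "S1'"
    return min(quals)[1]


def generate_equilibration(system: ToySystem, spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """A trajectory following the programmed hinge-angle and loop schedules.

    Distal-first composition keeps every schedule exactly recoverable: the
    CR1 block is rotated about the EGF-CR1 hinge first, then everything
    distal to the Lec-EGF hinge (including the already-rotated CR1) is
    rotated about the Lec-EGF hinge.  Both rotation axes are chosen
    perpendicular to the respective reference orientation vectors, so the
    recovered angle equals the programmed angle for θ in [0°, 180°].
    """
    if spec.mode != "equilibration":
        raise ValueError(f"spec.mode is {spec.mode!r}, expected 'equilibration'")
    rng = np.random.default_rng(spec.seed)
    topo_struct = system.structure
    base = topo_struct.coords
    idx = system.index_sets
    times = np.arange(spec.n_frames) * spec.dt_ns

    bp = np.array(spec.theta_schedule, dtype=float)
    theta_egf = np.interp(times, bp[:, 0], bp[:, 1])
    if spec.theta_cr1_schedule is not None:
        bp2 = np.array(spec.theta_cr1_schedule, dtype=float)
        theta_cr1 = np.interp(times, bp2[:, 0], bp2[:, 1])
    else:
        theta_cr1 = np.zeros_like(times)

    h1 = base[idx["hinge1"]].mean(axis=0)
    h2 = base[idx["hinge2"]].mean(axis=0)
    v1 = base[idx["egf"]].mean(axis=0) - h1
    v2 = base[idx["cr1"]].mean(axis=0) - h2
    axis1 = _perpendicular_axis(v1)
    axis2 = _perpendicular_axis(v2)

    distal1 = np.concatenate([idx["egf"], idx["hinge2"], idx["cr1"],
                              idx["hinge3"], idx["cr2"]])
    distal2 = np.concatenate([idx["cr1"], idx["hinge3"], idx["cr2"]])

    pairs, lam = _loop_blend(spec)
    loop_base = base[idx["loop"]] - _LOOP_OFFSETS["S1"]  # base carries S1

    frames = []
    for i in range(spec.n_frames):
        coords = base.copy()
        # loop conformation
        frm, to = pairs[i]
        off = (1 - lam[i]) * _LOOP_OFFSETS[frm] + lam[i] * _LOOP_OFFSETS[to]
        coords[idx["loop"]] = loop_base + off
        # CR1 rotation about the (unrotated) EGF-CR1 hinge, then the EGF rotation
        R2 = _rotation_about(axis2, float(theta_cr1[i]))
        coords[distal2] = (coords[distal2] - h2) @ R2.T + h2
        R1 = _rotation_about(axis1, float(theta_egf[i]))
        coords[distal1] = (coords[distal1] - h1) @ R1.T + h1
        if spec.sigma_A > 0:
            coords = coords + rng.normal(0, spec.sigma_A, coords.shape)
        if spec.global_motion:
            Q, t = _random_rigid_motion(rng)
            coords = coords @ Q.T + t
        frames.append(coords)

    expected = [_expected_call(f, t, float(l)) for (f, t), l in zip(pairs, lam)]
    transitions = _expected_transitions(spec, pairs, lam)
    dists = {}
    for a in STATE_LABELS:
        for b in STATE_LABELS:
            if a < b:
                dists[f"{a}|{b}"] = float(np.linalg.norm(_LOOP_OFFSETS[a] - _LOOP_OFFSETS[b]))
    truth = GroundTruth(
        mode="equilibration", seed=spec.seed, times_ns=times.tolist(),
        selections=dict(system.selections),
        theta_egf_deg=theta_egf.tolist(), theta_cr1_deg=theta_cr1.tolist(),
        loop_lambda=lam.tolist(), expected_calls=expected,
        transitions=[list(t) for t in transitions], loop_pair_rmsd_A=dists,
    )
    return Trajectory(topo_struct, frames, times), truth


def _expected_transitions(spec: SyntheticSpec, pairs: list[tuple[str, str]],
                          lam: np.ndarray) -> list[tuple[str, str, int]]:
    """Frame of first qualification for each scheduled target state."""
    out = []
    expected = [_expected_call(f, t, float(l)) for (f, t), l in zip(pairs, lam)]
    current = expected[0]
    for i, call in enumerate(expected):
        if call not in ("unassigned", current):
            out.append((current, call, i))
            current = call
    return out


def generate_dissociation(system: ToySystem, spec: SyntheticSpec) -> tuple[Trajectory, np.ndarray, GroundTruth]:
    """A forced-unbinding trajectory plus force log and ground truth.

    Phase 1 (frames [0, onset_frame)): the lectin block (rigid core + loop)
    and the ligand translate together along the force axis — intramolecular
    extension with constant receptor–ligand contact.  Phase 2: the ligand
    alone creeps away by ``creep_A``, then jumps past the cutoff clearance
    in the step into ``event_frame`` and keeps receding, so the interaction
    energy is exactly zero from ``event_frame`` on and well away from zero
    before it.
    """
    if spec.mode not in ("cf", "cv"):
        raise ValueError(f"spec.mode is {spec.mode!r}, expected 'cf' or 'cv'")
    if not (0 < spec.onset_frame < spec.event_frame < spec.n_frames - 1):
        raise ValueError("need 0 < onset_frame < event_frame < n_frames-1")
    rng = np.random.default_rng(spec.seed)
    base = system.structure.coords
    idx = system.index_sets
    n = spec.n_frames
    times = np.arange(n) * spec.dt_ns

    i_fixed = idx["cr2"][-1]
    i_pulled = idx["ligand"][-1]
    axis = base[i_pulled] - base[i_fixed]
    axis = axis / np.linalg.norm(axis)

    # block translation s(t): 0 → intra_extension over phase 1, then constant
    s = np.minimum(np.arange(n) / spec.onset_frame, 1.0) * spec.intra_extension_A
    # ligand-only translation u(t): creep, break, recede
    u = np.zeros(n)
    n_creep = spec.event_frame - spec.onset_frame
    # first creep step is nonzero: separation leaves its baseline at onset_frame
    u[spec.onset_frame:spec.event_frame] = (
        spec.creep_A * np.arange(1, n_creep + 1) / n_creep)
    tail = np.linspace(spec.clearance_A, spec.clearance_A * 1.5,
                       n - spec.event_frame)
    u[spec.event_frame:] = tail

    block = np.concatenate([idx["lec_rigid"], idx["loop"], idx["ligand"]])
    frames = []
    for i in range(n):
        coords = base.copy()
        coords[block] += s[i] * axis
        coords[idx["ligand"]] += u[i] * axis
        if spec.sigma_A > 0:
            coords = coords + rng.normal(0, spec.sigma_A, coords.shape)
        frames.append(coords)

    extension = s + u           # pulled-atom displacement along the axis
    separation_offset = u       # ligand-receptor separation change vs frame 0

    if spec.mode == "cf":
        force = np.full(n, spec.force_pN)
        peak_force = spec.force_pN
        peak_frame = 0
    else:
        # cantilever lag profile: rises to the programmed peak, then relaxes
        lag_peak = spec.peak_force_pN / spec.spring_pN_per_A
        lag = np.interp(np.arange(n),
                        [0, spec.peak_frame, spec.onset_frame, n - 1],
                        [0.0, lag_peak, 0.3 * lag_peak, 0.1 * lag_peak])
        force = spec.spring_pN_per_A * lag
        peak_force = float(force.max())
        peak_frame = int(np.argmax(force))

    truth = GroundTruth(
        mode=spec.mode, seed=spec.seed, times_ns=times.tolist(),
        selections=dict(system.selections),
        axis=axis.tolist(), extension_A=extension.tolist(),
        separation_offset_A=separation_offset.tolist(),
        onset_frame=spec.onset_frame, onset_extension_A=float(extension[spec.onset_frame]),
        event_frame=spec.event_frame, force_pN=force.tolist(),
        peak_force_pN=peak_force, peak_frame=peak_frame,
        peak_extension_A=float(extension[peak_frame]),
    )
    return Trajectory(system.structure, frames, times), force, truth
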