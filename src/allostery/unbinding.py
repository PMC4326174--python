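"""Forced-dissociation observables.

During steered pulling of a ligand off its receptor, the analysis tracks:

* **molecular extension** — displacement of the single pulled atom along the
  fixed→pulled force vector (frame 0 defines both the axis and the zero);
* **complex separation** — receptor/ligand geometric-center distance
  projected on the force axis, or alternatively a plain Euclidean
  marker-pair distance (e.g. fucose to calcium ion);
* **dissociation time** — the first time the receptor–ligand nonbond energy
  reaches zero (within a tolerance, persisting for a minimum number of
  frames);
* **force-profile features** — the peak force and the extension at which it
  occurs.

Units: Å, ns, kcal/mol, pN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .energetics import EnergyProfile
from .geometry import GeometryError, geometric_center
from .structio import Selection, Trajectory, resolve_selection

__all__ = [
    "PullingSetup",
    "DissociationEvent",
    "force_axis",
    "extension_series",
    "separation_series",
    "marker_distance_series",
    "dissociation_time",
    "force_profile_features",
    "replicate_statistics",
]


@dataclass(frozen=True)
class PullingSetup:
    """Steered-pulling protocol: which atom is held, which is pulled, and how.

    ``pulled_sel`` must resolve to exactly one atom (the ligand C-terminal
    Cα in the P-selectin systems); ``fixed_sel`` is the held anchor (a
    receptor C-terminal Cα).  Constant-force runs carry ``force_pN``
    (300 pN in the reference protocol); constant-velocity runs carry
    ``velocity_A_per_ps`` (0.01 Å/ps) and ``spring_pN_per_A`` (70 pN/Å).
    """

    fixed_sel: Selection
    pulled_sel: Selection
    mode: Literal["cf", "cv"] = "cf"
    force_pN: float = 300.0
    velocity_A_per_ps: float = 0.01
    spring_pN_per_A: float = 70.0

    def __post_init__(self) -> None:
        if self.mode not in ("cf", "cv"):
            raise ValueError(f"mode must be 'cf' or 'cv', got {self.mode!r}")


@dataclass(frozen=True)
class DissociationEvent:
    """First frame at which the receptor–ligand interaction has reached zero."""

    time_ns: float
    frame_index: int
    extension_at_event_A: float | None = None
    separation_at_event_A: float | None = None


def _single_atom(sel: Selection | str, traj: Trajectory, what: str) -> int:
    idx = resolve_selection(sel, traj.topology)
    if idx.size != 1:
        raise ValueError(f"{what} selection must resolve to exactly one atom, "
                         f"got {idx.size}")
    return int(idx[0])


def force_axis(setup: PullingSetup, traj: Trajectory) -> np.ndarray:
    """Unit vector from the fixed atom to the pulled atom in frame 0.

    Held constant across frames (the pulling direction is set once, at the
    start of the run).
    """
    i_fixed = _single_atom(setup.fixed_sel, traj, "fixed")
    i_pulled = _single_atom(setup.pulled_sel, traj, "pulled")
    if i_fixed == i_pulled:
        raise ValueError("fixed and pulled selections resolve to the same atom")
    v = traj.frames[0][i_pulled] - traj.frames[0][i_fixed]
    n = np.linalg.norm(v)
    if n <= 1e-9:
        raise GeometryError("fixed and pulled atoms are coincident in frame 0")
    return v / n


def extension_series(traj: Trajectory, setup: PullingSetup) -> np.ndarray:
    """Pulled-atom displacement (Å) along the force axis; frame 0 is 0."""
    axis = force_axis(setup, traj)
    i_pulled = _single_atom(setup.pulled_sel, traj, "pulled")
    origin = traj.frames[0][i_pulled]
    return np.array([float(np.dot(f[i_pulled] - origin, axis)) for f in traj.frames])


def separation_series(traj: Trajectory, receptor_sel: Selection | str,
                      ligand_sel: Selection | str, axis: np.ndarray) -> np.ndarray:
    """Receptor→ligand geometric-center separation projected on ``axis``, Å."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n <= 1e-9:
        raise GeometryError("separation axis has zero length")
    axis = axis / n
    ia = resolve_selection(receptor_sel, traj.topology)
    ib = resolve_selection(ligand_sel, traj.topology)
    return np.array([
        float(np.dot(geometric_center(f[ib]) - geometric_center(f[ia]), axis))
        for f in traj.frames
    ])


def marker_distance_series(traj: Trajectory, marker_a: Selection | str,
                           marker_b: Selection | str) -> np.ndarray:
    """Euclidean distance (Å) between two marker geometric centers, per frame."""
    ia = resolve_selection(marker_a, traj.topology)
    ib = resolve_selection(marker_b, traj.topology)
    return np.array([
        float(np.linalg.norm(geometric_center(f[ib]) - geometric_center(f[ia])))
        for f in traj.frames
    ])


def dissociation_time(profile: EnergyProfile, zero_tol: float = 0.5,
                      persistence: int = 5,
                      extension: np.ndarray | None = None,
                      separation: np.ndarray | None = None) -> DissociationEvent | None:
    """First frame where |total energy| ≤ ``zero_tol`` for ``persistence`` frames.

    "Reaching zero" on a fluctuating trace needs both a tolerance (kcal/mol)
    and a dwell: the event frame is the first index i such that every frame
    in [i, i+persistence) satisfies |total| ≤ zero_tol (runs truncated by the
    end of the trace still count if all their frames qualify).  Returns None
    if the criterion is never met.  Optional extension/separation series are
    sampled at the event frame for context.
    """
    if zero_tol <= 0:
        raise ValueError("zero_tol must be positive")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    total = profile.total
    if total.size == 0:
        raise ValueError("empty energy profile")
    ok = np.abs(total) <= zero_tol
    n = total.size
    for i in range(n):
        if not ok[i]:
            continue
        if np.all(ok[i:min(i + persistence, n)]):
            return DissociationEvent(
                time_ns=float(profile.times[i]),
                frame_index=i,
                extension_at_event_A=(float(extension[i])
                                      if extension is not None else None),
                separation_at_event_A=(float(separation[i])
                                       if separation is not None else None),
            )
    return None


def force_profile_features(force: np.ndarray,
                           extension: np.ndarray) -> tuple[float, float]:
    """(peak force pN, extension Å at the peak); ties go to the earliest frame."""
    force = np.asarray(force, dtype=float)
    extension = np.asarray(extension, dtype=float)
    if force.shape != extension.shape:
        raise ValueError(f"length mismatch: force {force.shape} vs "
                         f"extension {extension.shape}")
    if force.size == 0:
        raise ValueError("empty force profile")
    i = int(np.argmax(force))  # argmax returns the first maximal index
    return float(force[i]), float(extension[i])


def replicate_statistics(values: np.ndarray) -> tuple[float, float | None]:
    """Mean and sample SD (n−1) over replicate runs; SD is None for n < 2."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else None
    return mean, sd
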