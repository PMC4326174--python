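"""Conformational metrics: domain-orientation angles and loop-state calls.

Two families of observables describe the allosteric pathway of a multi-domain
receptor such as P-selectin:

* **Orientation angles.** The orientation of a distal domain (EGF relative to
  the lectin domain, or CR1 relative to EGF) is the angle between two
  vectors that both start at the geometric center of the heavy atoms of the
  two-residue interdomain hinge in a reference structure and end at the
  geometric center of the domain body — once in the reference and once in the
  trajectory frame, after the frame has been superposed onto the reference on
  an alignment selection (the rigid part of the proximal domain).

* **Loop-state calls.** The binding-pocket loop (the R3 loop, P81–D89 in
  P-selectin) interconverts among reference conformations labelled S1
  (unligated crystal), S1' (equilibration intermediate) and S2 (ligated
  crystal).  Per frame, the loop RMSD against each reference — fitted on the
  rigid alignment selection, measured over the loop — is thresholded at
  4.0 Å (inclusive).  A frame qualifying for exactly one state is called that
  state; a frame qualifying for both S1 and S1' is called S1'; any other
  multi-qualifier is resolved by smallest RMSD; no qualifier means
  ``unassigned``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (geometric_center, rmsd_after_alignment, superpose,
                       vector_angle)
from .structio import Selection, Structure, Trajectory, resolve_selection

__all__ = [
    "UNASSIGNED",
    "STATE_THRESHOLD_A",
    "OrientationDefinition",
    "ReferenceState",
    "StateCall",
    "orientation_series",
    "loop_rmsd_series",
    "classify_frames",
    "state_statistics",
    "transition_detect",
]

UNASSIGNED = "unassigned"

#: Loop-RMSD threshold (Å) below or at which a frame qualifies for a state.
STATE_THRESHOLD_A = 4.0


@dataclass(frozen=True)
class OrientationDefinition:
    """Hinge + domain-body selections defining an orientation vector.

    ``align_sel`` is the selection the frame is superposed on before the
    vectors are compared (e.g. Cα of the lectin-domain rigid parts for the
    EGF orientation, the EGF domain for the CR1 orientation).
    """

    hinge_sel: Selection
    body_sel: Selection
    align_sel: Selection
    reference: Structure

    def __post_init__(self) -> None:
        h = set(resolve_selection(self.hinge_sel, self.reference).tolist())
        b = set(resolve_selection(self.body_sel, self.reference).tolist())
        if h & b:
            raise ValueError("hinge and body selections overlap on the reference")
        resolve_selection(self.align_sel, self.reference)  # must be non-empty


@dataclass(frozen=True)
class ReferenceState:
    """A labelled reference conformation (e.g. S1, S1', S2) of the loop."""

    label: str
    structure: Structure
    align_sel: Selection
    loop_sel: Selection


@dataclass(frozen=True)
class StateCall:
    """Per-frame state assignment with the RMSD evidence behind it."""

    frame_index: int
    rmsd_by_state: dict[str, float]
    call: str  # a state label or UNASSIGNED


def orientation_series(traj: Trajectory, odef: OrientationDefinition,
                       frame_hinge_origin: bool = False) -> np.ndarray:
    """Per-frame orientation angle in degrees.

    Per frame: (1) superpose the frame onto the reference on ``align_sel``;
    (2) form the reference vector from the reference hinge center to the
    reference body center, and the frame vector from the reference hinge
    center to the aligned frame's body center; (3) return their angle.

    With ``frame_hinge_origin=True`` the frame vector instead starts at the
    aligned frame's own hinge center (config alternative; the default shares
    the reference origin).
    """
    hinge_t = resolve_selection(odef.hinge_sel, traj.topology)
    body_t = resolve_selection(odef.body_sel, traj.topology)
    align_t = resolve_selection(odef.align_sel, traj.topology)
    hinge_r = resolve_selection(odef.hinge_sel, odef.reference)
    body_r = resolve_selection(odef.body_sel, odef.reference)
    align_r = resolve_selection(odef.align_sel, odef.reference)
    if align_t.size != align_r.size:
        raise ValueError(
            f"alignment selection sizes differ between trajectory ({align_t.size}) "
            f"and reference ({align_r.size})")

    ref_coords = odef.reference.coords
    ref_hinge_center = geometric_center(ref_coords[hinge_r])
    v_ref = geometric_center(ref_coords[body_r]) - ref_hinge_center

    angles = np.empty(len(traj))
    for i, frame in enumerate(traj.frames):
        transform, _ = superpose(frame[align_t], ref_coords[align_r])
        body_center = geometric_center(transform.apply(frame[body_t]))
        if frame_hinge_origin:
            origin = geometric_center(transform.apply(frame[hinge_t]))
        else:
            origin = ref_hinge_center
        angles[i] = vector_angle(v_ref, body_center - origin)
    return angles


def loop_rmsd_series(traj: Trajectory, refs: list[ReferenceState]) -> pd.DataFrame:
    """Loop RMSD (Å) of every frame against every reference state.

    Returns a DataFrame with one column per state label, indexed by frame.
    Each value is the RMSD over the loop selection after superposition on the
    reference's alignment selection.
    """
    labels = [r.label for r in refs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate reference-state labels: {labels}")
    out = {}
    for ref in refs:
        align_t = resolve_selection(ref.align_sel, traj.topology)
        loop_t = resolve_selection(ref.loop_sel, traj.topology)
        align_r = resolve_selection(ref.align_sel, ref.structure)
        loop_r = resolve_selection(ref.loop_sel, ref.structure)
        ref_coords = ref.structure.coords
        out[ref.label] = [
            rmsd_after_alignment(frame, ref_coords, align_t, align_r, loop_t, loop_r)
            for frame in traj.frames
        ]
    return pd.DataFrame(out, index=pd.RangeIndex(len(traj), name="frame"))


def classify_frames(series: pd.DataFrame, threshold: float = STATE_THRESHOLD_A,
                    tie_pair: tuple[str, str] = ("S1", "S1'")) -> list[StateCall]:
    """Assign each frame to a state by thresholded loop RMSD.

    A frame qualifies for every state whose RMSD is ≤ ``threshold``
    (boundary inclusive).  Exactly one qualifier → that state.  If both
    members of ``tie_pair`` qualify, the second member (S1') absorbs the
    first — the intermediate state wins its overlap with the starting state.
    Any remaining multi-qualifier is resolved by smallest RMSD.  No
    qualifier → ``unassigned``.  Total and deterministic.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    calls = []
    labels = list(series.columns)
    values = series.to_numpy(dtype=float)
    for i, row in enumerate(values):
        by_state = dict(zip(labels, (float(x) for x in row)))
        qualifiers = [lab for lab in labels if by_state[lab] <= threshold]
        if tie_pair[0] in qualifiers and tie_pair[1] in qualifiers:
            qualifiers.remove(tie_pair[0])
        if not qualifiers:
            call = UNASSIGNED
        else:
            call = min(qualifiers, key=lambda lab: by_state[lab])
        calls.append(StateCall(i, by_state, call))
    return calls


def state_statistics(calls: list[StateCall],
                     weights: np.ndarray | None = None) -> pd.DataFrame:
    """Per-state frame counts, fractions, and mean ± sample SD of weights.

    ``weights`` (e.g. per-frame receptor–ligand interaction energies) align
    with ``calls`` by frame; unassigned frames are excluded from the weighted
    statistics.  SD uses the n−1 denominator and is reported as NaN (absent)
    for states with fewer than two frames; mean is NaN for empty states.
    """
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(calls),):
            raise ValueError(
                f"weights length {weights.shape} does not match {len(calls)} calls")
    states = sorted({c.call for c in calls} - {UNASSIGNED})
    # keep all state labels seen in the evidence maps too, so empty states report n=0
    for c in calls:
        for lab in c.rmsd_by_state:
            if lab not in states:
                states.append(lab)
    total = len(calls)
    rows = []
    for lab in states:
        idx = [c.frame_index for c in calls if c.call == lab]
        row = {"state": lab, "n": len(idx),
               "fraction": len(idx) / total if total else np.nan}
        if weights is not None:
            w = weights[idx]
            row["mean"] = float(np.mean(w)) if len(w) else np.nan
            row["sd"] = float(np.std(w, ddof=1)) if len(w) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("state")


def transition_detect(calls: list[StateCall],
                      min_dwell: int = 5) -> list[tuple[str, str, int]]:
    """Detect persistent state transitions in a call sequence.

    A transition ``(from_state, to_state, frame_index)`` is emitted when the
    call changes to a new state that then persists for at least ``min_dwell``
    assigned frames; shorter excursions are ignored as blips.  Unassigned
    frames neither start nor terminate a dwell.  The first persistent state
    establishes the baseline without emitting a transition.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    assigned = [(c.frame_index, c.call) for c in calls if c.call != UNASSIGNED]
    transitions: list[tuple[str, str, int]] = []
    current: str | None = None
    i = 0
    while i < len(assigned):
        frame, state = assigned[i]
        run = 1
        while i + run < len(assigned) and assigned[i + run][1] == state:
            run += 1
        if state != current and run >= min_dwell:
            if current is not None:
                transitions.append((current, state, frame))
            current = state
        i += run
    return transitions
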