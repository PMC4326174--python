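"""Rigid-body superposition, RMSD and vector geometry.

These are the kernels every conformational metric is built from: Kabsch
least-squares superposition (proper rotations only — reflections are
excluded), RMSD after alignment on one selection measured over another,
unweighted geometric centers, vector angles and signed projections.

Conventions: all lengths in Å, all angles in degrees.  "Geometric center"
is the plain arithmetic mean of coordinates — never mass-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "RigidTransform",
    "geometric_center",
    "superpose",
    "rmsd",
    "rmsd_after_alignment",
    "vector_angle",
    "project_along",
]


class GeometryError(ValueError):
    """Degenerate or inconsistent geometric input."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x ↦ R·x + t."""

    rotation: np.ndarray  # 3×3 proper orthogonal
    translation: np.ndarray  # 3-vector, Å

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise GeometryError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an N×3 array (or a single 3-vector)."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def geometric_center(coords: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of an N×3 coordinate array, Å."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[None, :]
    if coords.shape[0] == 0:
        raise GeometryError("geometric center of an empty point set")
    return coords.mean(axis=0)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unaligned) root-mean-square deviation between matched point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError(f"point-set shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def _check_nondegenerate(centered: np.ndarray, which: str) -> None:
    # collinear or coincident point sets leave the rotation underdetermined
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[1] < 1e-8 * scale:
        raise GeometryError(f"{which} point set is degenerate (collinear or coincident)")


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-RMSD proper rigid superposition of ``mobile`` onto ``target``.

    Kabsch algorithm: correspondence is by index, rotations only (the
    reflection branch of the SVD solution is explicitly excluded).  Returns
    the optimal transform and the minimized RMSD in Å.

    Raises :class:`GeometryError` for fewer than 3 points or for degenerate
    (collinear/coincident) point sets, where the rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("superpose expects matched N×3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superpose needs at least 3 points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    m = mobile - mc
    t = target - tc
    _check_nondegenerate(m, "mobile")
    _check_nondegenerate(t, "target")
    H = m.T @ t
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    transform = RigidTransform(R, tc - R @ mc)
    value = rmsd(m @ R.T, t)
    return transform, value


def rmsd_after_alignment(mobile: np.ndarray, reference: np.ndarray,
                         align_mobile: np.ndarray, align_reference: np.ndarray,
                         measure_mobile: np.ndarray,
                         measure_reference: np.ndarray) -> float:
    """RMSD over a measured selection after fitting on an alignment selection.

    ``mobile``/``reference`` are full N×3 / M×3 coordinate arrays;
    ``align_*`` and ``measure_*`` are index arrays into each.  The transform
    fitted on the alignment atoms is applied to the measured atoms of the
    mobile set; RMSD is computed over the measured atoms only.
    """
    align_mobile = np.asarray(align_mobile, dtype=int)
    align_reference = np.asarray(align_reference, dtype=int)
    measure_mobile = np.asarray(measure_mobile, dtype=int)
    measure_reference = np.asarray(measure_reference, dtype=int)
    if align_mobile.size != align_reference.size:
        raise GeometryError(
            f"alignment selections differ in size: {align_mobile.size} vs "
            f"{align_reference.size}")
    if measure_mobile.size != measure_reference.size:
        raise GeometryError(
            f"measured selections differ in size: {measure_mobile.size} vs "
            f"{measure_reference.size}")
    transform, _ = superpose(np.asarray(mobile)[align_mobile],
                             np.asarray(reference)[align_reference])
    moved = transform.apply(np.asarray(mobile)[measure_mobile])
    return rmsd(moved, np.asarray(reference)[measure_reference])


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two 3-vectors in degrees, in [0, 180].

    Computed as atan2(‖u×v‖, u·v) — identical to the arccos of the clamped
    normalized dot product but numerically stable near 0° and 180°.
    Zero-length vectors (norm ≤ 1e-9) are an error.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.linalg.norm(u) <= 1e-9 or np.linalg.norm(v) <= 1e-9:
        raise GeometryError("vector_angle of a zero-length vector")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)),
                                       np.dot(u, v))))


def project_along(point: np.ndarray, origin: np.ndarray, axis: np.ndarray) -> float:
    """Signed scalar projection of (point − origin) on ``axis``, Å.

    The axis is normalized here; a zero axis is an error.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n <= 1e-9:
        raise GeometryError("projection axis has zero length")
    return float(np.dot(np.asarray(point, dtype=float) - np.asarray(origin, dtype=float),
                        axis / n))
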