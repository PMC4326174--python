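r"""Group–group nonbond interaction energies with a smooth 10–12 Å cutoff.

The interaction energy between two disjoint atom groups (receptor vs ligand,
or two adjacent domains across a hinge) is the sum over all inter-group atom
pairs of a switched Lennard-Jones term and a switched Coulomb term:

.. math::

    E_{vdW}(r)  &= S(r)\,\varepsilon_{ij}\left[(R_{min,ij}/r)^{12}
                   - 2 (R_{min,ij}/r)^{6}\right] \\
    E_{elec}(r) &= S(r)\, C\, q_i q_j / r,\qquad C = 332.0636
                   \ \mathrm{kcal\,Å\,mol^{-1}\,e^{-2}}

with Lorentz–Berthelot combination (:math:`\\varepsilon_{ij} =
\\sqrt{\\varepsilon_i\\varepsilon_j}`, :math:`R_{min,ij} = R_{min,i}/2 +
R_{min,j}/2`) and the standard C¹ switching polynomial

.. math::

    S(r) = \\frac{(r_{off}^2-r^2)^2\\,(r_{off}^2+2r^2-3r_{on}^2)}
                 {(r_{off}^2-r_{on}^2)^3}

equal to 1 at and below :math:`r_{on}` = 10 Å and 0 at and beyond
:math:`r_{off}` = 12 Å.  A uniform dielectric of 1 is assumed.  This is a
post-analysis convention: only pairwise minimum-image-free sums, no Ewald
reciprocal terms, no intra-group exclusions (groups are disjoint by
contract, so 1-2/1-3/1-4 exclusions never arise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import (NonbondParamTable, Selection, StructureError, Trajectory,
                       resolve_selection)

__all__ = [
    "COULOMB_KCAL_A_PER_E2",
    "CutoffScheme",
    "EnergyProfile",
    "switching",
    "pair_energy",
    "group_energy_series",
    "hinge_energy_table",
]

#: Coulomb constant in kcal·Å/(mol·e²), uniform dielectric of 1.
COULOMB_KCAL_A_PER_E2 = 332.0636


@dataclass(frozen=True)
class CutoffScheme:
    """Switching window: full strength at ≤ r_on, zero at ≥ r_off (Å)."""

    r_on: float = 10.0
    r_off: float = 12.0

    def __post_init__(self) -> None:
        if not (0 < self.r_on < self.r_off):
            raise ValueError(f"need 0 < r_on < r_off, got ({self.r_on}, {self.r_off})")


def switching(r: np.ndarray | float, scheme: CutoffScheme = CutoffScheme()) -> np.ndarray | float:
    """C¹ switching factor in [0, 1]; accepts scalars or arrays of distances (Å)."""
    r = np.asarray(r, dtype=float)
    r2 = r * r
    on2 = scheme.r_on ** 2
    off2 = scheme.r_off ** 2
    s = (off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2) / (off2 - on2) ** 3
    out = np.where(r2 <= on2, 1.0, np.where(r2 >= off2, 0.0, s))
    return float(out) if out.ndim == 0 else out


@dataclass
class EnergyProfile:
    """Per-frame interaction-energy series, kcal/mol; total = vdw + elec."""

    times: np.ndarray  # ns
    vdw: np.ndarray
    elec: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vdw = np.asarray(self.vdw, dtype=float)
        self.elec = np.asarray(self.elec, dtype=float)
        if not (self.times.shape == self.vdw.shape == self.elec.shape):
            raise ValueError("times, vdw and elec must have equal lengths")

    @property
    def total(self) -> np.ndarray:
        return self.vdw + self.elec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ns": self.times,
            "vdw_kcal": self.vdw,
            "elec_kcal": self.elec,
            "total_kcal": self.total,
        })


def pair_energy(ri: np.ndarray, rj: np.ndarray,
                pi: tuple[float, float, float], pj: tuple[float, float, float],
                scheme: CutoffScheme = CutoffScheme(),
                switch_elec: bool = True) -> tuple[float, float]:
    """(vdw, elec) for one atom pair, kcal/mol.

    ``pi``/``pj`` are (charge_e, epsilon_kcal, rmin_half_A).  Coincident
    atoms (r < 1e-6 Å) are an error; both terms are exactly 0 at r ≥ r_off.
    """
    r = float(np.linalg.norm(np.asarray(ri, dtype=float) - np.asarray(rj, dtype=float)))
    if r < 1e-6:
        raise ValueError("coincident atoms in pair_energy")
    qi, ei, rhi = pi
    qj, ej, rhj = pj
    if r >= scheme.r_off:
        return 0.0, 0.0
    s = switching(r, scheme)
    eps = np.sqrt(ei * ej)
    rmin = rhi + rhj
    ratio6 = (rmin / r) ** 6
    vdw = s * eps * (ratio6 * ratio6 - 2.0 * ratio6)
    elec = COULOMB_KCAL_A_PER_E2 * qi * qj / r
    elec *= s if switch_elec else 1.0
    return float(vdw), float(elec)


def _group_frame_energy(coords_a: np.ndarray, coords_b: np.ndarray,
                        qa: np.ndarray, ea: np.ndarray, rha: np.ndarray,
                        qb: np.ndarray, eb: np.ndarray, rhb: np.ndarray,
                        scheme: CutoffScheme, switch_elec: bool) -> tuple[float, float]:
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    if np.any(r < 1e-6):
        raise ValueError("coincident atoms between interacting groups")
    inside = r < scheme.r_off
    s = np.where(inside, switching(r, scheme), 0.0)
    eps = np.sqrt(np.outer(ea, eb))
    rmin = rha[:, None] + rhb[None, :]
    with np.errstate(over="ignore"):
        ratio6 = np.where(inside, (rmin / np.where(inside, r, 1.0)) ** 6, 0.0)
    vdw = float(np.sum(s * eps * (ratio6 * ratio6 - 2.0 * ratio6)))
    qq = COULOMB_KCAL_A_PER_E2 * np.outer(qa, qb)
    elec_raw = np.where(inside, qq / np.where(inside, r, 1.0), 0.0)
    elec = float(np.sum((s if switch_elec else inside.astype(float)) * elec_raw))
    return vdw, elec


def group_energy_series(traj: Trajectory, group_a: Selection | str,
                        group_b: Selection | str, params: NonbondParamTable,
                        scheme: CutoffScheme = CutoffScheme(),
                        switch_elec: bool = True) -> EnergyProfile:
    """Per-frame A×B interaction energy (no intra-group terms, no images).

    Groups must be disjoint and fully covered by the parameter table.
    Symmetric in its group arguments and additive over disjoint splits of
    either group.
    """
    ia = resolve_selection(group_a, traj.topology)
    ib = resolve_selection(group_b, traj.topology)
    if set(ia.tolist()) & set(ib.tolist()):
        raise StructureError("interacting groups overlap")
    if ia[0] > ib[0]:
        ia, ib = ib, ia  # canonical order: E(A,B) and E(B,A) sum identically
    qa, ea, rha = params.resolve(traj.topology, ia)
    qb, eb, rhb = params.resolve(traj.topology, ib)
    vdw = np.empty(len(traj))
    elec = np.empty(len(traj))
    for k, frame in enumerate(traj.frames):
        vdw[k], elec[k] = _group_frame_energy(
            frame[ia], frame[ib], qa, ea, rha, qb, eb, rhb, scheme, switch_elec)
    return EnergyProfile(traj.times.copy(), vdw, elec)


def hinge_energy_table(trajs: list[Trajectory], domain_sels: list[Selection | str],
                       params: NonbondParamTable,
                       scheme: CutoffScheme = CutoffScheme(),
                       domain_names: list[str] | None = None) -> pd.DataFrame:
    """Mean ± SD of adjacent-domain interaction energies across trajectories.

    Two-stage averaging: the total interaction energy of each adjacent domain
    pair is time-averaged within each trajectory first, then the mean and
    sample SD are taken across trajectories.  With a single trajectory the SD
    is reported as NaN (absent).
    """
    if len(domain_sels) < 2:
        raise ValueError("need at least two domains")
    if not trajs:
        raise ValueError("need at least one trajectory")
    if domain_names is None:
        domain_names = [f"domain{i + 1}" for i in range(len(domain_sels))]
    rows = []
    for i in range(len(domain_sels) - 1):
        per_traj = [
            float(np.mean(group_energy_series(t, domain_sels[i], domain_sels[i + 1],
                                              params, scheme).total))
            for t in trajs
        ]
        rows.append({
            "pair": f"{domain_names[i]}-{domain_names[i + 1]}",
            "n_traj": len(per_traj),
            "mean_kcal": float(np.mean(per_traj)),
            "sd_kcal": float(np.std(per_traj, ddof=1)) if len(per_traj) > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("pair")
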