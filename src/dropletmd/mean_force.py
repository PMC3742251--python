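"""Mean-force decomposition on a tagged fixed solute.

The net mean force on solute S₂ splits exactly into the external-field term
F^E = Q₂E, the direct solute–solute term F^S1 (Coulomb + LJ at the fixed
separation), and the frame-averaged solvent term F^solv (Coulomb + LJ over
all water atoms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Trajectory
from .model import COULOMB_K, FieldSpec, Solute, combine_lj, field_force

__all__ = ["ForceDecomposition", "solute_pair_force", "solvent_force", "decompose"]


@dataclass(frozen=True)
class ForceDecomposition:
    """Time-averaged force components on the tagged solute, kcal/(mol·Å)."""

    f_e: np.ndarray
    f_s1_ele: np.ndarray
    f_s1_vdw: np.ndarray
    f_solv_ele: np.ndarray
    f_solv_vdw: np.ndarray
    n_frames: int
    sem: np.ndarray  # per-component standard error of the solvent mean

    @property
    def f_net(self) -> np.ndarray:
        """Exact identity: sum of all components."""
        return (self.f_e + self.f_s1_ele + self.f_s1_vdw
                + self.f_solv_ele + self.f_solv_vdw)

    @property
    def f_solv(self) -> np.ndarray:
        return self.f_solv_ele + self.f_solv_vdw

    @property
    def f_s1(self) -> np.ndarray:
        return self.f_s1_ele + self.f_s1_vdw

    def component(self, axis: int | str) -> float:
        idx = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
        return float(self.f_net[idx])


def solute_pair_force(s1: Solute, s2: Solute) -> tuple[np.ndarray, np.ndarray]:
    """Direct force on S₂ from S₁: (electrostatic, van der Waals) vectors.

    Coulomb: k·Q₁Q₂·R̂/R² along R₁₂ = r₂ − r₁.
    LJ: (12ε₁₂/R)[(Rmin,12/R)¹² − (Rmin,12/R)⁶]·R̂, with combining-rule pair
    parameters.
    """
    r12 = s2.position_array - s1.position_array
    r = float(np.linalg.norm(r12))
    if r < 1e-12:
        raise ValueError("solutes are coincident")
    rhat = r12 / r
    f_ele = COULOMB_K * s1.charge * s2.charge / r**2 * rhat
    eps12, rmin12 = combine_lj(s1.eps, s1.rmin2, s2.eps, s2.rmin2)
    s6 = (rmin12 / r) ** 6
    f_vdw = 12.0 * eps12 / r * (s6 * s6 - s6) * rhat
    return f_ele, f_vdw


def solvent_force(traj: Trajectory, s2: Solute
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-averaged solvent force on S₂: (F_ele, F_vdw, per-frame series).

    Sums over all water atoms with combining-rule LJ parameters; the
    per-frame net-solvent series (n_frames, 3) is returned for error bars.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no production frames")
    cl = traj.cluster
    n_wa = cl.n_water_atoms
    if n_wa == 0:
        z = np.zeros(3)
        return z, z, np.zeros((traj.n_frames, 3))
    q = cl.charges()[:n_wa]
    eps, rmin2 = cl.lj_params()
    eps, rmin2 = eps[:n_wa], rmin2[:n_wa]
    eps_2j = np.sqrt(eps * s2.eps)
    rmin_2j = rmin2 + s2.rmin2

    rvec = s2.position_array[None, None, :] - traj.frames[:, :n_wa]  # to S2
    r2 = np.einsum("fij,fij->fi", rvec, rvec)
    inv_r = 1.0 / np.sqrt(r2)
    inv_r2 = inv_r * inv_r
    c_ele = COULOMB_K * s2.charge * q[None, :] * inv_r2 * inv_r
    s6 = (rmin_2j[None, :] ** 2 * inv_r2) ** 3
    c_vdw = 12.0 * eps_2j[None, :] * (s6 * s6 - s6) * inv_r2
    f_ele_frames = np.einsum("fi,fij->fj", c_ele, rvec)
    f_vdw_frames = np.einsum("fi,fij->fj", c_vdw, rvec)
    series = f_ele_frames + f_vdw_frames
    return f_ele_frames.mean(axis=0), f_vdw_frames.mean(axis=0), series


def _block_sem(series: np.ndarray, times: np.ndarray, block_ps: float = 5.0
               ) -> np.ndarray:
    """Standard error of the mean per component via block averaging."""
    n = series.shape[0]
    if n < 2:
        return np.full(3, np.nan)
    span = times[-1] - times[0] if n > 1 else 0.0
    n_blocks = max(int(span / block_ps), 2) if span > 0 else 2
    n_blocks = min(n_blocks, n)
    blocks = np.array_split(series, n_blocks, axis=0)
    means = np.array([b.mean(axis=0) for b in blocks])
    return means.std(axis=0, ddof=1) / np.sqrt(n_blocks)


def decompose(traj: Trajectory, s2: Solute, s1: Solute | None = None,
              fieldspec: FieldSpec | None = None, block_ps: float = 5.0
              ) -> ForceDecomposition:
    """Assemble the full mean-force decomposition on S₂.

    One-solute systems pass ``s1=None`` (the direct term is zero).  The field
    defaults to the trajectory's own field.
    """
    fieldspec = traj.fieldspec if fieldspec is None else fieldspec
    f_e = field_force(s2.charge, fieldspec)
    if s1 is not None:
        f_s1_ele, f_s1_vdw = solute_pair_force(s1, s2)
    else:
        f_s1_ele = np.zeros(3)
        f_s1_vdw = np.zeros(3)
    f_solv_ele, f_solv_vdw, series = solvent_force(traj, s2)
    sem = _block_sem(series, traj.times, block_ps)
    return ForceDecomposition(
        f_e=f_e,
        f_s1_ele=f_s1_ele,
        f_s1_vdw=f_s1_vdw,
        f_solv_ele=f_solv_ele,
        f_solv_vdw=f_solv_vdw,
        n_frames=traj.n_frames,
        sem=sem,
    )
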