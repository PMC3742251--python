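"""NVE rigid-TIP3P droplet dynamics with a uniform external field.

Protocol per run: steepest-descent minimization, equilibration with periodic
velocity rescaling to the target temperature, then strictly NVE production
(leapfrog Verlet + SHAKE, 2 fs step), saving frames every 20 fs.  Solutes are
held rigidly fixed throughout; a half-harmonic restraint at the droplet
radius keeps water oxygens from evaporating (droplet, never periodic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .cluster import WaterCluster, init_velocities
from .kernels import (
    pair_forces_fast,
    pair_forces_ref,
    shake_waters,
    subtract_intra,
)
from .model import COULOMB_K, KB, KCAL_TO_AMU_A2_PS2, FieldSpec

__all__ = ["EngineConfig", "Trajectory", "compute_forces", "boundary_force",
           "shake", "minimize", "run"]


@dataclass(frozen=True)
class EngineConfig:
    """Integration and schedule parameters.

    ``cutoff`` is honored literally: at 99 Å every pair in a ≤25 Å droplet
    interacts, so the kernels simply take all pairs (no switching function).
    ``precision`` selects the nonbonded path used *inside the integrator*;
    'double' is exact reference arithmetic, 'mixed' evaluates the pairwise
    sweep in float32 (positions, constraints, velocities stay float64).
    """

    dt: float = 0.002  # ps
    cutoff: float = 99.0  # Å; effectively no cutoff for droplets
    shake_tol: float = 1e-8
    shake_maxiter: int = 500
    boundary_k: float = 2.0  # kcal/(mol·Å²)
    save_interval: int = 10  # steps between saved frames (10 → 20 fs)
    min_steps: int = 200
    equil_time: float = 10.0  # ps
    prod_time: float = 50.0  # ps
    temperature: float = 300.0  # K
    rescale_interval: int = 50  # equilibration rescale interval, steps (0.1 ps)
    log_interval: int = 100  # energy-log interval, steps (0.2 ps)
    precision: Literal["mixed", "double"] = "mixed"
    blowup_temperature: float = 2000.0  # K; abort threshold

    @classmethod
    def desk(cls, **overrides) -> "EngineConfig":
        """Desk-scale profile: 12 Å droplets, 10 ps equilibration, 50 ps
        production (≈240 waters)."""
        return cls(**overrides)

    @classmethod
    def full(cls, **overrides) -> "EngineConfig":
        """Full-scale profile: 1000-step minimization, 200 ps equilibration,
        1 ns production."""
        defaults = dict(min_steps=1000, equil_time=200.0, prod_time=1000.0)
        defaults.update(overrides)
        return cls(**defaults)

    def replace(self, **kw) -> "EngineConfig":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Saved production frames (coordinates in Å) plus run metadata.

    ``cluster`` is the system template (defines charges, LJ parameters,
    molecule layout); solute coordinates are identical in every frame.
    """

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # ps, relative to start of production
    cluster: WaterCluster
    fieldspec: FieldSpec
    seed: int | None = None
    config: EngineConfig | None = None
    energy_log: pd.DataFrame | None = None

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_waters(self) -> int:
        return self.cluster.n_waters


def boundary_force(cluster: WaterCluster, k: float = 2.0,
                   coords: np.ndarray | None = None
                   ) -> tuple[np.ndarray, float]:
    """Half-harmonic restraint on water oxygens outside the droplet radius.

    Returns (per-atom forces, energy).  U = ½k(r−R)² for r > R, zero inside;
    never applied to hydrogens or solutes.
    """
    pos = cluster.coords if coords is None else coords
    forces = np.zeros_like(pos)
    o_idx = np.arange(0, cluster.n_water_atoms, 3)
    ox = pos[o_idx]
    r = np.linalg.norm(ox, axis=1)
    out = r > cluster.radius
    energy = 0.0
    if np.any(out):
        over = r[out] - cluster.radius
        unit = ox[out] / r[out, None]
        forces[o_idx[out]] = -k * over[:, None] * unit
        energy = 0.5 * k * float(np.sum(over**2))
    return forces, energy


def compute_forces(cluster: WaterCluster, fieldspec: FieldSpec | None = None,
                   config: EngineConfig | None = None,
                   coords: np.ndarray | None = None
                   ) -> tuple[np.ndarray, dict[str, float]]:
    """Reference double-precision forces and energy terms.

    All-pairs Coulomb and LJ between atoms of distinct molecules, plus the
    uniform external field on every charged atom, plus the droplet boundary
    restraint.  Intramolecular nonbonded terms are excluded (rigid waters).
    """
    config = config or EngineConfig()
    pos = np.ascontiguousarray(cluster.coords if coords is None else coords)
    if pos.shape != (cluster.n_atoms, 3):
        raise ValueError("coordinate array shape mismatch")
    q = cluster.charges()
    eps, rmin2 = cluster.lj_params()
    mol = cluster.mol_ids()

    # hard-floor overlap guard
    forces = np.zeros_like(pos)
    e_c, e_lj = pair_forces_ref(pos, q, eps, rmin2, mol, COULOMB_K, forces)
    if not np.isfinite(forces).all():
        raise FloatingPointError("non-finite forces: overlapping atoms?")
    _check_overlap(pos, mol)

    energies = {"coulomb": float(e_c), "lj": float(e_lj)}

    fb, eb = boundary_force(cluster, config.boundary_k, coords=pos)
    forces += fb
    energies["boundary"] = eb

    if fieldspec is not None and fieldspec.magnitude > 0.0:
        evec = fieldspec.vector_kcal
        forces += q[:, None] * evec
        energies["field"] = float(-np.sum(q * (pos @ evec)))
    else:
        energies["field"] = 0.0

    energies["potential"] = sum(
        energies[k] for k in ("coulomb", "lj", "boundary", "field")
    )
    return forces, energies


def _check_overlap(pos: np.ndarray, mol: np.ndarray, floor: float = 0.1) -> None:
    """Reject configurations with contacts below ``floor`` Å.

    Intramolecular distances in a rigid water are ≥ 0.9572 Å, so any pair
    below the floor is a genuine overlap.
    """
    from scipy.spatial import cKDTree

    pairs = cKDTree(pos).query_pairs(floor, output_type="ndarray")
    if len(pairs):
        i, j = pairs[0]
        r = float(np.linalg.norm(pos[i] - pos[j]))
        raise ValueError(f"atoms {i} and {j} overlap: R = {r:.4f} Å < {floor} Å")


def shake(pos: np.ndarray, ref: np.ndarray, cluster: WaterCluster,
          tol: float = 1e-8, max_iter: int = 500) -> int:
    """Apply SHAKE to the water constraints in place; returns iterations used.

    Constraints per water: two O–H bonds at the model bond length and the
    H–H distance implied by the rigid angle.
    """
    m = cluster.model
    inv_mass = 1.0 / cluster.masses()[: cluster.n_water_atoms]
    it = shake_waters(
        pos[: cluster.n_water_atoms],
        ref[: cluster.n_water_atoms],
        inv_mass,
        cluster.n_waters,
        m.bond_oh**2,
        m.hh_distance**2,
        tol,
        max_iter,
    )
    if it < 0:
        raise RuntimeError(
            f"SHAKE failed to converge within {max_iter} iterations "
            "(unstable dynamics)"
        )
    return it


class _FastForceField:
    """Mixed-precision force evaluator used inside the integrator loop."""

    def __init__(self, cluster: WaterCluster, fieldspec: FieldSpec,
                 config: EngineConfig):
        self.cluster = cluster
        self.config = config
        self.q = cluster.charges()
        self.eps, self.rmin2 = cluster.lj_params()
        self.mol = cluster.mol_ids()
        self.q32 = self.q.astype(np.float32)
        self.eps32 = self.eps.astype(np.float32)
        self.rmin232 = self.rmin2.astype(np.float32)
        n_w = cluster.n_waters
        base = 3 * np.arange(n_w, dtype=np.int64)
        self.pair_i = np.concatenate([base, base, base + 1])
        self.pair_j = np.concatenate([base + 1, base + 2, base + 2])
        n = cluster.n_atoms
        self._fx = np.empty(n, np.float32)
        self._fy = np.empty(n, np.float32)
        self._fz = np.empty(n, np.float32)
        self.evec = (fieldspec.vector_kcal
                     if fieldspec is not None else np.zeros(3))
        self.has_field = bool(np.any(self.evec != 0.0))
        self.field_forces = self.q[:, None] * self.evec

    def forces(self, pos: np.ndarray) -> np.ndarray:
        if self.config.precision == "double":
            f = np.zeros_like(pos)
            pair_forces_ref(pos, self.q, self.eps, self.rmin2, self.mol,
                            COULOMB_K, f)
        else:
            px = pos[:, 0].astype(np.float32)
            py = pos[:, 1].astype(np.float32)
            pz = pos[:, 2].astype(np.float32)
            pair_forces_fast(px, py, pz, self.q32, self.eps32, self.rmin232,
                             np.float32(COULOMB_K), self._fx, self._fy, self._fz)
            subtract_intra(px, py, pz, self.q32, self.eps32, self.rmin232,
                           self.pair_i, self.pair_j, np.float32(COULOMB_K),
                           self._fx, self._fy, self._fz)
            f = np.stack([self._fx, self._fy, self._fz], axis=1).astype(np.float64)
        fb, _ = boundary_force(self.cluster, self.config.boundary_k, coords=pos)
        f += fb
        if self.has_field:
            f += self.field_forces
        return f


def minimize(cluster: WaterCluster, fieldspec: FieldSpec | None = None,
             config: EngineConfig | None = None) -> WaterCluster:
    """Steepest-descent minimization with adaptive step, constraints kept
    rigid by SHAKE after every move; solutes never move."""
    config = config or EngineConfig()
    cl = cluster.copy()
    n_wa = cl.n_water_atoms
    pos = cl.coords
    if n_wa == 0:
        return cl  # nothing movable (vacuum control)
    step = 0.01  # Å, max displacement per move
    _, energies = compute_forces(cl, fieldspec, config)
    e_prev = energies["potential"]
    for _ in range(config.min_steps):
        f, _ = compute_forces(cl, fieldspec, config)
        fmax = float(np.abs(f[:n_wa]).max())
        if fmax < 1e-8:
            break
        trial = pos.copy()
        trial[:n_wa] += (step / fmax) * f[:n_wa]
        shake(trial, pos, cl, config.shake_tol, config.shake_maxiter)
        _, e_new = compute_forces(cl, fieldspec, config, coords=trial)
        if e_new["potential"] < e_prev:
            pos[:] = trial
            e_prev = e_new["potential"]
            step = min(step * 1.2, 0.2)
        else:
            step *= 0.5
            if step < 1e-7:
                break
    cl.velocities = None
    return cl


def _kinetic_energy(vel: np.ndarray, mass: np.ndarray, n_wa: int) -> float:
    return 0.5 * float(np.sum(mass[:n_wa, None] * vel[:n_wa] ** 2)) \
        / KCAL_TO_AMU_A2_PS2


def run(cluster: WaterCluster, fieldspec: FieldSpec | None = None,
        config: EngineConfig | None = None, seed: int = 0) -> Trajectory:
    """Minimize, equilibrate (velocity rescaling to the target temperature),
    then NVE production; returns the production trajectory.

    Frames are recorded every ``save_interval`` steps of production.  Fixed
    solutes keep their exact input coordinates in every frame.
    """
    config = config or EngineConfig()
    fieldspec = fieldspec or FieldSpec.zero()
    if 2.0 * cluster.radius > config.cutoff:
        raise ValueError("droplet diameter exceeds the nonbond cutoff")

    cl = minimize(cluster, fieldspec, config)
    init_velocities(cl, config.temperature, seed)

    ff = _FastForceField(cl, fieldspec, config)
    pos = cl.coords
    vel = cl.velocities
    mass = cl.masses()
    n_wa = cl.n_water_atoms
    inv_m_dt = (config.dt * KCAL_TO_AMU_A2_PS2 / mass[:n_wa])[:, None]
    dof = 6 * cl.n_waters
    dt = config.dt

    n_equil = int(round(config.equil_time / dt))
    n_prod = int(round(config.prod_time / dt))
    n_frames = n_prod // config.save_interval
    frames = np.empty((n_frames, cl.n_atoms, 3))
    times = np.empty(n_frames)
    log_rows: list[tuple] = []

    def step_once() -> None:
        f = ff.forces(pos)
        vel[:n_wa] += f[:n_wa] * inv_m_dt
        ref = pos.copy()
        pos[:n_wa] += dt * vel[:n_wa]
        shake(pos, ref, cl, config.shake_tol, config.shake_maxiter)
        vel[:n_wa] = (pos[:n_wa] - ref[:n_wa]) / dt

    def check_stability(stage: str, istep: int) -> float:
        ke = _kinetic_energy(vel, mass, n_wa)
        t_inst = 2.0 * ke / (dof * KB) if dof else 0.0
        if not math.isfinite(t_inst) or t_inst > config.blowup_temperature:
            raise RuntimeError(
                f"energy blow-up during {stage} at step {istep}: "
                f"T = {t_inst:.1f} K (seed={seed}, radius={cl.radius}, "
                f"field={fieldspec.magnitude} MV/cm)"
            )
        return t_inst

    # --- equilibration with periodic velocity rescaling ---
    for istep in range(n_equil):
        step_once()
        if (istep + 1) % config.rescale_interval == 0 and dof:
            t_inst = check_stability("equilibration", istep)
            if t_inst > 0:
                vel[:n_wa] *= math.sqrt(config.temperature / t_inst)

    # --- NVE production ---
    iframe = 0
    for istep in range(n_prod):
        step_once()
        if (istep + 1) % config.save_interval == 0 and iframe < n_frames:
            frames[iframe] = pos
            times[iframe] = (istep + 1) * dt
            iframe += 1
        if (istep + 1) % config.log_interval == 0:
            t_inst = check_stability("production", istep)
            ke = _kinetic_energy(vel, mass, n_wa)
            _, en = compute_forces(cl, fieldspec, config, coords=pos)
            log_rows.append(
                ((istep + 1) * dt, ke, en["potential"], ke + en["potential"],
                 t_inst, en["coulomb"], en["lj"], en["boundary"], en["field"])
            )

    log = pd.DataFrame(
        log_rows,
        columns=["time_ps", "kinetic", "potential", "total", "temperature",
                 "coulomb", "lj", "boundary", "field"],
    )
    return Trajectory(
        frames=frames[:iframe],
        times=times[:iframe],
        cluster=cl,
        fieldspec=fieldspec,
        seed=seed,
        config=config,
        energy_log=log,
    )
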