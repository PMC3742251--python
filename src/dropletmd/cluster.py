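"""Droplet construction: spherical TIP3P clusters with optional fixed solutes.

Waters are inserted by seeded random placement with overlap rejection, at the
liquid number density that reproduces the molecule counts of the reference
systems (1119 waters in a 20 Å droplet, 2185 in a 25 Å droplet holding one
solute).  One water is removed per solute (substitution, not addition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (
    KB,
    KCAL_TO_AMU_A2_PS2,
    TIP3P,
    Solute,
    WaterModel,
    combine_lj,
)

#: Liquid water number density used for droplet filling, Å⁻³.
WATER_NUMBER_DENSITY = 0.0334

#: Hard minimum O–O distance accepted during insertion, Å.
MIN_OO_DISTANCE = 2.4

#: A water oxygen must stay at least this fraction of the combined Rmin away
#: from any solute during insertion.
SOLUTE_EXCLUSION_SCALE = 0.85


@dataclass
class WaterCluster:
    """Particle system: n_waters rigid waters (atoms ordered O, H, H per
    molecule) followed by fixed solutes, inside a droplet of given radius.

    ``coords`` has shape (3·n_waters + n_solutes, 3) in Å; ``velocities`` is
    None until initialized (Å/ps).
    """

    radius: float
    n_waters: int
    coords: np.ndarray
    solutes: tuple[Solute, ...] = ()
    model: WaterModel = TIP3P
    velocities: np.ndarray | None = None

    @property
    def n_water_atoms(self) -> int:
        return 3 * self.n_waters

    @property
    def n_atoms(self) -> int:
        return self.n_water_atoms + len(self.solutes)

    @property
    def water_coords(self) -> np.ndarray:
        """View of water atom coordinates with shape (n_waters, 3, 3)."""
        return self.coords[: self.n_water_atoms].reshape(self.n_waters, 3, 3)

    @property
    def oxygen_coords(self) -> np.ndarray:
        return self.coords[0 : self.n_water_atoms : 3]

    def charges(self) -> np.ndarray:
        q = np.empty(self.n_atoms)
        q[0 : self.n_water_atoms : 3] = self.model.q_o
        q[1 : self.n_water_atoms : 3] = self.model.q_h
        q[2 : self.n_water_atoms : 3] = self.model.q_h
        for k, s in enumerate(self.solutes):
            q[self.n_water_atoms + k] = s.charge
        return q

    def lj_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-atom (ε, Rmin/2) arrays; pair parameters follow the standard
        combining rules."""
        eps = np.empty(self.n_atoms)
        rmin2 = np.empty(self.n_atoms)
        m = self.model
        eps[0 : self.n_water_atoms : 3] = m.eps_o
        eps[1 : self.n_water_atoms : 3] = m.eps_h
        eps[2 : self.n_water_atoms : 3] = m.eps_h
        rmin2[0 : self.n_water_atoms : 3] = m.rmin2_o
        rmin2[1 : self.n_water_atoms : 3] = m.rmin2_h
        rmin2[2 : self.n_water_atoms : 3] = m.rmin2_h
        for k, s in enumerate(self.solutes):
            eps[self.n_water_atoms + k] = s.eps
            rmin2[self.n_water_atoms + k] = s.rmin2
        return eps, rmin2

    def masses(self) -> np.ndarray:
        mass = np.empty(self.n_atoms)
        mass[0 : self.n_water_atoms : 3] = self.model.mass_o
        mass[1 : self.n_water_atoms : 3] = self.model.mass_h
        mass[2 : self.n_water_atoms : 3] = self.model.mass_h
        mass[self.n_water_atoms :] = self.model.mass_o  # inert: solutes are fixed
        return mass

    def mol_ids(self) -> np.ndarray:
        """Molecule index per atom; each solute is its own molecule."""
        ids = np.empty(self.n_atoms, dtype=np.int64)
        ids[: self.n_water_atoms] = np.repeat(np.arange(self.n_waters), 3)
        ids[self.n_water_atoms :] = self.n_waters + np.arange(len(self.solutes))
        return ids

    def movable(self) -> np.ndarray:
        """True for atoms the integrator propagates (all water atoms)."""
        mov = np.zeros(self.n_atoms, dtype=bool)
        mov[: self.n_water_atoms] = True
        return mov

    def copy(self) -> "WaterCluster":
        return WaterCluster(
            radius=self.radius,
            n_waters=self.n_waters,
            coords=self.coords.copy(),
            solutes=self.solutes,
            model=self.model,
            velocities=None if self.velocities is None else self.velocities.copy(),
        )


def target_count(radius: float, n_solutes: int = 0) -> int:
    """Number of waters filling a droplet of the given radius at liquid
    density, after substituting one water per solute."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    n = round((4.0 / 3.0) * math.pi * radius**3 * WATER_NUMBER_DENSITY) - n_solutes
    return max(n, 0)


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform random rotation matrices via normalized quaternions."""
    quat = rng.normal(size=(n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    w, x, y, z = quat.T
    mats = np.empty((n, 3, 3))
    mats[:, 0, 0] = 1 - 2 * (y * y + z * z)
    mats[:, 0, 1] = 2 * (x * y - z * w)
    mats[:, 0, 2] = 2 * (x * z + y * w)
    mats[:, 1, 0] = 2 * (x * y + z * w)
    mats[:, 1, 1] = 1 - 2 * (x * x + z * z)
    mats[:, 1, 2] = 2 * (y * z - x * w)
    mats[:, 2, 0] = 2 * (x * z - y * w)
    mats[:, 2, 1] = 2 * (y * z + x * w)
    mats[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return mats


def build_cluster(
    radius: float,
    solutes: Sequence[Solute] = (),
    seed: int = 0,
    model: WaterModel = TIP3P,
    max_tries_per_water: int = 2000,
    n_waters: int | None = None,
) -> WaterCluster:
    """Construct a droplet: seeded random insertion with overlap rejection.

    Oxygens are placed uniformly in the sphere subject to a minimum O–O
    distance and a solute exclusion zone; each water then gets the rigid
    TIP3P internal geometry at a uniformly random orientation.  The result
    is deterministic for a given seed.  ``n_waters`` overrides the
    density-implied count (0 gives a vacuum control system).
    """
    solutes = tuple(solutes)
    for s in solutes:
        if np.linalg.norm(s.position_array) > radius:
            raise ValueError(f"solute at {s.position} lies outside radius {radius}")
    n = target_count(radius, len(solutes)) if n_waters is None else int(n_waters)

    rng = np.random.default_rng(seed)
    solute_pos = np.array([s.position_array for s in solutes]).reshape(len(solutes), 3)
    solute_excl = np.array(
        [SOLUTE_EXCLUSION_SCALE * combine_lj(model.eps_o, model.rmin2_o, s.eps, s.rmin2)[1]
         for s in solutes]
    )

    oxygens = np.empty((n, 3))
    placed = 0
    budget = max_tries_per_water * max(n, 1)
    tries = 0
    while placed < n:
        if tries >= budget:
            raise RuntimeError(
                f"placed only {placed}/{n} waters after {tries} attempts "
                f"(radius={radius} Å, density={WATER_NUMBER_DENSITY} Å⁻³); "
                "the requested density appears infeasible"
            )
        tries += 1
        # uniform point in the sphere
        pt = rng.uniform(-radius, radius, size=3)
        r = np.linalg.norm(pt)
        if r > radius:
            continue
        if placed and np.min(np.linalg.norm(oxygens[:placed] - pt, axis=1)) < MIN_OO_DISTANCE:
            continue
        if len(solutes) and np.any(np.linalg.norm(solute_pos - pt, axis=1) < solute_excl):
            continue
        oxygens[placed] = pt
        placed += 1

    template = model.template_coords()  # (3, 3), O at origin
    rots = _random_rotations(rng, n)
    waters = np.einsum("nij,aj->nai", rots, template) + oxygens[:, None, :]

    coords = np.concatenate([waters.reshape(-1, 3), solute_pos]) if len(solutes) \
        else waters.reshape(-1, 3)
    return WaterCluster(
        radius=float(radius), n_waters=n, coords=coords, solutes=solutes, model=model
    )


def _project_out_bond_velocities(
    cluster: WaterCluster, vel: np.ndarray, n_sweeps: int = 50, tol: float = 1e-12
) -> None:
    """Iteratively remove relative velocities along the three constrained
    distances of each water (in place)."""
    n_w = cluster.n_waters
    pos = cluster.coords
    mass = cluster.masses()
    pairs = [(0, 1), (0, 2), (1, 2)]
    for _ in range(n_sweeps):
        worst = 0.0
        for a, b in pairs:
            ia = np.arange(n_w) * 3 + a
            ib = np.arange(n_w) * 3 + b
            rab = pos[ia] - pos[ib]
            r2 = np.einsum("ij,ij->i", rab, rab)
            vab = vel[ia] - vel[ib]
            vr = np.einsum("ij,ij->i", vab, rab)
            worst = max(worst, float(np.max(np.abs(vr))))
            inv_m = 1.0 / mass[ia] + 1.0 / mass[ib]
            g = vr / (r2 * inv_m)
            vel[ia] -= (g / mass[ia])[:, None] * rab
            vel[ib] += (g / mass[ib])[:, None] * rab
        if worst < tol:
            break


def init_velocities(cluster: WaterCluster, temperature: float, seed: int = 0
                    ) -> WaterCluster:
    """Maxwell–Boltzmann velocities at the target temperature (in place).

    Net linear momentum of the waters is removed, relative velocities along
    the rigid constraints are projected out, and the result is rescaled so
    the constrained-ensemble kinetic temperature (6 degrees of freedom per
    water) equals the target exactly.  Fixed solutes get zero velocity.
    """
    if cluster.n_waters == 0:
        cluster.velocities = np.zeros((cluster.n_atoms, 3))
        return cluster
    rng = np.random.default_rng(seed)
    mass = cluster.masses()
    vel = np.zeros((cluster.n_atoms, 3))
    n_wa = cluster.n_water_atoms
    if temperature > 0.0:
        sigma = np.sqrt(KB * temperature * KCAL_TO_AMU_A2_PS2 / mass[:n_wa])
        vel[:n_wa] = rng.normal(size=(n_wa, 3)) * sigma[:, None]
        # remove net momentum of the free atoms
        p_net = (mass[:n_wa, None] * vel[:n_wa]).sum(axis=0)
        vel[:n_wa] -= p_net / mass[:n_wa].sum()
        _project_out_bond_velocities(cluster, vel)
        dof = 6 * cluster.n_waters
        ke = 0.5 * np.sum(mass[:n_wa, None] * vel[:n_wa] ** 2) / KCAL_TO_AMU_A2_PS2
        t_now = 2.0 * ke / (dof * KB)
        if t_now > 0:
            vel[:n_wa] *= math.sqrt(temperature / t_now)
    cluster.velocities = vel
    return cluster


def kinetic_temperature(cluster: WaterCluster) -> float:
    """Instantaneous kinetic temperature using 6 DOF per rigid water."""
    if cluster.velocities is None:
        raise ValueError("velocities not initialized")
    n_wa = cluster.n_water_atoms
    mass = cluster.masses()
    ke = 0.5 * np.sum(mass[:n_wa, None] * cluster.velocities[:n_wa] ** 2) \
        / KCAL_TO_AMU_A2_PS2
    dof = 6 * cluster.n_waters
    return 2.0 * ke / (dof * KB) if dof else 0.0
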