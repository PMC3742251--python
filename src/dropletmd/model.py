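"""Physical constants, the rigid TIP3P water model, solutes, and field specs.

Internal unit system (AKMA-like): length Å, energy kcal/mol, charge e,
mass amu, time ps.  External electrostatic field magnitudes are given in
MV/cm and converted once, at the boundary, to kcal/(mol·e·Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# Coulomb constant in kcal·Å/(mol·e²), CHARMM/AKMA convention.
COULOMB_K = 332.0636

# Boltzmann constant, kcal/(mol·K).
KB = 1.987204259e-3

# SI building blocks for the field conversion.
_E_CHARGE = 1.602176634e-19  # C
_AVOGADRO = 6.02214076e23  # 1/mol
_J_PER_KCAL = 4184.0  # thermochemical calorie

# Force per unit charge exerted by a 1 MV/cm field, in kcal/(mol·e·Å):
# 1 MV/cm = 1e8 V/m acting on one elementary charge over 1 Å, per mole.
FIELD_CONV = 1e8 * _E_CHARGE * 1e-10 * _AVOGADRO / _J_PER_KCAL  # ≈ 0.23061

# 1 kcal/mol expressed in amu·Å²/ps² (converts forces to accelerations).
KCAL_TO_AMU_A2_PS2 = _J_PER_KCAL / 10.0  # = 418.4

MASS_O = 15.9994
MASS_H = 1.008


@dataclass(frozen=True)
class WaterModel:
    """Rigid three-site TIP3P water.

    Charges in e, lengths in Å, angle in degrees, LJ well depths stored as
    positive magnitudes in kcal/mol (the energy formula uses |ε|).
    """

    q_o: float = -0.834
    q_h: float = +0.417
    bond_oh: float = 0.9572
    angle_hoh: float = 104.52
    eps_o: float = 0.1521
    eps_h: float = 0.046
    rmin2_o: float = 1.7682
    rmin2_h: float = 0.2245
    mass_o: float = MASS_O
    mass_h: float = MASS_H

    def __post_init__(self) -> None:
        if abs(self.q_o + 2.0 * self.q_h) > 1e-12:
            raise ValueError("water molecule must be net-neutral")

    @property
    def hh_distance(self) -> float:
        """Constrained H–H distance implied by the O–H bond and H–O–H angle."""
        return 2.0 * self.bond_oh * math.sin(math.radians(self.angle_hoh) / 2.0)

    @property
    def dipole_magnitude(self) -> float:
        """Permanent dipole magnitude of the rigid geometry, eÅ (≈ 0.4887)."""
        return 2.0 * self.q_h * self.bond_oh * math.cos(
            math.radians(self.angle_hoh) / 2.0
        )

    def template_coords(self) -> np.ndarray:
        """Equilibrium geometry: O at origin, dipole (bisector) along +x.

        Rows are O, H, H; the molecule lies in the xy plane.
        """
        half = math.radians(self.angle_hoh) / 2.0
        x = self.bond_oh * math.cos(half)
        y = self.bond_oh * math.sin(half)
        return np.array([[0.0, 0.0, 0.0], [x, y, 0.0], [x, -y, 0.0]])


TIP3P = WaterModel()


@dataclass(frozen=True)
class Solute:
    """A fixed monatomic solute.

    Default van der Waals parameters equal the TIP3P oxygen, the choice used
    for every solute in this study.
    """

    charge: float = 0.0
    eps: float = 0.1521
    rmin2: float = 1.7682
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fixed: bool = True

    def __post_init__(self) -> None:
        if self.eps < 0.0 or self.rmin2 < 0.0:
            raise ValueError("LJ parameters are stored as positive magnitudes")
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))

    @property
    def position_array(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


def solute_pair(charge1: float, charge2: float, d: float, **kw) -> tuple[Solute, Solute]:
    """Two solutes on the x axis at (−d/2, 0, 0) and (+d/2, 0, 0)."""
    s1 = Solute(charge=charge1, position=(-d / 2.0, 0.0, 0.0), **kw)
    s2 = Solute(charge=charge2, position=(+d / 2.0, 0.0, 0.0), **kw)
    return s1, s2


@dataclass(frozen=True)
class FieldSpec:
    """Uniform external electrostatic field: magnitude in MV/cm plus a unit axis."""

    magnitude: float = 0.0
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.magnitude < 0.0:
            raise ValueError("field magnitude must be non-negative")
        ax = np.asarray(self.axis, dtype=float)
        norm = float(np.linalg.norm(ax))
        if norm == 0.0:
            raise ValueError("field axis must be a non-zero vector")
        object.__setattr__(self, "axis", tuple(ax / norm))

    @classmethod
    def x(cls, magnitude: float) -> "FieldSpec":
        return cls(magnitude=magnitude, axis=(1.0, 0.0, 0.0))

    @classmethod
    def y(cls, magnitude: float) -> "FieldSpec":
        return cls(magnitude=magnitude, axis=(0.0, 1.0, 0.0))

    @classmethod
    def zero(cls) -> "FieldSpec":
        return cls(magnitude=0.0)

    @property
    def axis_array(self) -> np.ndarray:
        return np.asarray(self.axis, dtype=float)

    @property
    def vector_kcal(self) -> np.ndarray:
        """Field vector in kcal/(mol·e·Å)."""
        return self.magnitude * FIELD_CONV * self.axis_array


def combine_lj(eps_i: float, rmin2_i: float, eps_j: float, rmin2_j: float
               ) -> tuple[float, float]:
    """Standard (Lorentz–Berthelot style) combining rules.

    Returns (ε_ij, Rmin_ij) with ε_ij = sqrt(ε_i ε_j) and
    Rmin_ij = Rmin_i/2 + Rmin_j/2.
    """
    if eps_i < 0.0 or eps_j < 0.0 or rmin2_i < 0.0 or rmin2_j < 0.0:
        raise ValueError("LJ parameters must be non-negative")
    return math.sqrt(eps_i * eps_j), rmin2_i + rmin2_j


def molecular_dipole(coords: np.ndarray, model: WaterModel = TIP3P) -> np.ndarray:
    """Dipole moment (eÅ) of one water from its three atom positions (O, H, H).

    Referenced to the oxygen position; the molecule is net-neutral, so the
    reference point does not matter.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (3, 3):
        raise ValueError(f"expected 3 atoms (O, H, H), got shape {coords.shape}")
    q = np.array([model.q_o, model.q_h, model.q_h])
    return (q[:, None] * (coords - coords[0])).sum(axis=0)


def field_force(charge: float, fieldspec: FieldSpec) -> np.ndarray:
    """Force Q·E on a point charge from the uniform external field,
    kcal/(mol·Å)."""
    return charge * fieldspec.vector_kcal
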