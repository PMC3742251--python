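"""Distance scans, mean-force curves, PMF integration, and the continuum
point-charge superposition analysis.

A scan runs one independent droplet simulation per solute separation d
(fresh cluster, fresh seed), decomposes the mean force on S₂, and records
the requested force component versus d.  The PMF is the inward trapezoidal
integral of the mean force with a zero-force tail beyond the largest
separation; curves are shifted so the barrier after the contact well (the
"second peak") sits at zero, the escape-energy convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import build_cluster
from .engine import EngineConfig, run
from .mean_force import ForceDecomposition, decompose
from .model import FieldSpec, Solute, solute_pair

logger = logging.getLogger("dropletmd")

__all__ = ["MeanForceCurve", "PmfCurve", "scan", "integrate_pmf",
           "continuum_estimate", "excluded_solvent"]

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class MeanForceCurve:
    """Mean-force component on S₂ versus solute separation d."""

    d: np.ndarray  # Å, strictly increasing
    f: np.ndarray  # kcal/(mol·Å)
    sem: np.ndarray | None = None
    axis: str = "x"
    fieldspec: FieldSpec = field(default_factory=FieldSpec.zero)
    charges: tuple[float, float] = (0.0, 0.0)
    decompositions: list[ForceDecomposition] | None = None
    seeds: list[int] | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.d.ndim != 1 or self.d.shape != self.f.shape:
            raise ValueError("d and f must be 1-D arrays of equal length")
        if len(self.d) > 1 and not np.all(np.diff(self.d) > 0):
            raise ValueError("d grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"d": self.d, f"f_{self.axis}": self.f})
        if self.sem is not None:
            out["sem"] = self.sem
        return out

    @property
    def minimum(self) -> tuple[float, float]:
        """(d, F) at the most attractive point of the curve."""
        i = int(np.argmin(self.f))
        return float(self.d[i]), float(self.f[i])

    @property
    def maximum(self) -> tuple[float, float]:
        i = int(np.argmax(self.f))
        return float(self.d[i]), float(self.f[i])


@dataclass
class PmfCurve:
    """Potential of mean force versus separation, kcal/mol.

    ``shift_d`` marks the separation of the second peak used as the zero of
    energy; None means no peak was identifiable and the curve is unshifted.
    """

    d: np.ndarray
    pmf: np.ndarray
    shift_d: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"d": self.d, "pmf": self.pmf})


def scan(
    charges: tuple[float, float],
    fieldspec: FieldSpec,
    d_values: Sequence[float],
    radius: float = 12.0,
    config: EngineConfig | None = None,
    seed: int = 0,
    axis: str = "x",
    solute_kw: dict | None = None,
    vacuum: bool = False,
) -> MeanForceCurve:
    """Mean-force curve from one independent MD run per separation.

    Solutes sit at (∓d/2, 0, 0) with the given charges (TIP3P-oxygen vdW by
    default); per-d seeds are spawned deterministically from ``seed``.
    ``vacuum=True`` builds solvent-free controls (the curve must then equal
    the closed-form direct force, plus the field term).
    """
    config = config or EngineConfig.desk()
    d_values = np.asarray(sorted(float(d) for d in d_values))
    solute_kw = solute_kw or {}
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(len(d_values))
    ]
    forces, sems, decomps = [], [], []
    for d, run_seed in zip(d_values, child_seeds):
        s1, s2 = solute_pair(charges[0], charges[1], d, **solute_kw)
        cluster = build_cluster(radius, [s1, s2], seed=run_seed,
                                n_waters=0 if vacuum else None)
        logger.info(
            "scan point d=%.2f Å: %d waters, field %.0f MV/cm along %s, seed %d",
            d, cluster.n_waters, fieldspec.magnitude, axis, run_seed,
        )
        traj = run(cluster, fieldspec, config, seed=run_seed)
        dec = decompose(traj, s2=s2, s1=s1, fieldspec=fieldspec)
        forces.append(dec.component(axis))
        sems.append(float(dec.sem[_AXIS[axis]]))
        decomps.append(dec)
    return MeanForceCurve(
        d=d_values,
        f=np.array(forces),
        sem=np.array(sems),
        axis=axis,
        fieldspec=fieldspec,
        charges=tuple(charges),
        decompositions=decomps,
        seeds=child_seeds,
    )


def _smooth(f: np.ndarray, d: np.ndarray, window: float = 0.4) -> np.ndarray:
    """Centered moving average over a ``window`` Å span (odd point count)."""
    if len(f) < 3:
        return f.copy()
    dd = float(np.median(np.diff(d)))
    half = max(int(round(window / (2 * dd))), 1)
    out = np.empty_like(f)
    for i in range(len(f)):
        lo, hi = max(0, i - half), min(len(f), i + half + 1)
        out[i] = f[lo:hi].mean()
    return out


def _second_peak_index(pmf: np.ndarray, d: np.ndarray) -> int | None:
    """Barrier after the contact well: scanning from small d, find the first
    local minimum, then the next local maximum (3-point stencil on the
    smoothed curve; ties break toward smaller d)."""
    u = _smooth(pmf, d)
    n = len(u)
    well = None
    for i in range(1, n - 1):
        if u[i] <= u[i - 1] and u[i] < u[i + 1]:
            well = i
            break
    if well is None:
        return None
    for i in range(well + 1, n - 1):
        if u[i] >= u[i - 1] and u[i] > u[i + 1]:
            return i
    return None


def integrate_pmf(curve: MeanForceCurve) -> PmfCurve:
    """PMF(d) = ∫_d^∞ F dd′, trapezoidal, zero-force tail beyond d_max.

    After integration the curve is shifted so the second peak (the barrier
    out of the contact well) is exactly zero; if no such peak exists a
    warning is raised and the unshifted curve returned.
    """
    d, f = curve.d, curve.f
    if len(d) < 2:
        raise ValueError("need at least two grid points to integrate")
    # cumulative trapezoid from the right; F(d_max) tail treated as zero
    seg = 0.5 * (f[1:] + f[:-1]) * np.diff(d)
    pmf = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    idx = _second_peak_index(pmf, d)
    if idx is None:
        warnings.warn(
            "no identifiable second peak; PMF returned unshifted",
            RuntimeWarning,
            stacklevel=2,
        )
        return PmfCurve(d=d.copy(), pmf=pmf, shift_d=None)
    return PmfCurve(d=d.copy(), pmf=pmf - pmf[idx], shift_d=float(d[idx]))


def _check_grids(a: MeanForceCurve, b: MeanForceCurve) -> None:
    if a.d.shape != b.d.shape or not np.allclose(a.d, b.d):
        raise ValueError("mean-force curves are on different d grids")
    if a.axis != b.axis:
        raise ValueError(f"axis mismatch: {a.axis} vs {b.axis}")


def continuum_estimate(curve_zero_field: MeanForceCurve,
                       one_atom: ForceDecomposition,
                       axis: str | None = None) -> MeanForceCurve:
    """Point-charge superposition estimate of the in-field curve.

    F^est(d; E) = F(two_atoms; E=0)(d) + F^net(one_atom; E) — the
    d-independent single-ion net force broadcast over the grid.
    """
    axis = axis or curve_zero_field.axis
    one = float(one_atom.f_net[_AXIS[axis]])
    return MeanForceCurve(
        d=curve_zero_field.d.copy(),
        f=curve_zero_field.f + one,
        axis=axis,
        fieldspec=curve_zero_field.fieldspec,
        charges=curve_zero_field.charges,
    )


def excluded_solvent(curve_field: MeanForceCurve,
                     curve_zero_field: MeanForceCurve,
                     one_atom: ForceDecomposition) -> MeanForceCurve:
    """Superposition residual: the force on S₂ attributed to solvent excluded
    by S₁'s volume.

    residual(d) = F(two; E)(d) − F(two; 0)(d) − F^net(one; E).
    """
    _check_grids(curve_field, curve_zero_field)
    one = float(one_atom.f_net[_AXIS[curve_field.axis]])
    return MeanForceCurve(
        d=curve_field.d.copy(),
        f=curve_field.f - curve_zero_field.f - one,
        axis=curve_field.axis,
        fieldspec=curve_field.fieldspec,
        charges=curve_field.charges,
    )
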