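"""Trajectory observables: per-water dipole, net electrostatic field, radial
profiles around a charged solute, and the solvent molecular polarizability.

All averages follow the occupancy-weighted convention: sums run over every
qualifying water in every saved frame and are divided by the total qualifying
count N (not frame-by-frame means), so sparsely occupied regions are weighted
by how often they are actually visited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trajectory
from .kernels import field_sum_uniform, radial_profile_sums
from .model import COULOMB_K, Solute

__all__ = [
    "DipoleFieldPoint",
    "RadialProfile",
    "mean_dipole",
    "mean_net_field",
    "radial_profiles",
    "pool_profile_points",
    "fit_polarizability",
]


@dataclass(frozen=True)
class DipoleFieldPoint:
    """One (p, E^net) observation from a uniform-field run.

    ``p`` and ``e_net`` are the components along the field axis (eÅ and
    kcal/(mol·e·Å)); the full vectors are kept alongside.  ``n`` counts
    qualifying water observations (waters × frames inside r_cut).
    """

    p: float
    e_net: float
    n: int
    e_ext: float  # MV/cm
    p_vector: tuple[float, float, float] = (0.0, 0.0, 0.0)
    e_net_vector: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class RadialProfile:
    """Binned radial profiles around a central solute (Δr bins).

    Empty bins hold NaN (undefined), never zero.
    """

    r: np.ndarray  # bin centers, Å
    p: np.ndarray  # radial dipole component, eÅ
    e_net: np.ndarray  # radial net-field component, kcal/(mol·e·Å)
    n: np.ndarray  # occupancy counts
    dr: float
    solute_charge: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r, "p": self.p, "e_net": self.e_net, "n": self.n}
        )


def _water_dipoles(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame, per-water dipole vectors and oxygen distances from origin.

    Returns (dipoles (nf, n_w, 3) in eÅ, r_O (nf, n_w) in Å).
    """
    m = traj.cluster.model
    nw = traj.n_waters
    w = traj.frames[:, : 3 * nw].reshape(traj.n_frames, nw, 3, 3)
    o = w[:, :, 0]
    dip = m.q_h * ((w[:, :, 1] - o) + (w[:, :, 2] - o))
    return dip, np.linalg.norm(o, axis=-1)


def default_r_cut(traj: Trajectory, margin: float = 4.0) -> float:
    """Default sampling radius: droplet radius minus a surface-layer margin."""
    return max(traj.cluster.radius - margin, 0.0)


def mean_dipole(traj: Trajectory, r_cut: float | None = None) -> DipoleFieldPoint:
    """Mean dipole per water over all frames, restricted to waters whose
    oxygen lies within ``r_cut`` of the origin.

    Reported as the component along the field axis of the run (the droplet
    center direction is meaningless for uniform fields) plus the full vector.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no production frames")
    r_cut = default_r_cut(traj) if r_cut is None else r_cut
    dip, r_o = _water_dipoles(traj)
    mask = r_o <= r_cut
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no waters inside r_cut = {r_cut} Å")
    p_vec = dip[mask].sum(axis=0) / n
    axis = traj.fieldspec.axis_array
    return DipoleFieldPoint(
        p=float(p_vec @ axis),
        e_net=float("nan"),
        n=n,
        e_ext=traj.fieldspec.magnitude,
        p_vector=tuple(p_vec),
    )


def mean_net_field(traj: Trajectory, r_cut: float | None = None) -> DipoleFieldPoint:
    """Mean net electrostatic field at qualifying water oxygens.

    The external field (converted to kcal/(mol·e·Å)) plus the Coulomb field
    from all atoms of every *other* molecule, averaged over qualifying
    oxygens and frames; solute charges are included when present.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no production frames")
    r_cut = default_r_cut(traj) if r_cut is None else r_cut
    cl = traj.cluster
    acc, count = field_sum_uniform(
        np.ascontiguousarray(traj.frames), cl.charges(), cl.mol_ids(),
        cl.n_waters, r_cut, COULOMB_K,
    )
    if count == 0:
        raise ValueError(f"no waters inside r_cut = {r_cut} Å")
    e_vec = acc / count + traj.fieldspec.vector_kcal
    axis = traj.fieldspec.axis_array
    # also report p on the same selection for convenience
    p_point = mean_dipole(traj, r_cut)
    return DipoleFieldPoint(
        p=p_point.p,
        e_net=float(e_vec @ axis),
        n=int(count),
        e_ext=traj.fieldspec.magnitude,
        p_vector=p_point.p_vector,
        e_net_vector=tuple(e_vec),
    )


def radial_profiles(traj: Trajectory, solute: Solute | None = None,
                    dr: float = 0.1, r_max: float | None = None
                    ) -> RadialProfile:
    """Radial dipole and net-field profiles around a single central solute.

    Per bin: the radial projection (onto the oxygen's radial unit vector) of
    the molecular dipole and of the net field at the oxygen — the solute
    point-charge term k·q_j/r² plus the Coulomb field from all atoms of other
    waters — divided by the bin occupancy.  Bins never visited are NaN.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no production frames")
    cl = traj.cluster
    if solute is None:
        if len(cl.solutes) != 1:
            raise ValueError("radial profiles need exactly one central solute")
        solute = cl.solutes[0]
    if np.linalg.norm(solute.position_array) > 1e-9:
        raise ValueError("the central solute must sit at the origin")
    r_max = cl.radius if r_max is None else r_max
    n_bins = int(np.ceil(r_max / dr))
    m = cl.model
    dip_sum, field_sum, counts = radial_profile_sums(
        np.ascontiguousarray(traj.frames), cl.charges(), cl.mol_ids(),
        cl.n_waters, m.q_o, m.q_h, solute.charge, dr, n_bins, COULOMB_K,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(counts > 0, dip_sum / counts, np.nan)
        e = np.where(counts > 0, field_sum / counts, np.nan)
    r = (np.arange(n_bins) + 0.5) * dr
    return RadialProfile(r=r, p=p, e_net=e, n=counts, dr=dr,
                         solute_charge=solute.charge)


def pool_profile_points(profiles: list[RadialProfile],
                        r_max: float | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool (E^net, p) bin pairs across profiles (e.g., across solute
    charges), keeping occupied bins with r ≤ r_max.

    Returns (e_net, p, weights) where weights are bin occupancies.
    """
    es, ps, ws = [], [], []
    for prof in profiles:
        keep = prof.n > 0
        if r_max is not None:
            keep &= prof.r <= r_max
        es.append(prof.e_net[keep])
        ps.append(prof.p[keep])
        ws.append(prof.n[keep].astype(float))
    return np.concatenate(es), np.concatenate(ps), np.concatenate(ws)


def fit_polarizability(e_net: np.ndarray, p: np.ndarray,
                       weights: np.ndarray | None = None,
                       window: float = 25.0) -> float:
    """Solvent molecular polarizability ε₀γ_mol = dp/dE^net.

    Weighted least-squares slope of p versus E^net restricted to the
    linear-response window |E^net| < window (kcal/(mol·e·Å)).  Units of the
    result: (mol·e²·Å²)/kcal.
    """
    e_net = np.asarray(e_net, dtype=float)
    p = np.asarray(p, dtype=float)
    w = np.ones_like(e_net) if weights is None else np.asarray(weights, float)
    keep = (np.abs(e_net) < window) & np.isfinite(e_net) & np.isfinite(p)
    if keep.sum() < 2:
        raise ValueError(
            f"need at least 2 points with |E^net| < {window}, got {keep.sum()}"
        )
    e, pp, w = e_net[keep], p[keep], w[keep]
    # weighted linear fit p = a + s·E; return the slope s
    sw = w.sum()
    eb = (w * e).sum() / sw
    pb = (w * pp).sum() / sw
    denom = (w * (e - eb) ** 2).sum()
    if denom == 0.0:
        raise ValueError("degenerate fit: all E^net values identical")
    return float((w * (e - eb) * (pp - pb)).sum() / denom)
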