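"""Study protocols: the droplet experiments this package was built to run.

Each function wires together the cluster builder, the MD engine, and the
observables at the desk-scale study conditions (12 Å droplets, ≈240 waters,
10 ps equilibration, 50 ps production per run) and returns plain numbers.
The full-scale conditions (20–25 Å droplets, 200 ps + 1 ns) are available by
passing ``EngineConfig.full()`` and a larger radius; they are identical
protocols, only bigger.

All randomness is derived from one base seed via ``numpy.random.SeedSequence``
spawning, so every study is reproducible end to end.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .cluster import build_cluster
from .engine import EngineConfig, run
from .mean_force import ForceDecomposition, decompose
from .model import FieldSpec, Solute
from .observables import (
    fit_polarizability,
    mean_dipole,
    mean_net_field,
    pool_profile_points,
    radial_profiles,
)
from .pmf import MeanForceCurve, scan

logger = logging.getLogger("dropletmd")

DESK_RADIUS = 12.0

#: Surface-layer margin excluded from uniform-field dipole/field averages.
R_CUT_MARGIN = 4.0


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def dipole_response(
    seed: int,
    field_values: Sequence[float] = (10.0, 20.0, 30.0, 40.0),
    radius: float = DESK_RADIUS,
    config: EngineConfig | None = None,
    axis: str = "x",
) -> dict:
    """p versus E^ext for a pure-water droplet; low-field slope through the
    origin.

    Returns {'e_ext': [...], 'p': [...], 'slope': eÅ per MV/cm}.
    """
    config = config or EngineConfig.desk()
    seeds = _spawn_seeds(seed, len(field_values))
    make = FieldSpec.x if axis == "x" else FieldSpec.y
    p_values = []
    for e_ext, s in zip(field_values, seeds):
        cluster = build_cluster(radius, [], seed=s)
        traj = run(cluster, make(e_ext), config, seed=s)
        point = mean_dipole(traj, r_cut=radius - R_CUT_MARGIN)
        logger.info("dipole response E=%g MV/cm: p=%.4f eÅ", e_ext, point.p)
        p_values.append(point.p)
    e = np.asarray(field_values, dtype=float)
    p = np.asarray(p_values)
    slope = float((e @ p) / (e @ e))  # least squares through the origin
    return {"e_ext": list(e), "p": list(p), "slope": slope}


def dipole_at_field(
    seed: int,
    e_ext: float = 50.0,
    radius: float = DESK_RADIUS,
    config: EngineConfig | None = None,
) -> dict:
    """Field-axis dipole component and net field at one field strength."""
    config = config or EngineConfig.desk()
    (s,) = _spawn_seeds(seed, 1)
    cluster = build_cluster(radius, [], seed=s)
    traj = run(cluster, FieldSpec.x(e_ext), config, seed=s)
    point = mean_net_field(traj, r_cut=radius - R_CUT_MARGIN)
    logger.info("dipole at E=%g: p=%.4f eÅ, E_net=%.2f", e_ext, point.p,
                point.e_net)
    return {"e_ext": e_ext, "p": point.p, "e_net": point.e_net, "n": point.n}


def polarizability_study(
    seed: int,
    charges: Sequence[float] = (-1.0, -0.6, -0.2, +0.2, +0.6, +1.0),
    radius: float = DESK_RADIUS,
    config: EngineConfig | None = None,
    window: float = 25.0,
) -> dict:
    """ε₀γ_mol from radial p(r)/E^net(r) profiles around central solutes.

    One zero-field run per solute charge; (E^net, p) bin pairs are pooled
    across charges (bins within radius − 4 Å) and the slope fitted inside
    the |E^net| < window linear-response region, weighted by bin occupancy.
    """
    config = config or EngineConfig.desk()
    seeds = _spawn_seeds(seed, len(charges))
    profiles = []
    for q, s in zip(charges, seeds):
        cluster = build_cluster(radius, [Solute(charge=q)], seed=s)
        traj = run(cluster, None, config, seed=s)
        profiles.append(radial_profiles(traj))
        logger.info("radial profiles for Q=%+.1f e done", q)
    e_net, p, weights = pool_profile_points(
        profiles, r_max=radius - R_CUT_MARGIN
    )
    gamma = fit_polarizability(e_net, p, weights, window=window)
    return {"charges": list(charges), "eps0_gamma_mol": gamma,
            "n_points": int(len(e_net))}


def ion_pair_curve(
    seed: int,
    e_ext: float = 0.0,
    d_values: Sequence[float] = tuple(np.round(np.arange(2.6, 3.61, 0.2), 10)),
    radius: float = DESK_RADIUS,
    config: EngineConfig | None = None,
    field_axis: str = "x",
    force_axis: str = "x",
) -> MeanForceCurve:
    """F on S₂ versus d for the −1 e / +1 e pair under a given field."""
    config = config or EngineConfig.desk()
    field = (FieldSpec.x(e_ext) if field_axis == "x" else FieldSpec.y(e_ext))
    return scan((-1.0, +1.0), field, d_values, radius=radius, config=config,
                seed=seed, axis=force_axis)


def neutral_pair_curve(
    seed: int,
    d_values: Sequence[float],
    e_ext: float = 0.0,
    radius: float = DESK_RADIUS,
    config: EngineConfig | None = None,
    field_axis: str = "x",
) -> MeanForceCurve:
    """F_X on S₂ versus d for two uncharged TIP3P-oxygen-like solutes.

    Neutral-pair mean forces are an order of magnitude smaller than the
    ion-pair ones (tenths of kcal/(mol·Å)), so this protocol defaults to the
    long end of the desk schedule: 100 ps production per point.
    """
    config = config or EngineConfig.desk(prod_time=100.0)
    field = (FieldSpec.x(e_ext) if field_axis == "x" else FieldSpec.y(e_ext))
    return scan((0.0, 0.0), field, d_values, radius=radius, config=config,
                seed=seed, axis="x")


def one_atom_decomposition(
    seed: int,
    e_ext: float,
    charge: float = +1.0,
    radius: float = DESK_RADIUS,
    config: EngineConfig | None = None,
    field_axis: str = "x",
) -> ForceDecomposition:
    """Mean-force decomposition on a single charged solute under a field."""
    config = config or EngineConfig.desk()
    (s,) = _spawn_seeds(seed, 1)
    solute = Solute(charge=charge)
    cluster = build_cluster(radius, [solute], seed=s)
    field = FieldSpec.x(e_ext) if field_axis == "x" else FieldSpec.y(e_ext)
    traj = run(cluster, field, config, seed=s)
    return decompose(traj, s2=solute)
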