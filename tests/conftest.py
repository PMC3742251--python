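"""Shared fixtures: hand-built frames and tiny trajectories for oracle tests."""

from __future__ import annotations

import numpy as np
import pytest

from dropletmd import FieldSpec, TIP3P, WaterCluster
from dropletmd.engine import Trajectory


def make_water(origin, rotation=None, model=TIP3P) -> np.ndarray:
    """One rigid water at ``origin`` (oxygen position), optionally rotated."""
    coords = model.template_coords()
    if rotation is not None:
        coords = coords @ np.asarray(rotation).T
    return coords + np.asarray(origin, dtype=float)


def hand_cluster(waters, solutes=(), radius=50.0) -> WaterCluster:
    """Cluster from explicit water blocks (each (3, 3) O,H,H) and solutes."""
    blocks = [np.asarray(w, dtype=float) for w in waters]
    solutes = tuple(solutes)
    parts = [b for b in blocks]
    if solutes:
        parts.append(np.array([s.position_array for s in solutes]))
    coords = np.concatenate(parts) if parts else np.empty((0, 3))
    return WaterCluster(radius=radius, n_waters=len(blocks), coords=coords,
                        solutes=solutes)


def hand_trajectory(waters, solutes=(), fieldspec=None, radius=50.0,
                    n_frames=1) -> Trajectory:
    """Single- or repeated-frame trajectory from hand-placed molecules."""
    cl = hand_cluster(waters, solutes, radius)
    frames = np.repeat(cl.coords[None], n_frames, axis=0)
    return Trajectory(
        frames=frames,
        times=0.02 * np.arange(n_frames),
        cluster=cl,
        fieldspec=fieldspec or FieldSpec.zero(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def rotation_matrix(axis, angle) -> np.ndarray:
    """Rodrigues rotation about a (unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
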