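"""File formats and reproducibility plumbing.

Native trajectory format is extended XYZ: one block per frame, a comment line
carrying ``key=value`` metadata, coordinates at full float precision so a
write/read round-trip is lossless.  Run configuration is YAML validated
through a pydantic schema (unknown keys rejected); every run can emit a
manifest recording config, seeds, package version and output digests.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cluster import WaterCluster
from .engine import EngineConfig, Trajectory
from .model import FieldSpec, Solute

__all__ = ["write_xyz", "read_xyz", "trajectory_to_xyz", "load_config",
           "RunConfig", "RunManifest"]


def _format_value(v) -> str:
    if isinstance(v, str):
        return f'"{v}"' if (" " in v or "=" in v) else v
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def _parse_comment(line: str) -> dict:
    """Parse ``key=value`` pairs; values fall back to str if not numeric."""
    out: dict = {}
    for tok in line.split():
        if "=" not in tok:
            continue
        key, raw = tok.split("=", 1)
        raw = raw.strip('"')
        try:
            out[key] = int(raw)
        except ValueError:
            try:
                out[key] = float(raw)
            except ValueError:
                out[key] = raw
    return out


def write_xyz(path: str | Path, frames: list[np.ndarray] | np.ndarray,
              elements: list[str], comments: list[dict] | None = None) -> None:
    """Write frames as extended XYZ with full-precision coordinates."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if comments is not None and len(comments) != len(frames):
        raise ValueError("one comment dict per frame required")
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            if frame.shape[0] != len(elements):
                raise ValueError(
                    f"frame {k}: {frame.shape[0]} coordinates for "
                    f"{len(elements)} elements"
                )
            fh.write(f"{len(elements)}\n")
            meta = comments[k] if comments else {}
            fh.write(" ".join(f"{key}={_format_value(v)}"
                              for key, v in meta.items()) + "\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path: str | Path
             ) -> tuple[np.ndarray, list[str], list[dict]]:
    """Read an extended-XYZ file: (frames, elements, per-frame metadata).

    An empty file yields an empty trajectory.  Malformed headers or per-frame
    atom-count mismatches raise ValueError naming the frame index.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    comments: list[dict] = []
    elements: list[str] = []
    i = 0
    k = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"frame {k}: malformed atom-count header "
                             f"{lines[i]!r}") from exc
        if i + 2 + nat > len(lines):
            raise ValueError(f"frame {k}: truncated (expected {nat} atoms)")
        comments.append(_parse_comment(lines[i + 1]))
        coords = np.empty((nat, 3))
        els: list[str] = []
        for a in range(nat):
            parts = lines[i + 2 + a].split()
            if len(parts) < 4:
                raise ValueError(f"frame {k}, atom {a}: malformed line")
            els.append(parts[0])
            coords[a] = [float(p) for p in parts[1:4]]
        if elements and els != elements:
            raise ValueError(f"frame {k}: element list differs from frame 0")
        elements = els
        frames.append(coords)
        i += 2 + nat
        k += 1
    stacked = (np.stack(frames) if frames
               else np.empty((0, 0, 3)))
    return stacked, elements, comments


def _cluster_elements(cluster: WaterCluster) -> list[str]:
    els = ["O", "H", "H"] * cluster.n_waters
    els += ["X"] * len(cluster.solutes)
    return els


def trajectory_to_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory with per-frame time and run metadata."""
    cl = traj.cluster
    base = {
        "radius": cl.radius,
        "n_waters": cl.n_waters,
        "field_mv_cm": traj.fieldspec.magnitude,
        "field_axis": "_".join(repr(a) for a in traj.fieldspec.axis),
        "seed": -1 if traj.seed is None else traj.seed,
        "solute_charges": "_".join(repr(s.charge) for s in cl.solutes) or "none",
    }
    comments = [dict(base, time_ps=float(t)) for t in traj.times]
    write_xyz(path, traj.frames, _cluster_elements(cl), comments)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class FieldConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    magnitude: float = Field(0.0, ge=0.0, description="MV/cm")
    axis: Literal["x", "y"] = "x"

    def to_spec(self) -> FieldSpec:
        return FieldSpec.x(self.magnitude) if self.axis == "x" \
            else FieldSpec.y(self.magnitude)


class SoluteConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    charge: float = 0.0
    eps: float = Field(0.1521, ge=0.0)
    rmin2: float = Field(1.7682, ge=0.0)
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def to_solute(self) -> Solute:
        return Solute(charge=self.charge, eps=self.eps, rmin2=self.rmin2,
                      position=self.position)


class RunConfig(BaseModel):
    """Validated run configuration with full-protocol defaults.

    Defaults follow the reference protocol: 2 fs step, frames every 20 fs,
    99 Å cutoff, 300 K.
    """

    model_config = ConfigDict(extra="forbid")

    radius: float = Field(20.0, gt=0.0)
    field: FieldConfig = Field(default_factory=FieldConfig)
    solutes: list[SoluteConfig] = Field(default_factory=list)
    seed: int = Field(0, ge=0, lt=2**31)
    profile: Literal["full", "desk"] = "desk"
    dt: float = Field(0.002, gt=0.0)
    cutoff: float = Field(99.0, gt=0.0)
    save_interval: int = Field(10, ge=1)
    temperature: float = Field(300.0, ge=0.0)
    boundary_k: float = Field(2.0, ge=0.0)
    min_steps: int | None = None
    equil_time: float | None = None
    prod_time: float | None = None

    def engine_config(self) -> EngineConfig:
        base = (EngineConfig.full() if self.profile == "full"
                else EngineConfig.desk())
        overrides = dict(
            dt=self.dt, cutoff=self.cutoff, save_interval=self.save_interval,
            temperature=self.temperature, boundary_k=self.boundary_k,
        )
        for key in ("min_steps", "equil_time", "prod_time"):
            val = getattr(self, key)
            if val is not None:
                overrides[key] = val
        return base.replace(**overrides)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


@dataclass
class RunManifest:
    """Everything needed to reproduce a deterministic run: configuration,
    seeds, package version, and digests of the files the run produced."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict[str, str] = dc_field(default_factory=dict)

    def add_output(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)
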