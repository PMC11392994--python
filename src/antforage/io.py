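"""Snapshot serialisation and run manifests.

Everything is plain text: configs and manifests as JSON, ant tables and
field grids as CSV (pandas round-trip, full float precision), so a run
directory is diffable and greppable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import config_to_dict
from .lattice import MODE_CODES, MODE_NAMES, PheromoneField, SimulationState


def config_hash(config) -> str:
    """Stable short hash of a configuration (for manifests)."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every run's outputs."""

    config_hash: str
    seed: int
    code_version: str
    started: str
    finished: str | None = None
    outputs: list[str] = field(default_factory=list)
    status: str = "running"
    extra: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def start_manifest(config, seed: int) -> RunManifest:
    from . import __version__

    return RunManifest(
        config_hash=config_hash(config),
        seed=int(seed),
        code_version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def write_ant_table(state: SimulationState, path) -> None:
    """Ant table CSV: one row per ant (id, x, y, mode)."""
    df = pd.DataFrame(
        {
            "id": np.arange(len(state.positions)),
            "x": state.positions[:, 0],
            "y": state.positions[:, 1],
            "mode": [MODE_NAMES[int(m)] for m in state.modes],
        }
    )
    df.to_csv(path, index=False)


def read_ant_table(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    pos = df[["x", "y"]].to_numpy(dtype=np.int64)
    modes = np.array([MODE_CODES[m] for m in df["mode"]], dtype=np.int8)
    return pos, modes


def write_grid(c: np.ndarray, path, value: str = "c") -> None:
    """Long-form grid CSV (x, y, value), 1-based site indices, full precision."""
    M, N = c.shape
    xs, ys = np.meshgrid(np.arange(1, M + 1), np.arange(1, N + 1), indexing="ij")
    df = pd.DataFrame({"x": xs.ravel(), "y": ys.ravel(), value: c.ravel()})
    df.to_csv(path, index=False, float_format="%.17g")


def read_grid(path, value: str = "c") -> np.ndarray:
    # round_trip parsing: the default C float parser can be off by 1 ulp
    df = pd.read_csv(path, float_precision="round_trip")
    M = int(df["x"].max())
    N = int(df["y"].max())
    c = np.zeros((M, N))
    c[df["x"].to_numpy() - 1, df["y"].to_numpy() - 1] = df[value].to_numpy()
    return c


def write_snapshot(state: SimulationState, out_dir, tag: str | None = None) -> list[str]:
    """Write one lattice snapshot (ant table + pheromone grid); returns paths.

    Partial files are removed if a write fails, so a run directory never
    holds a torn snapshot.
    """
    tag = tag if tag is not None else f"t{state.time:g}"
    ant_path = os.path.join(out_dir, f"ants_{tag}.csv")
    grid_path = os.path.join(out_dir, f"pheromone_{tag}.csv")
    written = []
    try:
        write_ant_table(state, ant_path)
        written.append(ant_path)
        write_grid(state.field.c, grid_path)
        written.append(grid_path)
    except Exception:
        for p in written:
            try:
                os.remove(p)
            except OSError:
                pass
        raise
    return written


def read_snapshot(ant_path, grid_path, time: float = 0.0,
                  discovery_flag: bool = False) -> SimulationState:
    pos, modes = read_ant_table(ant_path)
    c = read_grid(grid_path)
    return SimulationState(
        positions=pos,
        modes=modes,
        steps_since_conversion=np.zeros(len(pos), dtype=np.int64),
        field=PheromoneField(c=c, t=time),
        time=time,
        discovery_flag=discovery_flag,
    )


def write_continuum_snapshot(fields, params, path) -> None:
    """Long-form CSV (x, y, p, q, u) of one continuum snapshot."""
    from .continuum import grid_coordinates

    xs, ys = grid_coordinates(params)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    df = pd.DataFrame(
        {
            "x": X.ravel(),
            "y": Y.ravel(),
            "p": fields.p.ravel(),
            "q": fields.q.ravel(),
            "u": fields.u.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
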