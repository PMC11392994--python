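"""Stochastic lattice model of foraging ants coupled to a pheromone field.

Ants hop on an M x N lattice (sites indexed from 1, reflecting walls).
Foragers perform a Moore-neighbourhood random walk that becomes biased up
the local pheromone gradient once a trail exists; an ant that steps onto a
food source converts to a carrier, beelines back to the nest while
secreting pheromone at a rate that decays with its distance from the food,
and converts back to a forager on arrival.  The pheromone obeys a
reaction--diffusion equation (forward Euler, 5-point Laplacian) with a
Robin "leaky" boundary so the chemical keeps flowing out with its gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._kernels import CARRIER, FORAGER
from .config import ScenarioConfig

MODE_NAMES = {FORAGER: "forager", CARRIER: "carrier"}
MODE_CODES = {v: k for k, v in MODE_NAMES.items()}


@dataclass
class AntState:
    """Position and behavioural mode of one ant."""

    pos: tuple[int, int]
    mode: str = "forager"
    steps_since_conversion: int = 0

    def __post_init__(self):
        if self.mode not in MODE_CODES:
            raise ValueError(f"unknown ant mode {self.mode!r}")


@dataclass
class PheromoneField:
    """Pheromone concentration c(x, t) on the lattice, shape (M, N)."""

    c: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, config: ScenarioConfig) -> "PheromoneField":
        return cls(c=np.zeros((config.M, config.N)), t=0.0)

    def total_mass(self, dx: float = 1.0) -> float:
        return float(self.c.sum()) * dx * dx


@dataclass
class SimulationState:
    """One snapshot of a lattice run (positions, modes, field, clock)."""

    positions: np.ndarray  # (n, 2) int
    modes: np.ndarray  # (n,) int8, 0 = forager, 1 = carrier
    steps_since_conversion: np.ndarray  # (n,) int
    field: PheromoneField
    time: float
    discovery_flag: bool

    @property
    def ants(self) -> list[AntState]:
        return [
            AntState(
                pos=(int(x), int(y)),
                mode=MODE_NAMES[int(m)],
                steps_since_conversion=int(s),
            )
            for (x, y), m, s in zip(
                self.positions, self.modes, self.steps_since_conversion
            )
        ]

    @property
    def n_carriers(self) -> int:
        return int((self.modes == CARRIER).sum())


@dataclass
class LatticeResult:
    """Full output of :func:`simulate`."""

    config: ScenarioConfig
    snapshots: list[SimulationState]
    trips: np.ndarray  # (n_trips, 2): chebyshev distance at conversion, moves taken
    discovery_time: float  # -1.0 if no source was ever found

    @property
    def final(self) -> SimulationState:
        return self.snapshots[-1]


def _check_pos(pos, config: ScenarioConfig) -> tuple[int, int]:
    x, y = int(pos[0]), int(pos[1])
    if not (1 <= x <= config.M and 1 <= y <= config.N):
        raise ValueError(f"position {pos} outside the lattice [1,{config.M}]x[1,{config.N}]")
    return x, y


def moore_neighborhood(pos, config: ScenarioConfig) -> list[tuple[int, int]]:
    """In-bounds Moore neighbours of ``pos``, in a fixed row-major order."""
    x, y = _check_pos(pos, config)
    nb = np.empty((8, 2), dtype=np.int64)
    cnt = _kernels.neighbors(x, y, config.M, config.N, nb)
    return [(int(nb[i, 0]), int(nb[i, 1])) for i in range(cnt)]


def forager_move_distribution(pos, pher: PheromoneField, config: ScenarioConfig) -> np.ndarray:
    """Move probabilities over :func:`moore_neighborhood`'s neighbour order.

    Each neighbour a gets weight eps if the concentration drop dc_a < 0,
    1 if dc_a = 0, and 1 + dc_a if dc_a > 0, normalised over the in-bounds
    neighbourhood; the walk is therefore uniform on a flat (e.g. zero)
    field and biased up the steepest pheromone gradient otherwise.
    """
    x, y = _check_pos(pos, config)
    if not np.all(np.isfinite(pher.c)):
        raise FloatingPointError("pheromone field contains non-finite values")
    nb = np.empty((8, 2), dtype=np.int64)
    cnt = _kernels.neighbors(x, y, config.M, config.N, nb)
    w = np.empty(8, dtype=np.float64)
    total = _kernels.forager_weights(
        x,
        y,
        pher.c,
        config.epsilon,
        config.sense_threshold,
        config.weber_fraction,
        nb,
        cnt,
        w,
    )
    return w[:cnt] / total


def carrier_step(pos, config: ScenarioConfig) -> tuple[int, int]:
    """Beeline move of a carrier at ``pos`` toward the nest.

    Returns the neighbour first entered by the ray from the cell centre in
    the homing direction; ties through a cell corner take the diagonal.
    The Chebyshev distance to the nest decreases by exactly one.
    """
    x, y = _check_pos(pos, config)
    if (x, y) == config.x0:
        raise ValueError("carrier is already at the nest; convert its mode instead of stepping")
    nx, ny = _kernels.beeline_step(x, y, config.x0[0], config.x0[1])
    return int(nx), int(ny)


def deposition_rate(ant: AntState, config: ScenarioConfig, source_index: int = -1) -> float:
    """Pheromone secretion rate of ``ant``: zero for foragers, Gaussian-decayed
    amplitude summed over food sources for carriers."""
    if ant.mode == "forager":
        return 0.0
    food = np.asarray(config.food_sources, dtype=np.int64).reshape(-1, 2)
    sum_all = config.deposition == "all_sources"
    return float(
        _kernels.deposition_rate(
            ant.pos[0],
            ant.pos[1],
            food,
            config.A_dep,
            config.sigma_decay,
            source_index,
            sum_all,
        )
    )


def pheromone_step(pher: PheromoneField, ants: list[AntState], config: ScenarioConfig) -> PheromoneField:
    """One forward-Euler step of the pheromone reaction--diffusion field.

    c <- c + dt (D lap c - gamma c + S) with carrier secretion S added as a
    discrete delta (rate / dx^2) into each carrier's cell, and the Robin
    boundary closure described in :mod:`antforage._kernels`.
    """
    cn = np.empty_like(pher.c)
    _kernels.pheromone_diffuse_decay(pher.c, cn, config.D, config.gamma, config.dt, config.dx)
    if ants:
        pos = np.array([a.pos for a in ants], dtype=np.int64).reshape(-1, 2)
        mode = np.array([MODE_CODES[a.mode] for a in ants], dtype=np.int8)
        src = np.full(len(ants), -1, dtype=np.int64)
        food = np.asarray(config.food_sources, dtype=np.int64).reshape(-1, 2)
        _kernels.deposit(
            cn,
            pos,
            mode,
            src,
            food,
            config.A_dep,
            config.sigma_decay,
            config.dt,
            config.dx,
            config.deposition == "all_sources",
        )
    return PheromoneField(c=cn, t=pher.t + config.dt)


def boundary_outflow(pher: PheromoneField, config: ScenarioConfig) -> float:
    """Discrete Robin outflow rate: sum of boundary-face concentrations.

    Each boundary face of a cell contributes c_b * dx; corner cells sit on
    two faces and contribute twice.  With evaporation and secretion off,
    the field's total mass decreases by exactly dt * outflow per step.
    """
    c = pher.c
    dx = config.dx
    flow = c[0, :].sum() + c[-1, :].sum() + c[:, 0].sum() + c[:, -1].sum()
    return float(flow) * dx


def update_mode(ant: AntState, config: ScenarioConfig) -> AntState:
    """Apply the conversion rules: forager on food -> carrier; carrier at
    the nest -> forager; otherwise unchanged."""
    if ant.mode == "forager" and tuple(ant.pos) in config.food_sources:
        return AntState(pos=tuple(ant.pos), mode="carrier", steps_since_conversion=0)
    if ant.mode == "carrier" and tuple(ant.pos) == config.x0:
        return AntState(pos=tuple(ant.pos), mode="forager", steps_since_conversion=0)
    return ant


def simulate(config: ScenarioConfig, snapshot_times=None) -> LatticeResult:
    """Run the lattice model for ``config.T_max`` time units.

    ``snapshot_times`` is a list of integer time units (0 = initial state)
    at which to record the full state; it defaults to ``[T_max]``.  The
    same (config, seed) pair always reproduces the identical trajectory.
    """
    if snapshot_times is None:
        snapshot_times = [config.T_max]
    snaps = sorted(int(t) for t in snapshot_times)
    for t in snaps:
        if t < 0 or t > config.T_max:
            raise ValueError(f"snapshot time {t} outside the run [0, {config.T_max}]")
    snap_units = np.asarray(snaps, dtype=np.int64)
    food = np.asarray(config.food_sources, dtype=np.int64).reshape(-1, 2)

    snap_pos, snap_mode, snap_steps, snap_field, trips, discovery = _kernels.run_lattice(
        config.M,
        config.N,
        config.n,
        config.x0[0],
        config.x0[1],
        food,
        config.D,
        config.gamma,
        config.A_dep,
        config.sigma_decay,
        config.epsilon,
        config.sense_threshold,
        config.weber_fraction,
        config.dt,
        config.dx,
        config.T_max,
        config.seed,
        snap_units,
        config.beeline == "adaptive",
        config.deposition == "all_sources",
    )

    snapshots = [
        SimulationState(
            positions=snap_pos[s].copy(),
            modes=snap_mode[s].copy(),
            steps_since_conversion=snap_steps[s].copy(),
            field=PheromoneField(c=snap_field[s].copy(), t=float(snaps[s])),
            time=float(snaps[s]),
            discovery_flag=bool(0.0 <= discovery <= snaps[s]),
        )
        for s in range(len(snaps))
    ]
    return LatticeResult(
        config=config,
        snapshots=snapshots,
        trips=trips,
        discovery_time=float(discovery),
    )
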