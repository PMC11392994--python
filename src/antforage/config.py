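"""Configuration objects for the lattice, continuum and averaged models.

Every model run is fully specified by one of the dataclasses below plus a
seed; the JSON (de)serialisers reject unknown keys so that a config file
cannot silently misname a parameter.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence


class ConfigError(ValueError):
    """Raised when a configuration violates a model invariant."""


def _as_int_pair(value, name: str) -> tuple[int, int]:
    try:
        x, y = value
    except (TypeError, ValueError):
        raise ConfigError(f"{name}: expected a pair of coordinates, got {value!r}")
    if not (float(x).is_integer() and float(y).is_integer()):
        raise ConfigError(f"{name}: lattice coordinates must be integers, got {value!r}")
    return int(x), int(y)


def _as_float_pair(value, name: str) -> tuple[float, float]:
    try:
        x, y = value
    except (TypeError, ValueError):
        raise ConfigError(f"{name}: expected a pair of coordinates, got {value!r}")
    return float(x), float(y)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a stochastic lattice run.

    Sites are indexed ``1..M`` x ``1..N``.  All ``n`` ants start at the nest
    ``x0`` as foragers.  ``D``, ``gamma``, ``A_dep`` and ``sigma_decay``
    parameterise the pheromone reaction--diffusion field; ``epsilon`` is the
    small weight given to down-gradient moves, and ``sense_threshold`` the
    concentration below which ants cannot perceive the chemical at all and
    keep walking unbiased; ``dt`` is the forward-Euler time step of the
    field, interleaved with ant moves once food is found.

    ``beeline`` selects how carriers head home: ``"adaptive"`` re-aims the
    beeline ray at the nest from the carrier's current site each move (the
    default; it guarantees the Chebyshev distance to the nest shrinks by one
    per move), while ``"fixed"`` extends the constant nest-minus-food vector
    as literally stated for the homebound rule.  ``deposition`` selects
    whether a carrier's secretion rate sums the Gaussian factor over all
    food sources (``"all_sources"``, the printed form) or uses only the
    source it last visited (``"visited_source"``).
    """

    M: int
    N: int
    n: int
    x0: tuple[int, int]
    food_sources: tuple[tuple[int, int], ...]
    D: float = 10.0
    gamma: float = 0.001
    A_dep: float = 1.0
    sigma_decay: float = 1.0
    epsilon: float = 0.001
    sense_threshold: float = 0.001
    weber_fraction: float = 0.0
    dt: float = 0.001
    dx: float = 1.0
    T_max: int = 100
    seed: int = 0
    beeline: str = "adaptive"
    deposition: str = "all_sources"

    def __post_init__(self):
        object.__setattr__(self, "x0", _as_int_pair(self.x0, "x0"))
        object.__setattr__(
            self,
            "food_sources",
            tuple(
                _as_int_pair(fs, f"food_sources[{k}]")
                for k, fs in enumerate(self.food_sources)
            ),
        )
        if self.M < 2 or self.N < 2:
            raise ConfigError(f"M, N: lattice must be at least 2x2, got {self.M}x{self.N}")
        if self.n < 1:
            raise ConfigError(f"n: need at least one ant, got {self.n}")
        for name, site in [("x0", self.x0)] + [
            (f"food_sources[{k}]", fs) for k, fs in enumerate(self.food_sources)
        ]:
            if not (1 <= site[0] <= self.M and 1 <= site[1] <= self.N):
                raise ConfigError(
                    f"{name}: site {site} outside the lattice [1,{self.M}]x[1,{self.N}]"
                )
        if any(fs == self.x0 for fs in self.food_sources):
            raise ConfigError("food_sources: a food source may not coincide with the nest x0")
        if len(set(self.food_sources)) != len(self.food_sources):
            raise ConfigError("food_sources: food sources must be pairwise distinct")
        if not (0.0 < self.epsilon < 1.0):
            raise ConfigError(f"epsilon: need 0 < epsilon < 1, got {self.epsilon}")
        if self.sense_threshold < 0:
            raise ConfigError(
                f"sense_threshold: detection floor must be nonnegative, got {self.sense_threshold}"
            )
        if not (0.0 <= self.weber_fraction < 1.0):
            raise ConfigError(
                f"weber_fraction: need 0 <= weber_fraction < 1, got {self.weber_fraction}"
            )
        if self.dt <= 0:
            raise ConfigError(f"dt: time step must be positive, got {self.dt}")
        if self.dx <= 0:
            raise ConfigError(f"dx: lattice spacing must be positive, got {self.dx}")
        for name in ("D", "gamma", "A_dep"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: rate must be nonnegative, got {getattr(self, name)}")
        if self.sigma_decay <= 0:
            raise ConfigError(f"sigma_decay: decay length must be positive, got {self.sigma_decay}")
        mu = self.D * self.dt / self.dx**2
        if mu > 0.25 + 1e-12:
            raise ConfigError(
                f"D*dt/dx^2 = {mu:.4g} violates the forward-Euler stability bound 1/4"
            )
        if self.T_max < 0:
            raise ConfigError(f"T_max: run length must be nonnegative, got {self.T_max}")
        if self.beeline not in ("adaptive", "fixed"):
            raise ConfigError(f"beeline: unknown mode {self.beeline!r}")
        if self.deposition not in ("all_sources", "visited_source"):
            raise ConfigError(f"deposition: unknown mode {self.deposition!r}")

    @property
    def K(self) -> int:
        """Number of food sources."""
        return len(self.food_sources)

    @property
    def field_steps_per_unit(self) -> int:
        """Forward-Euler pheromone steps interleaved into one unit of time."""
        return max(1, round(1.0 / self.dt))


@dataclass(frozen=True)
class ContinuumParams:
    """Parameters of the macroscopic forager/carrier/pheromone PDE system.

    ``alpha`` is the forager diffusivity, ``chi`` the chemotactic
    sensitivity to the pheromone gradient, ``nu`` the carrier advection
    speed toward the nest, and ``Omega_pq`` / ``Omega_qp`` the conversion
    rate constants at the food sources / nest.  The nest and sources live in
    the rectangle ``[0, Lx] x [0, Ly]`` discretised with spacing ``h``;
    point conversions are mollified over a radius ``delta_width``.
    """

    Lx: float
    Ly: float
    x0: tuple[float, float]
    food_sources: tuple[tuple[float, float], ...]
    alpha: float = 1.0
    chi: float = 1.0
    nu: float = 1.0
    Omega_pq: float = 1.0
    Omega_qp: float = 1.0
    D: float = 10.0
    gamma: float = 0.001
    A_dep: float = 1.0
    h: float = 0.5
    dt: float = 0.005
    delta_width: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "x0", _as_float_pair(self.x0, "x0"))
        object.__setattr__(
            self,
            "food_sources",
            tuple(
                _as_float_pair(fs, f"food_sources[{k}]")
                for k, fs in enumerate(self.food_sources)
            ),
        )
        if self.Lx <= 0 or self.Ly <= 0:
            raise ConfigError(f"Lx, Ly: domain extents must be positive, got {self.Lx}, {self.Ly}")
        if self.h <= 0 or self.dt <= 0:
            raise ConfigError("h, dt: grid spacing and time step must be positive")
        for name in ("alpha", "chi", "nu", "Omega_pq", "Omega_qp", "D", "gamma", "A_dep"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: rate must be nonnegative, got {getattr(self, name)}")
        for name, pt in [("x0", self.x0)] + [
            (f"food_sources[{k}]", fs) for k, fs in enumerate(self.food_sources)
        ]:
            if not (0.0 <= pt[0] <= self.Lx and 0.0 <= pt[1] <= self.Ly):
                raise ConfigError(f"{name}: point {pt} outside the domain [0,{self.Lx}]x[0,{self.Ly}]")
        if self.delta_width <= 0:
            raise ConfigError(f"delta_width: mollifier radius must be positive, got {self.delta_width}")
        cfl = self.nu * self.dt / self.h
        if cfl > 1.0 + 1e-12:
            raise ConfigError(
                f"nu*dt/h = {cfl:.4g} violates the upwind CFL bound 1 for the carrier advection"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Cell-centred grid shape (nx, ny)."""
        return (int(round(self.Lx / self.h)), int(round(self.Ly / self.h)))


@dataclass(frozen=True)
class AveragedParams:
    """Coefficients of the space-averaged three-field system.

    Used by the linear-stability machinery: the conversion deltas of the
    full PDE are replaced by their spatial averages ``Omega/(M*N)`` and the
    pheromone source by an error-function factor, so the coefficients are
    constant and plane-wave analysis applies.
    """

    M: float
    N: float
    x0: tuple[float, float]
    x_f: tuple[float, float]
    alpha: float = 1.0
    chi: float = 1.0
    nu: float = 1.0
    Omega_pq: float = 1.0
    Omega_qp: float = 1.0
    D: float = 10.0
    gamma: float = 0.001
    A_dep: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "x0", _as_float_pair(self.x0, "x0"))
        object.__setattr__(self, "x_f", _as_float_pair(self.x_f, "x_f"))
        if self.M <= 0 or self.N <= 0:
            raise ConfigError("M, N: domain dimensions must be positive")
        for name in ("alpha", "chi", "nu", "D", "gamma", "A_dep"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: rate must be nonnegative, got {getattr(self, name)}")
        for name in ("Omega_pq", "Omega_qp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: conversion rate must be positive, got {getattr(self, name)}")
        if self.x0 == self.x_f:
            raise ConfigError("x_f: food source may not coincide with the nest x0")

    @property
    def MN(self) -> float:
        return self.M * self.N

    @property
    def e_hat(self) -> tuple[float, float]:
        """Unit vector from the food source toward the nest."""
        dx = self.x0[0] - self.x_f[0]
        dy = self.x0[1] - self.x_f[1]
        r = math.hypot(dx, dy)
        return (dx / r, dy / r)

    @property
    def Gamma(self) -> float:
        """Composite equilibrium constant ``(MN)^-2 (1/Opq + 1/Oqp)^-1``."""
        return 1.0 / (self.MN**2 * (1.0 / self.Omega_pq + 1.0 / self.Omega_qp))

    @property
    def E_val(self) -> float:
        """Error-function factor of the averaged pheromone source term."""
        from .stability import erf_factor

        return erf_factor(self.x_f, self.M, self.N)


_KINDS = {
    "lattice": ScenarioConfig,
    "continuum": ContinuumParams,
    "averaged": AveragedParams,
}


def _infer_kind(data: dict) -> str:
    if "Lx" in data or "delta_width" in data:
        return "continuum"
    if "x_f" in data:
        return "averaged"
    return "lattice"


def config_from_dict(data: dict):
    """Build a validated config from a plain dict; unknown keys are errors."""
    data = dict(data)
    kind = data.pop("kind", None) or _infer_kind(data)
    try:
        cls = _KINDS[kind]
    except KeyError:
        raise ConfigError(f"kind: unknown configuration kind {kind!r}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown configuration key(s) for {cls.__name__}: {', '.join(unknown)}")
    return cls(**data)


def config_to_dict(config) -> dict:
    """Serialise a config to a JSON-ready dict, tagged with its kind."""
    kind = {v: k for k, v in _KINDS.items()}[type(config)]
    out = {"kind": kind}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            v = [list(e) if isinstance(e, tuple) else e for e in v]
        out[f.name] = v
    return out


def load_config(path):
    """Load and validate a JSON configuration file."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a JSON object at top level")
    return config_from_dict(data)


def save_config(config, path) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2)
        fh.write("\n")


def load_preset(name: str):
    """Load one of the shipped scenario presets.

    Available presets: ``one_food``, ``two_equidistant``, ``two_unequal``
    (lattice scenarios) and their ``pde_``-prefixed continuum counterparts.
    """
    ref = resources.files("antforage") / "presets" / f"{name}.json"
    if not ref.is_file():
        raise ConfigError(f"unknown preset {name!r}")
    return config_from_dict(json.loads(ref.read_text()))
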