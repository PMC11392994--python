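"""Trail-formation and food-source-competition metrics.

The underlying models make qualitative claims -- "a well-formed trail
connects the nest to the food source", "all ants converge to the closer
source" -- and the functions here turn those into numbers.  A *corridor*
is the set of points within a configurable half-width of the straight
nest--source segment; trail strength is measured as the fraction of ants
(or density mass) inside it.  The thresholds are artifact definitions, not
quantities taken from observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import CARRIER, FORAGER

DEFAULT_HALF_WIDTH = 3.0


@dataclass(frozen=True)
class TrailMetricConfig:
    """Knobs shared by the trail metrics."""

    corridor_half_width: float = DEFAULT_HALF_WIDTH
    burn_in: float = 0.0
    source_index: int = 0

    def __post_init__(self):
        if self.corridor_half_width < 1:
            raise ValueError("corridor_half_width must be >= 1 lattice unit")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")


def segment_distance(points: np.ndarray, a, b) -> np.ndarray:
    """Euclidean distance from each row of ``points`` to the segment [a, b]."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        raise ValueError("degenerate segment: endpoints coincide")
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def corridor_occupancy(positions, nest, source, half_width: float = DEFAULT_HALF_WIDTH,
                       weights=None) -> float:
    """Fraction of ants (or density mass) within ``half_width`` of the
    nest--source segment.

    ``positions`` is an (m, 2) array of ant positions or grid-node
    coordinates; ``weights`` (optional) carries density mass per row, so a
    continuum field can be scored by passing its node coordinates and cell
    masses.
    """
    if tuple(nest) == tuple(source):
        raise ValueError("degenerate corridor: nest and source coincide")
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[0] == 0:
        return 0.0
    inside = segment_distance(pos, nest, source) <= half_width
    if weights is None:
        return float(inside.mean())
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        return 0.0
    return float(w[inside].sum() / total)


def winner_index(carrier_positions, nest, sources, half_width: float = DEFAULT_HALF_WIDTH,
                 weights=None):
    """Per-source share of carriers among those inside any corridor.

    Each carrier (or mass element) within ``half_width`` of at least one
    nest--source segment is assigned to the nearest such segment (lowest
    index on ties); the result sums to 1 over sources.  Returns ``None``
    when no carrier lies in any corridor (the undefined case), rather than
    propagating NaNs.
    """
    sources = [tuple(s) for s in sources]
    if len(sources) < 1:
        raise ValueError("winner_index needs at least one source")
    pos = np.atleast_2d(np.asarray(carrier_positions, dtype=float))
    if pos.shape[0] == 0:
        return None
    d = np.stack([segment_distance(pos, nest, s) for s in sources], axis=1)
    nearest = np.argmin(d, axis=1)
    in_corr = d[np.arange(len(pos)), nearest] <= half_width
    if weights is None:
        w = np.ones(len(pos))
    else:
        w = np.asarray(weights, dtype=float)
    total = w[in_corr].sum()
    if total <= 0:
        return None
    shares = np.zeros(len(sources))
    for k in range(len(sources)):
        shares[k] = w[in_corr & (nearest == k)].sum() / total
    return shares


def forager_spread(positions, nest) -> tuple[float, float]:
    """Per-axis second moment of forager positions about the nest.

    This is the variance of displacement from the nest (mean taken at the
    nest, not the sample mean), matching the random-walk prediction
    Var = 0.75 t per axis for the unbiased Moore walk.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[0] < 2:
        raise ValueError("forager_spread needs at least 2 ants")
    d = pos - np.asarray(nest, dtype=float)
    return (float(np.mean(d[:, 0] ** 2)), float(np.mean(d[:, 1] ** 2)))


def discovery_time(result) -> float:
    """Time of the first forager--food contact in a lattice run.

    Returns ``inf`` if no source was ever found (e.g. a foodless run).
    """
    t = getattr(result, "discovery_time", result)
    t = float(t)
    return math.inf if t < 0 else t


def carrier_positions(state) -> np.ndarray:
    """Positions of the carriers in a lattice snapshot."""
    return state.positions[state.modes == CARRIER]


def forager_positions(state) -> np.ndarray:
    """Positions of the foragers in a lattice snapshot."""
    return state.positions[state.modes == FORAGER]


def snapshot_report(state, config, half_width: float = DEFAULT_HALF_WIDTH) -> dict:
    """Standard per-snapshot metric bundle for a lattice state."""
    report = {
        "time": state.time,
        "n_carriers": int(state.n_carriers),
        "pheromone_mass": state.field.total_mass(config.dx),
    }
    if len(config.food_sources) >= 1:
        report["corridor_occupancy"] = [
            corridor_occupancy(state.positions, config.x0, s, half_width)
            for s in config.food_sources
        ]
        shares = winner_index(
            carrier_positions(state), config.x0, config.food_sources, half_width
        )
        report["winner_index"] = None if shares is None else [float(v) for v in shares]
    forg = forager_positions(state)
    if len(forg) >= 2:
        report["forager_spread"] = list(forager_spread(forg, config.x0))
    return report
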