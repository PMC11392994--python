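"""Macroscopic PDE model: forager density p, carrier density q, pheromone u.

The three coupled fields evolve on a cell-centred rectangular grid:

* p diffuses (coefficient alpha), drifts up the pheromone gradient with
  sensitivity chi (a conservative chemotaxis flux), and converts to q at
  the food sources;
* q is advected at speed nu straight toward the nest (first-order upwind)
  and converts back to p at the nest;
* u diffuses (coefficient D), evaporates (gamma), and is sourced by q with
  a Gaussian factor centred on each food source.

Diffusion is integrated with a Peaceman--Rachford alternating-direction
implicit (ADI) splitting; chemotaxis, advection and the conversion
exchange are explicit.  p and q satisfy no-flux (Neumann) boundaries so
the total ant mass is conserved to round-off; u uses the same Robin
("leaky") boundary closure as the lattice pheromone field.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .config import ContinuumParams


@dataclass
class ContinuumFields:
    """State of the three-field system plus conservation bookkeeping."""

    p: np.ndarray
    q: np.ndarray
    u: np.ndarray
    t: float
    mass0: float
    h: float

    @property
    def ant_mass(self) -> float:
        """Current total ant mass, integral of p + q."""
        return float((self.p.sum() + self.q.sum()) * self.h**2)

    @property
    def mass_drift(self) -> float:
        return self.ant_mass - self.mass0

    def copy(self) -> "ContinuumFields":
        return ContinuumFields(
            self.p.copy(), self.q.copy(), self.u.copy(), self.t, self.mass0, self.h
        )


def grid_coordinates(params: ContinuumParams):
    """Cell-centre coordinate vectors (xs, ys) of the solver grid."""
    nx, ny = params.shape
    xs = (np.arange(nx) + 0.5) * params.h
    ys = (np.arange(ny) + 0.5) * params.h
    return xs, ys


def mollified_delta(center, params: ContinuumParams) -> np.ndarray:
    """Discrete mollifier for a point mass at ``center``.

    A raised-cosine bump supported within ``params.delta_width`` of the
    centre, normalised so its discrete integral is exactly 1.  When the
    support is narrower than the grid spacing the nearest cell becomes a
    single-cell indicator of height 1/h^2.
    """
    cx, cy = float(center[0]), float(center[1])
    if not (0.0 <= cx <= params.Lx and 0.0 <= cy <= params.Ly):
        raise ValueError(f"mollifier centre {center} outside the domain")
    xs, ys = grid_coordinates(params)
    r = np.hypot(xs[:, None] - cx, ys[None, :] - cy)
    R = params.delta_width
    w = np.where(r < R, np.cos(np.pi * r / (2.0 * R)) ** 2, 0.0)
    total = w.sum() * params.h**2
    if total <= 0.0:
        # degenerate support: indicator on the nearest cell
        i = int(np.argmin(np.abs(xs - cx)))
        j = int(np.argmin(np.abs(ys - cy)))
        w = np.zeros((len(xs), len(ys)))
        w[i, j] = 1.0 / params.h**2
        return w
    return w / total


def _second_difference_banded(m: int, r: float, robin_ratio: float | None):
    """Banded form of (I - r L) for the 1D second-difference operator L.

    ``robin_ratio`` is h/D for the leaky Robin closure (ghost value
    c_ghost = c_b (1 - h/D)), or None for a reflecting Neumann closure.
    """
    ab = np.zeros((3, m))
    ab[0, 1:] = -r  # superdiagonal
    ab[2, :-1] = -r  # subdiagonal
    ab[1, :] = 1.0 + 2.0 * r
    edge = 1.0 + r if robin_ratio is None else 1.0 + r * (1.0 + robin_ratio)
    ab[1, 0] = edge
    ab[1, m - 1] = edge
    return ab


def _apply_L(f: np.ndarray, axis: int, robin_ratio: float | None) -> np.ndarray:
    """Apply the 1D second-difference operator along ``axis`` (unscaled)."""
    if axis == 1:
        return _apply_L(f.T, 0, robin_ratio).T
    out = np.empty_like(f)
    out[1:-1] = f[2:] - 2.0 * f[1:-1] + f[:-2]
    if robin_ratio is None:
        out[0] = f[1] - f[0]
        out[-1] = f[-2] - f[-1]
    else:
        out[0] = f[1] - (1.0 + robin_ratio) * f[0]
        out[-1] = f[-2] - (1.0 + robin_ratio) * f[-1]
    return out


class _ADISolver:
    """Peaceman--Rachford split implicit diffusion for one coefficient/BC."""

    def __init__(self, shape, coef, dt, h, robin_ratio):
        self.r = coef * dt / (2.0 * h**2)
        self.robin_ratio = robin_ratio
        nx, ny = shape
        self.abx = _second_difference_banded(nx, self.r, robin_ratio)
        self.aby = _second_difference_banded(ny, self.r, robin_ratio)

    def step(self, f: np.ndarray) -> np.ndarray:
        if self.r == 0.0:
            return f
        g = f + self.r * _apply_L(f, 1, self.robin_ratio)
        half = solve_banded((1, 1), self.abx, g)
        g = half + self.r * _apply_L(half, 0, self.robin_ratio)
        return solve_banded((1, 1), self.aby, g.T).T


@functools.lru_cache(maxsize=32)
class _Workspace:
    """Precomputed grids and solvers for one parameter set (cached)."""

    def __init__(self, params: ContinuumParams):
        self.params = params
        nx, ny = params.shape
        h, dt = params.h, params.dt
        self.xs, self.ys = grid_coordinates(params)
        self.adi_p = _ADISolver((nx, ny), params.alpha, dt, h, None)
        robin = h / params.D if params.D > 0 else None
        self.adi_u = _ADISolver((nx, ny), params.D, dt, h, robin)
        self.delta_nest = mollified_delta(params.x0, params)
        self.delta_food = sum(
            (mollified_delta(fs, params) for fs in params.food_sources),
            start=np.zeros((nx, ny)),
        )
        # Gaussian secretion factor of the u equation (unit decay length).
        self.source_gauss = np.zeros((nx, ny))
        for fx, fy in params.food_sources:
            r2 = (self.xs[:, None] - fx) ** 2 + (self.ys[None, :] - fy) ** 2
            self.source_gauss += np.exp(-r2)
        # Upwind face velocities of the nest-directed advection field.
        self.vx_face = np.zeros((nx + 1, ny))
        self.vy_face = np.zeros((nx, ny + 1))
        xf = np.arange(nx + 1) * h
        yf = np.arange(ny + 1) * h
        x0x, x0y = params.x0

        def unit_to_nest(px, py):
            dx = x0x - px
            dy = x0y - py
            r = np.hypot(dx, dy)
            with np.errstate(invalid="ignore", divide="ignore"):
                ex = np.where(r > 1e-12, dx / np.maximum(r, 1e-300), 0.0)
                ey = np.where(r > 1e-12, dy / np.maximum(r, 1e-300), 0.0)
            return ex, ey

        ex, _ = unit_to_nest(xf[1:-1, None], self.ys[None, :])
        self.vx_face[1:-1, :] = params.nu * ex
        _, ey = unit_to_nest(self.xs[:, None], yf[None, 1:-1])
        self.vy_face[:, 1:-1] = params.nu * ey


def conversion_exchange(p, q, params: ContinuumParams):
    """Mass exchanged in one step: returns (dp, dq) with dp = -dq.

    Foragers convert to carriers at rate Omega_pq under the food mollifier;
    carriers convert back at rate Omega_qp under the nest mollifier.
    """
    ws = _Workspace(params)
    t_pq = params.dt * params.Omega_pq * ws.delta_food * p
    t_qp = params.dt * params.Omega_qp * ws.delta_nest * q
    return t_qp - t_pq, t_pq - t_qp


def chemotaxis_divergence(p, u, params: ContinuumParams) -> np.ndarray:
    """div(chi (grad u) p) by centred conservative differencing, no-flux edges."""
    h = params.h
    nx, ny = p.shape
    Fx = np.zeros((nx + 1, ny))
    Fy = np.zeros((nx, ny + 1))
    gx = (u[1:, :] - u[:-1, :]) / h
    Fx[1:-1, :] = params.chi * gx * 0.5 * (p[1:, :] + p[:-1, :])
    gy = (u[:, 1:] - u[:, :-1]) / h
    Fy[:, 1:-1] = params.chi * gy * 0.5 * (p[:, 1:] + p[:, :-1])
    return (Fx[1:, :] - Fx[:-1, :]) / h + (Fy[:, 1:] - Fy[:, :-1]) / h


def advection_divergence(q, params: ContinuumParams) -> np.ndarray:
    """div(v q) with v the unit nest-directed field, first-order upwind."""
    ws = _Workspace(params)
    h = params.h
    nx, ny = q.shape
    Fx = np.zeros((nx + 1, ny))
    Fy = np.zeros((nx, ny + 1))
    vx = ws.vx_face[1:-1, :]
    Fx[1:-1, :] = np.maximum(vx, 0.0) * q[:-1, :] + np.minimum(vx, 0.0) * q[1:, :]
    vy = ws.vy_face[:, 1:-1]
    Fy[:, 1:-1] = np.maximum(vy, 0.0) * q[:, :-1] + np.minimum(vy, 0.0) * q[:, 1:]
    return (Fx[1:, :] - Fx[:-1, :]) / h + (Fy[:, 1:] - Fy[:, :-1]) / h


def step_p(fields: ContinuumFields, params: ContinuumParams,
           exchange=None) -> np.ndarray:
    """One step of the forager equation; returns the updated p grid.

    Explicit chemotaxis and conversion first, then ADI implicit diffusion.
    ``exchange`` may carry a pre-evaluated (dp, dq) pair so that a combined
    step charges the conversion exactly once to each field.
    """
    ws = _Workspace(params)
    if exchange is None:
        exchange = conversion_exchange(fields.p, fields.q, params)
    p = fields.p - params.dt * chemotaxis_divergence(fields.p, fields.u, params)
    p = p + exchange[0]
    return ws.adi_p.step(p)


def step_q(fields: ContinuumFields, params: ContinuumParams,
           exchange=None) -> np.ndarray:
    """One step of the carrier equation (upwind advection + conversion)."""
    if exchange is None:
        exchange = conversion_exchange(fields.p, fields.q, params)
    q = fields.q - params.dt * advection_divergence(fields.q, params)
    return q + exchange[1]


def step_u(fields: ContinuumFields, params: ContinuumParams) -> np.ndarray:
    """One step of the pheromone equation (decay + secretion, ADI diffusion)."""
    ws = _Workspace(params)
    u = fields.u + params.dt * (
        -params.gamma * fields.u + params.A_dep * fields.q * ws.source_gauss
    )
    return ws.adi_u.step(u)


def initial_fields(params: ContinuumParams) -> ContinuumFields:
    """Unit mass of foragers mollified at the nest; no carriers, no pheromone."""
    nx, ny = params.shape
    p = mollified_delta(params.x0, params)
    fields = ContinuumFields(
        p=p,
        q=np.zeros((nx, ny)),
        u=np.zeros((nx, ny)),
        t=0.0,
        mass0=0.0,
        h=params.h,
    )
    fields.mass0 = fields.ant_mass
    return fields


def advance(fields: ContinuumFields, params: ContinuumParams, n_steps: int) -> ContinuumFields:
    """March ``n_steps`` time steps in place (order: u, then q, then p)."""
    for _ in range(n_steps):
        exchange = conversion_exchange(fields.p, fields.q, params)
        u_new = step_u(fields, params)
        q_new = step_q(fields, params, exchange=exchange)
        fields.u = u_new
        p_new = step_p(fields, params, exchange=exchange)
        fields.p = p_new
        fields.q = q_new
        fields.t += params.dt
        if not np.isfinite(fields.p).all() or abs(fields.p).max() > 1e12:
            raise RuntimeError(
                f"continuum solve diverged at t = {fields.t:.4g} "
                f"(|p|max = {abs(fields.p).max():.3g}); reduce dt or chi"
            )
    return fields


def run_pde(params: ContinuumParams, T: float, snapshot_times=None):
    """Integrate the system to time ``T``; returns a list of snapshots.

    Snapshot times are rounded to the nearest step.  The final snapshot's
    ``mass_drift`` reports the conservation error of the whole run.
    """
    if snapshot_times is None:
        snapshot_times = [T]
    n_total = int(round(T / params.dt))
    snap_steps = sorted({min(n_total, max(0, int(round(t / params.dt)))) for t in snapshot_times})
    fields = initial_fields(params)
    out = []
    done = 0
    for s in snap_steps:
        advance(fields, params, s - done)
        done = s
        snap = fields.copy()
        snap.t = s * params.dt
        out.append(snap)
    return out
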