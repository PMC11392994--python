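"""Linear stability of the space-averaged three-field system.

Averaging the conversion deltas and the pheromone source of the continuum
model over the domain gives a constant-coefficient system for (p, q, u)
whose homogeneous equilibrium can be destabilised by the chemotaxis--
secretion feedback loop.  This module builds the equilibrium, assembles
the 3x3 linearisation for a plane-wave perturbation exp(i k.x + lambda t),
solves the det(A) = 0 dispersion relation (a monic cubic in lambda), and
drives parameter sweeps over the growth-rate surface.

A positive real part of any root signals instability of the uniform state
-- the onset of trail formation; k = 0 always carries a zero root (total
ant mass is conserved), so instability scans exclude the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .config import AveragedParams


def erf_factor(x_f, M: float, N: float) -> float:
    """Error-function factor of the averaged pheromone source.

    E(x_f) = (erf(x_f1) - erf(x_f1 - N)) * (erf(x_f2) - erf(x_f2 - M)),
    the exact integral of the unit-width Gaussian secretion kernel over
    the rectangular domain, up to the pi/4 prefactor kept elsewhere.
    For a source a few lengths inside a large domain E ~ 4.
    """
    xf1, xf2 = float(x_f[0]), float(x_f[1])
    return float((erf(xf1) - erf(xf1 - N)) * (erf(xf2) - erf(xf2 - M)))


def homogeneous_equilibrium(params: AveragedParams) -> tuple[float, float, float]:
    """Uniform stationary state (p_h, q_h, u_h) of the averaged system.

    Satisfies the normalisation identity MN (p_h + q_h) = 1 exactly, and
    recovers (1/MN, 0, 0) in the no-food limit Omega_pq -> 0,
    Omega_qp -> inf, E -> 0.
    """
    G = params.Gamma
    MN = params.MN
    p_h = G * MN / params.Omega_pq
    q_h = G * MN / params.Omega_qp
    if params.gamma <= 0:
        raise ValueError("homogeneous equilibrium requires gamma > 0")
    u_h = G * params.A_dep * np.pi * params.E_val / (4.0 * params.gamma * params.Omega_qp)
    return (p_h, q_h, u_h)


def averaged_rhs(p: float, q: float, u: float, params: AveragedParams) -> tuple[float, float, float]:
    """Right-hand side of the averaged system for spatially uniform fields.

    All gradient terms vanish for uniform fields, leaving the conversion
    exchange and the pheromone balance; used to verify equilibria.
    """
    MN = params.MN
    a = params.Omega_pq / MN
    b = params.Omega_qp / MN
    dp = -a * p + b * q
    dq = a * p - b * q
    du = -params.gamma * u + params.A_dep * np.pi * params.E_val / (4.0 * MN) * q
    return (dp, dq, du)


def _coefficient_matrix(k, params: AveragedParams) -> np.ndarray:
    """The lambda-free part B of the linearisation A = lambda I + B."""
    k1, k2 = float(k[0]), float(k[1])
    k2norm = k1 * k1 + k2 * k2
    MN = params.MN
    a = params.Omega_pq / MN
    b = params.Omega_qp / MN
    e1, e2 = params.e_hat
    ek = e1 * k1 + e2 * k2
    chem = params.Gamma * params.chi * MN / params.Omega_pq * k2norm
    w = params.A_dep * np.pi * params.E_val / (4.0 * MN)
    return np.array(
        [
            [params.alpha * k2norm + a, -b, -chem],
            [-a, -1j * params.nu * ek + b, 0.0],
            [0.0, -w, params.gamma + params.D * k2norm],
        ],
        dtype=complex,
    )


def assemble_matrix(k, lam: complex, params: AveragedParams) -> np.ndarray:
    """The 3x3 plane-wave linearisation matrix A(k, lambda).

    Row order (p, q, u); det(A) = 0 is the dispersion relation.
    """
    return lam * np.eye(3, dtype=complex) + _coefficient_matrix(k, params)


def dispersion_cubic(k, params: AveragedParams) -> np.ndarray:
    """Coefficients [1, c2, c1, c0] of det(A) as a monic cubic in lambda."""
    B = _coefficient_matrix(k, params)
    c2 = np.trace(B)
    c1 = (
        B[0, 0] * B[1, 1]
        - B[0, 1] * B[1, 0]
        + B[0, 0] * B[2, 2]
        - B[0, 2] * B[2, 0]
        + B[1, 1] * B[2, 2]
        - B[1, 2] * B[2, 1]
    )
    c0 = np.linalg.det(B)
    return np.array([1.0, c2, c1, c0], dtype=complex)


def dispersion_roots(k, params: AveragedParams) -> np.ndarray:
    """All three roots lambda(k) of the dispersion relation at one wavevector.

    The cubic is solved through its companion matrix (np.roots); each root
    is checked against |det A| with a small relative residual.
    """
    coeffs = dispersion_cubic(k, params)
    roots = np.roots(coeffs)
    scale = max(1.0, float(np.abs(coeffs).max()))
    for lam in roots:
        resid = abs(np.polyval(coeffs, lam))
        if not np.isfinite(resid) or resid > 1e-6 * scale * max(1.0, abs(lam)) ** 3:
            # fall back to the eigen-solve of -B, which is backward stable
            return np.linalg.eigvals(-_coefficient_matrix(k, params))
    return roots


@dataclass
class DispersionResult:
    """Growth-rate surface over a wavevector grid."""

    k_grid: np.ndarray  # (m, 2)
    roots: np.ndarray  # (m, 3) complex
    max_re: float
    argmax_k: tuple[float, float]


def wavevector_grid(k_max: float, n_k: int, include_zero: bool = False) -> np.ndarray:
    """Uniform (2 n_k + 1)^2 grid over [-k_max, k_max]^2, origin optional.

    The k = 0 mode always carries an exact zero root (mass conservation),
    so instability scans drop it by default.
    """
    ks = np.linspace(-k_max, k_max, 2 * n_k + 1)
    k1, k2 = np.meshgrid(ks, ks, indexing="ij")
    grid = np.column_stack([k1.ravel(), k2.ravel()])
    if not include_zero:
        grid = grid[~np.all(grid == 0.0, axis=1)]
    return grid


def dispersion_surface(k_grid: np.ndarray, params: AveragedParams) -> np.ndarray:
    """Roots at every wavevector, batched eigenvalue solve of -B(k)."""
    k_grid = np.atleast_2d(np.asarray(k_grid, dtype=float))
    m = len(k_grid)
    B = np.zeros((m, 3, 3), dtype=complex)
    k1 = k_grid[:, 0]
    k2 = k_grid[:, 1]
    k2norm = k1 * k1 + k2 * k2
    MN = params.MN
    a = params.Omega_pq / MN
    b = params.Omega_qp / MN
    e1, e2 = params.e_hat
    ek = e1 * k1 + e2 * k2
    w = params.A_dep * np.pi * params.E_val / (4.0 * MN)
    B[:, 0, 0] = params.alpha * k2norm + a
    B[:, 0, 1] = -b
    B[:, 0, 2] = -params.Gamma * params.chi * MN / params.Omega_pq * k2norm
    B[:, 1, 0] = -a
    B[:, 1, 1] = -1j * params.nu * ek + b
    B[:, 2, 1] = -w
    B[:, 2, 2] = params.gamma + params.D * k2norm
    return np.linalg.eigvals(-B)


def max_growth_rate(params: AveragedParams, k_grid: np.ndarray) -> DispersionResult:
    """Maximum Re(lambda) over the grid and the wavevector attaining it."""
    k_grid = np.atleast_2d(np.asarray(k_grid, dtype=float))
    if len(k_grid) == 0:
        raise ValueError("max_growth_rate needs a nonempty wavevector grid")
    roots = dispersion_surface(k_grid, params)
    re = roots.real.max(axis=1)
    i = int(np.argmax(re))
    return DispersionResult(
        k_grid=k_grid,
        roots=roots,
        max_re=float(re[i]),
        argmax_k=(float(k_grid[i, 0]), float(k_grid[i, 1])),
    )


_SWEEPABLE = ("alpha", "chi", "nu", "Omega_pq", "Omega_qp", "D", "gamma", "A_dep")


def parameter_sweep(param_name: str, values, params: AveragedParams, k_grid: np.ndarray):
    """Growth-rate summary per value of one swept rate parameter.

    Returns a list of dicts (value, max_re, argmax_k1, argmax_k2), ready
    for CSV serialisation.
    """
    if param_name not in _SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {param_name!r}; choose from {_SWEEPABLE}")
    from dataclasses import replace

    out = []
    for v in values:
        res = max_growth_rate(replace(params, **{param_name: float(v)}), k_grid)
        out.append(
            {
                "value": float(v),
                "max_re": res.max_re,
                "argmax_k1": res.argmax_k[0],
                "argmax_k2": res.argmax_k[1],
            }
        )
    return out


def default_params(**overrides) -> AveragedParams:
    """Baseline averaged parameters for dispersion studies.

    A 10x10 domain with the nest and food six lengths apart; rate
    constants unity, pheromone parameters at their simulation values.  At
    this size the secretion amplitude threshold for instability sits just
    above A = 5, so moderate increases in A (or decreases in gamma or D)
    cross from a stable uniform state to a trail-forming one.
    """
    base = dict(
        M=10.0,
        N=10.0,
        x0=(2.0, 5.0),
        x_f=(8.0, 5.0),
        alpha=1.0,
        chi=1.0,
        nu=1.0,
        Omega_pq=1.0,
        Omega_qp=1.0,
        D=10.0,
        gamma=0.001,
        A_dep=1.0,
    )
    base.update(overrides)
    return AveragedParams(**base)
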