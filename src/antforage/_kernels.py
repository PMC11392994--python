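"""Numba-compiled primitives for the stochastic lattice model.

All positions are 1-based lattice pairs (x, y) with x in 1..M, y in 1..N;
the concentration grid ``c`` has shape (M, N) and ``c[x-1, y-1]`` is the
pheromone at site (x, y).  The same jitted primitives back both the public
single-step operations and the fused simulation loop, so unit tests of the
small operations exercise exactly the code the full run executes.

Draw order of the random generator, per ant-move event: one integer draw
selects the ant, then one uniform draw selects a forager's move (carriers
draw nothing).  The pre-discovery walk uses the same code path (all weights
equal 1 on a zero field), so the number of draws per event is constant.
"""

import numpy as np
from numba import njit

FORAGER = 0
CARRIER = 1

# Fixed, row-major enumeration of the Moore offsets.
_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@njit(cache=True)
def neighbors(x, y, M, N, out):
    """Write the in-bounds Moore neighbours of (x, y) into ``out``; return count."""
    cnt = 0
    for k in range(8):
        nx = x + _OFFSETS[k, 0]
        ny = y + _OFFSETS[k, 1]
        if 1 <= nx <= M and 1 <= ny <= N:
            out[cnt, 0] = nx
            out[cnt, 1] = ny
            cnt += 1
    return cnt


@njit(cache=True)
def forager_weights(x, y, c, eps, floor, weber, nb, cnt, w):
    """Gradient-sensing move weights over the ``cnt`` neighbours in ``nb``.

    The paired-antennae comparison has a just-noticeable difference
    max(floor, weber * (c_a + c_0)): an absolute detection floor plus a
    Weber's-law relative term.  A concentration pair closer than that
    counts as equal, so an ant cannot climb arbitrarily faint gradients
    and keeps performing an unbiased walk in shallow parts of the field.
    """
    c0 = c[x - 1, y - 1]
    total = 0.0
    for i in range(cnt):
        ca = c[nb[i, 0] - 1, nb[i, 1] - 1]
        dc = ca - c0
        jnd = weber * (ca + c0)
        if jnd < floor:
            jnd = floor
        if -jnd < dc < jnd:
            dc = 0.0
        if dc < 0.0:
            w[i] = eps
        elif dc == 0.0:
            w[i] = 1.0
        else:
            w[i] = 1.0 + dc
        total += w[i]
    return total


@njit(cache=True)
def beeline_step(x, y, tx, ty):
    """First neighbour entered by the ray from (x, y) toward (tx, ty).

    The ray leaves the unit cell through a vertical face when the target
    direction's |x|-component dominates, a horizontal face when the
    |y|-component dominates, and exactly through the corner when they tie,
    in which case the diagonal neighbour is taken.
    """
    ax = tx - x
    ay = ty - y
    sx = 0
    if ax > 0:
        sx = 1
    elif ax < 0:
        sx = -1
    sy = 0
    if ay > 0:
        sy = 1
    elif ay < 0:
        sy = -1
    aax = ax if ax >= 0 else -ax
    aay = ay if ay >= 0 else -ay
    if aax > aay:
        return x + sx, y
    elif aay > aax:
        return x, y + sy
    else:
        return x + sx, y + sy


@njit(cache=True)
def deposition_rate(x, y, food, A, sigma, src_idx, sum_all):
    """Secretion rate of a carrier at (x, y): Gaussian decay from the source(s)."""
    rate = 0.0
    K = food.shape[0]
    for k in range(K):
        if not sum_all and k != src_idx:
            continue
        dx = float(x - food[k, 0])
        dy = float(y - food[k, 1])
        r = np.sqrt(dx * dx + dy * dy)
        rate += A * np.exp(-((r / sigma) ** 2))
    return rate


@njit(cache=True)
def pheromone_diffuse_decay(c, cn, D, gamma, dt, dx):
    """One forward-Euler step of diffusion + evaporation into ``cn``.

    The Robin (homogeneous Fourier-type) boundary closure uses a ghost cell
    c_ghost = c_b * (1 - dx/D), the first-order discretisation of
    D dc/dn_out = -c: the chemical keeps flowing out with its gradient.
    """
    M, N = c.shape
    inv_dx2 = 1.0 / (dx * dx)
    if D > 0.0:
        g = 1.0 - dx / D
        for i in range(M):
            for j in range(N):
                cc = c[i, j]
                left = c[i - 1, j] if i > 0 else cc * g
                right = c[i + 1, j] if i < M - 1 else cc * g
                down = c[i, j - 1] if j > 0 else cc * g
                up = c[i, j + 1] if j < N - 1 else cc * g
                lap = (left + right + down + up - 4.0 * cc) * inv_dx2
                cn[i, j] = cc + dt * (D * lap - gamma * cc)
    else:
        for i in range(M):
            for j in range(N):
                cn[i, j] = c[i, j] * (1.0 - dt * gamma)


@njit(cache=True)
def deposit(cn, pos, mode, src, food, A, sigma, dt, dx, sum_all):
    """Add one field step's worth of carrier secretion (discrete deltas)."""
    n = pos.shape[0]
    inv_dx2 = 1.0 / (dx * dx)
    for i in range(n):
        if mode[i] == CARRIER:
            rate = deposition_rate(pos[i, 0], pos[i, 1], food, A, sigma, src[i], sum_all)
            cn[pos[i, 0] - 1, pos[i, 1] - 1] += dt * rate * inv_dx2


@njit(cache=True)
def _chebyshev(x, y, tx, ty):
    ax = x - tx if x >= tx else tx - x
    ay = y - ty if y >= ty else ty - y
    return ax if ax >= ay else ay


@njit(cache=True)
def run_lattice(
    M,
    N,
    n,
    x0x,
    x0y,
    food,  # (K, 2) int64, may be empty
    D,
    gamma,
    A,
    sigma,
    eps,
    floor,
    weber,
    dt,
    dx,
    T_max,
    seed,
    snap_units,  # sorted int64 array of snapshot times (time units)
    adaptive_beeline,
    sum_all_sources,
):
    """Run the full lattice simulation; returns snapshots and trip records.

    One unit of time = ``n`` ant-move events (ant chosen uniformly with
    replacement).  Once any food source has been discovered, round(1/dt)
    pheromone forward-Euler steps per unit are interleaved, distributed
    evenly over the events with each batch executed *before* the ant event
    it precedes (field first, then movement).
    """
    np.random.seed(seed)

    pos = np.empty((n, 2), dtype=np.int64)
    for i in range(n):
        pos[i, 0] = x0x
        pos[i, 1] = x0y
    mode = np.zeros(n, dtype=np.int8)
    src = np.full(n, -1, dtype=np.int64)
    steps_since = np.zeros(n, dtype=np.int64)
    conv_cheb = np.zeros(n, dtype=np.int64)

    c = np.zeros((M, N), dtype=np.float64)
    cn = np.zeros((M, N), dtype=np.float64)

    K = food.shape[0]
    m_field = max(1, int(round(1.0 / dt)))

    S = snap_units.shape[0]
    snap_pos = np.zeros((S, n, 2), dtype=np.int64)
    snap_mode = np.zeros((S, n), dtype=np.int8)
    snap_steps = np.zeros((S, n), dtype=np.int64)
    snap_field = np.zeros((S, M, N), dtype=np.float64)

    # Each completed nest-return is one row: (chebyshev at conversion, moves).
    trips_cap = n * T_max + 1
    trips = np.zeros((trips_cap, 2), dtype=np.int64)
    n_trips = 0

    nb = np.empty((8, 2), dtype=np.int64)
    w = np.empty(8, dtype=np.float64)

    active = False
    discovery_time = -1.0
    si = 0
    while si < S and snap_units[si] == 0:
        snap_pos[si] = pos
        snap_mode[si] = mode
        snap_steps[si] = steps_since
        snap_field[si] = c
        si += 1

    for t in range(1, T_max + 1):
        for j in range(n):
            if active:
                k_j = ((j + 1) * m_field) // n - (j * m_field) // n
                for _ in range(k_j):
                    pheromone_diffuse_decay(c, cn, D, gamma, dt, dx)
                    deposit(cn, pos, mode, src, food, A, sigma, dt, dx, sum_all_sources)
                    tmp = c
                    c = cn
                    cn = tmp
            i = np.random.randint(0, n)
            x = pos[i, 0]
            y = pos[i, 1]
            if mode[i] == FORAGER:
                cnt = neighbors(x, y, M, N, nb)
                total = forager_weights(x, y, c, eps, floor, weber, nb, cnt, w)
                r = np.random.random() * total
                acc = 0.0
                pick = cnt - 1
                for a in range(cnt):
                    acc += w[a]
                    if r < acc:
                        pick = a
                        break
                pos[i, 0] = nb[pick, 0]
                pos[i, 1] = nb[pick, 1]
                for k in range(K):
                    if pos[i, 0] == food[k, 0] and pos[i, 1] == food[k, 1]:
                        mode[i] = CARRIER
                        src[i] = k
                        steps_since[i] = 0
                        conv_cheb[i] = _chebyshev(pos[i, 0], pos[i, 1], x0x, x0y)
                        if not active:
                            active = True
                            discovery_time = (t - 1) + (j + 1) / n
                        break
            else:
                if adaptive_beeline:
                    tx, ty = x0x, x0y
                else:
                    # Extend the constant nest-minus-food vector; fall back to
                    # re-aiming at the nest if that ray has left the lattice.
                    tx = x + (x0x - food[src[i], 0])
                    ty = y + (x0y - food[src[i], 1])
                    if tx == x and ty == y:
                        tx, ty = x0x, x0y
                nxp, nyp = beeline_step(x, y, tx, ty)
                if nxp < 1 or nxp > M or nyp < 1 or nyp > N:
                    nxp, nyp = beeline_step(x, y, x0x, x0y)
                pos[i, 0] = nxp
                pos[i, 1] = nyp
                steps_since[i] += 1
                if nxp == x0x and nyp == x0y:
                    if n_trips < trips_cap:
                        trips[n_trips, 0] = conv_cheb[i]
                        trips[n_trips, 1] = steps_since[i]
                        n_trips += 1
                    mode[i] = FORAGER
                    src[i] = -1
        while si < S and snap_units[si] == t:
            snap_pos[si] = pos
            snap_mode[si] = mode
            snap_steps[si] = steps_since
            snap_field[si] = c
            si += 1

    return snap_pos, snap_mode, snap_steps, snap_field, trips[:n_trips], discovery_time
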