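# Methods

## Scope and assumptions

The package models a single colony foraging from a nest toward point food
sources with infinite reservoirs, over a time horizon short enough that
births and deaths are ignored. Ants are identical points with no
orientation state, no memory and no direct interactions; the only coupling
is the secreted pheromone field. Two ant modes exist: foragers (random
walk, gradient-biased when pheromone is perceptible) and carriers
(deterministic beeline to the nest, secreting). Mode conversion happens
only on a food site (forager to carrier) and on the nest site (carrier to
forager).

## Lattice model

* **Clock.** One unit of time is `n` single-ant move events, each moving
  one uniformly chosen ant (with replacement). Once any food source has
  been discovered, `round(1/dt)` forward-Euler pheromone steps per time
  unit are interleaved, distributed evenly over the events with the field
  step(s) executed before the ant event they precede. With the standard
  values (`n = 1000`-scale colonies, `dt = 0.001`) this is exactly one
  field step per ant event.
* **Random numbers.** A single generator drives everything in a fixed draw
  order per event: one integer draw (ant selection), then one uniform draw
  if the selected ant is a forager. Carriers consume no randomness, and the
  pre-discovery walk uses the same code path as the biased walk (on a zero
  field all weights are 1), so the draw count per event is constant and
  `(config, seed)` reproduces runs bit-for-bit.
* **Beeline.** The carrier step follows the ray from the current cell
  centre toward the nest: the neighbour whose face the ray crosses first,
  with exact corner crossings taking the diagonal. This contracts the
  Chebyshev distance to the nest by exactly 1 per move — completed returns
  always take exactly `d_Chebyshev(conversion site, nest)` moves, which the
  tests assert exactly. The direction is re-aimed at the nest every move; a
  literal fixed-vector variant (`beeline="fixed"`, extending the constant
  nest-minus-food direction) is available and falls back to re-aiming when
  its ray leaves the lattice.
* **Boundaries.** Ant moves are restricted to in-bounds Moore neighbours
  (reflecting walls, population conserved). The pheromone uses a Robin
  closure via the ghost value `c_ghost = c_b (1 - dx/D)`, the first-order
  discretisation of `D dc/dn_out = -c`: chemical keeps leaving with its
  gradient. This gives an exact discrete budget — with evaporation and
  secretion off, the mass lost per step equals `dt` times the sum of
  boundary-face concentrations — which is asserted to 1e-9.
* **Stability.** `D dt / dx^2 <= 1/4` is enforced at configuration time
  (the standard values give 0.01); under it the field stays nonnegative.

### Parameters and sensing

| parameter | default | meaning |
| --- | --- | --- |
| `D` | 10 | pheromone diffusivity (lattice units^2 / time) |
| `gamma` | 0.001 | evaporation rate (1/time) |
| `A_dep` | 1 | secretion amplitude at the food source |
| `sigma_decay` | 1 | decay length of secretion with distance from the source |
| `epsilon` | 0.001 | weight of a perceptibly down-gradient move |
| `sense_threshold` | 0.002 | detection floor on concentration differences |
| `weber_fraction` | 0 | optional relative (Weber-law) component of the floor |
| `dt` | 0.001 | pheromone time step |

The biological table behind these values is internally inconsistent for
`gamma` (its dimensionless value does not match its quoted physical rate
under the time scale implied by `D`); we use the prescribed dimensionless
value. `epsilon` and the detection threshold are distinct roles of one
"estimated" parameter: `epsilon` keeps ants from freezing on local maxima,
while `sense_threshold` models the minimum signal an antenna pair can
resolve — differences below `max(sense_threshold, weber_fraction * (c_a +
c_0))` count as equal and leave the walk unbiased. The floor matters: with
`sense_threshold = 0` a forager will climb concentration differences of
1e-6 and below, and the halo of the first discovered source (which spreads
at diffusion speed, much faster than the ant cloud) deterministically
funnels the entire colony before any other source can be found. The
default 0.002 is the largest value that leaves single-trail formation
robust at the preset scale (distance 15, occupancy ~0.98); by 0.005
ignition at that distance already fails. It is far below trail-scale
concentrations (0.2–6), so it only affects behaviour at minute signal
levels.

### Scenario presets and what they show

* `one_food` — 50x50, n=500, source 15 sites from the nest, T=300. A
  corridor trail forms after a ~30–50-unit diffusive search phase;
  corridor occupancy (half-width 3) reaches ~0.98–0.99 across seeds.
* `two_unequal` — 51x51, sources at distances 12 and 15 on opposite sides,
  T=600 (the longer horizon lets the transient resolve). The proximal
  source ends with 100% of the corridor-assigned carriers in every seed.
* `two_equidistant` — 51x51, sources at distance 15 on opposite sides,
  T=300, nest at the exact lattice centre so the scenario's mirror
  symmetry is exact.

**Known limitation (two-source competition is winner-take-all).** In this
model the symmetric two-trail state for equidistant sources is not stable:
when both sources ignite, the trails coexist only transiently (tens of
time units) before the nest-junction feedback — re-emerging foragers climb
the momentarily steeper superposed gradient, and `epsilon` suppresses
moves down it — hands the whole colony to one trail, chosen at random.
We probed this systematically (down-gradient weight 0.001–0.2, detection
floors 0–0.02, Weber fractions 0–0.2, evaporation 0.001–0.1, distances
5–40, source separations 23–180 degrees, colonies of 500–2000 ants,
domains up to 151x151, horizons to 2000 units): the collapse is robust.
This is the classic outcome for memoryless trail models with effectively
saturating choice at a junction; persistent multi-trail foraging in real
colonies is generally attributed to individual-level site fidelity, which
this model deliberately omits. The equidistant preset therefore shows a
quasistationary double trail followed by winner-take-all, and the test
asserting persistent coexistence fails by design rather than being
weakened. The unequal-distance prediction — all ants converge on the
closer source — is reproduced robustly, trivially so at larger distance
gaps where the distal source is never even discovered.

## Continuum model

Cell-centred grid on `[0, Lx] x [0, Ly]`, spacing `h`. Per step (order:
pheromone, carriers, foragers, so the new pheromone drives the same step's
chemotaxis): explicit decay + secretion then Peaceman–Rachford ADI
diffusion for `u`; first-order upwind flux-form advection for `q`;
explicit conservative chemotaxis flux then ADI diffusion for `p`. The
conversion exchange is evaluated once per step on the entering fields and
added antisymmetrically to `p` and `q`, so with Neumann (zero-flux)
boundaries the total ant mass is conserved to round-off (measured drift
~1e-12 over 10^4 steps). Point masses (the initial forager distribution at
the nest and the conversion deltas) are raised-cosine mollifiers of radius
`delta_width` (default 2h), normalised to unit discrete integral; a
sub-grid radius degenerates to a single-cell indicator.

Numerical notes: the nest-directed unit field `v` is evaluated at cell
faces and set to zero within 1e-12 of the nest. The upwind CFL bound `nu
dt / h <= 1` is enforced at configuration time; the explicit chemotaxis
term is monitored at run time via a divergence check (field blow-up aborts
with a diagnostic). The centred chemotaxis flux is second-order but not
positivity-preserving: strong feedback (large `chi A`) can produce small
negative forager-density undershoots (~1e-4 of the peak) near sharp
ridges; a ridge is visible once `chi A` is large enough for the
chemotactic drift to beat the conversion sink at the source (e.g. `chi =
20, A = 500` on a 16x16 domain with unit ant mass), consistent with the
averaged-system threshold below. The semi-discrete 5-point Laplacian
reproduces the heat-kernel variance growth `2 alpha t` exactly in the
interior, so the ADI solver's variance error (~1e-10 relative) measures
pure time-splitting error.

## Averaged system and dispersion

Replacing the conversion deltas by their spatial means `Omega/(MN)` and
the secretion kernel by its domain integral (`pi/4 E(x_f)`, a product of
error-function differences) gives a constant-coefficient system. Its
homogeneous equilibrium satisfies `MN (p_h + q_h) = 1` identically, and
the no-food limit recovers the uniform forager state. The plane-wave
linearisation is a 3x3 matrix whose determinant is a monic cubic in
`lambda`; roots are computed through the companion matrix, with a batched
eigenvalue solve of the equivalent `-B(k)` matrix for grid scans and an
automatic fallback to it if the polynomial residual is poor. One matrix
entry couples the carrier advection as `-i nu (e.k)` with `e` the unit
nest-minus-food direction; the opposite sign convention (our independent
re-derivation) maps `k` to `-k` and conjugates the root set, leaving every
real part — hence every stability statement — unchanged.

At `k = 0` the cubic factors exactly into `{0, -(Opq+Oqp)/MN, -gamma}`
(the zero root is total-mass conservation). The instability window, when
present, sits at low wavenumber: to leading order the uniform state is
unstable where `alpha b (gamma + D k^2) < Gamma chi A pi E / (4 MN)` with
`b = Oqp/MN`, giving a critical secretion amplitude `A_crit = 4 alpha
gamma Oqp (MN)^2 (1/Opq + 1/Oqp) / (chi pi E)`. With the default baseline
(10x10 domain, unit rates, standard pheromone values) `A_crit ~ 6.4`: `A =
5` is stable at every wavevector while `A = 10` has a positive-growth
window below `|k| ~ 0.015`. Default scans therefore use `k_max = 0.05`
with a 101x101 grid (origin excluded), which resolves that window.
Increasing `D` or `gamma` shrinks it monotonically; `nu` has exactly no
effect on the maximum growth rate here because the most unstable mode is
perpendicular to `e` (the advection term enters through `e.k` only).

## Metrics

A *corridor* is the set of points within a half-width (default 3 lattice
units, configurable — an artifact definition, not an observed quantity) of
the straight nest–source segment. `corridor_occupancy` is the fraction of
ants (or density mass) inside it; `winner_index` assigns each carrier
inside at least one corridor to the nearest segment (lowest index on ties)
and reports per-source shares that sum to 1, returning the undefined flag
(`None`) when no carrier is in any corridor. `forager_spread` is the
second moment of positions about the nest (not the sample mean), matching
the unbiased-Moore-walk law `Var = 0.75 t` per axis (each of the 8 offsets
has probability 1/8, so `E[dx^2] = 6/8`). All metrics are pure functions
of snapshots.

## What the tests do and do not show

The stochastic scenarios run at deliberately reduced scale (50x50 with 500
ants rather than metre-scale arenas with 10^3–10^6 ants) so the whole
suite completes in about a minute; the documented phenomenology (search
phase, recruitment, corridor trails, proximal-source takeover) is robust
at this scale, but quantitative values such as discovery times and final
carrier counts are scale-dependent. The generator produces ideal
conditions — no terrain, no ant–ant exclusion, infinite food, a single
pheromone — so passing tests validate the self-organisation mechanism, not
agreement with any specific field experiment.
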