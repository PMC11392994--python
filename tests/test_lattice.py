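"""Unit and property tests of the stochastic lattice model."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from antforage import lattice
from antforage.config import ConfigError, ScenarioConfig
from antforage.lattice import (
    AntState,
    PheromoneField,
    boundary_outflow,
    carrier_step,
    deposition_rate,
    forager_move_distribution,
    moore_neighborhood,
    pheromone_step,
    simulate,
    update_mode,
)


def cfg(M=10, N=10, **kw):
    kw.setdefault("n", 10)
    kw.setdefault("x0", (3, 3))
    kw.setdefault("food_sources", [(8, 8)])
    kw.setdefault("T_max", 10)
    return ScenarioConfig(M=M, N=N, **kw)


class TestMooreNeighborhood:
    @pytest.mark.parametrize(
        "pos, expected_count",
        [((5, 5), 8), ((1, 1), 3), ((1, 5), 5), ((10, 10), 3), ((10, 4), 5)],
    )
    def test_counts(self, pos, expected_count):
        assert len(moore_neighborhood(pos, cfg())) == expected_count

    def test_corner_sites(self):
        assert set(moore_neighborhood((1, 1), cfg())) == {(1, 2), (2, 1), (2, 2)}

    def test_excludes_self_and_stays_in_bounds(self):
        c = cfg()
        for pos in [(1, 1), (5, 5), (10, 1), (3, 10)]:
            nb = moore_neighborhood(pos, c)
            assert pos not in nb
            assert all(1 <= x <= 10 and 1 <= y <= 10 for x, y in nb)
            assert all(max(abs(x - pos[0]), abs(y - pos[1])) == 1 for x, y in nb)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            moore_neighborhood((0, 5), cfg())


class TestForagerMoveDistribution:
    def test_uniform_on_zero_field(self):
        c = cfg()
        probs = forager_move_distribution((5, 5), PheromoneField.zeros(c), c)
        assert np.allclose(probs, 1 / 8)
        assert abs(probs.sum() - 1) < 1e-12

    def test_local_maximum_is_uniform(self):
        # every neighbour is perceptibly downhill -> all weights epsilon
        c = cfg()
        f = PheromoneField.zeros(c)
        f.c[4, 4] = 5.0  # site (5,5)
        probs = forager_move_distribution((5, 5), f, c)
        assert np.allclose(probs, 1 / 8)

    def test_weighted_example(self):
        # one neighbour +0.5, one -0.2, six flat; eps = 0.001:
        # weights {1.5, 0.001, 1 x 6}, denominator 7.501
        c = cfg(epsilon=0.001, sense_threshold=0.0)
        f = PheromoneField.zeros(c)
        f.c[4, 5] = 0.5  # neighbour (5,6): up-gradient
        f.c[4, 3] = -0.2  # neighbour (5,4): down-gradient
        probs = forager_move_distribution((5, 5), f, c)
        nb = moore_neighborhood((5, 5), c)
        p_up = probs[nb.index((5, 6))]
        p_down = probs[nb.index((5, 4))]
        assert p_up == pytest.approx(1.5 / 7.501, rel=1e-12)
        assert p_down == pytest.approx(0.001 / 7.501, rel=1e-12)

    def test_subthreshold_difference_is_neutral(self):
        c = cfg(sense_threshold=0.01)
        f = PheromoneField.zeros(c)
        f.c[4, 5] = 0.005  # below the detection floor
        probs = forager_move_distribution((5, 5), f, c)
        assert np.allclose(probs, 1 / 8)

    def test_nan_field_rejected(self):
        c = cfg()
        f = PheromoneField.zeros(c)
        f.c[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            forager_move_distribution((5, 5), f, c)

    @given(
        x=hst.integers(1, 10),
        y=hst.integers(1, 10),
        seed=hst.integers(0, 10_000),
    )
    def test_normalised_for_random_fields(self, x, y, seed):
        c = cfg()
        rng = np.random.default_rng(seed)
        f = PheromoneField(c=rng.random((10, 10)) * 3)
        probs = forager_move_distribution((x, y), f, c)
        assert abs(probs.sum() - 1) < 1e-12
        assert (probs >= 0).all()
        assert len(probs) == len(moore_neighborhood((x, y), c))


class TestCarrierStep:
    @pytest.mark.parametrize(
        "pos, nest, expected",
        [
            ((5, 5), (1, 1), (4, 4)),  # exact diagonal -> diagonal move
            ((2, 1), (1, 1), (1, 1)),  # adjacent to nest
            ((7, 3), (1, 1), (6, 3)),  # shallow ray exits through the left face
        ],
    )
    def test_examples(self, pos, nest, expected):
        assert carrier_step(pos, cfg(x0=nest, food_sources=[(9, 9)])) == expected

    def test_at_nest_is_error(self):
        with pytest.raises(ValueError):
            carrier_step((3, 3), cfg())

    @given(
        px=hst.integers(1, 30),
        py=hst.integers(1, 30),
        nx=hst.integers(1, 30),
        ny=hst.integers(1, 30),
    )
    def test_chebyshev_contraction(self, px, py, nx, ny):
        if (px, py) == (nx, ny):
            return
        c = ScenarioConfig(M=30, N=30, n=1, x0=(nx, ny), food_sources=[], T_max=1)
        d0 = max(abs(px - nx), abs(py - ny))
        pos = (px, py)
        for _ in range(d0):
            pos = carrier_step(pos, c)
            d1 = max(abs(pos[0] - nx), abs(pos[1] - ny))
            assert d1 == d0 - 1
            d0 = d1
        assert pos == (nx, ny)


class TestDepositionRate:
    def test_carrier_on_source(self):
        c = cfg(A_dep=1.0, sigma_decay=1.0)
        ant = AntState(pos=(8, 8), mode="carrier")
        assert deposition_rate(ant, c) == pytest.approx(1.0)

    def test_distance_two(self):
        c = cfg(food_sources=[(8, 8)])
        ant = AntState(pos=(8, 6), mode="carrier")
        assert deposition_rate(ant, c) == pytest.approx(math.exp(-4.0))

    def test_forager_secretes_nothing(self):
        assert deposition_rate(AntState(pos=(8, 8), mode="forager"), cfg()) == 0.0

    def test_sums_over_sources(self):
        c = cfg(food_sources=[(8, 8), (8, 6)])
        ant = AntState(pos=(8, 8), mode="carrier")
        assert deposition_rate(ant, c) == pytest.approx(1.0 + math.exp(-4.0))

    def test_visited_source_variant(self):
        c = cfg(food_sources=[(8, 8), (8, 6)], deposition="visited_source")
        ant = AntState(pos=(8, 8), mode="carrier")
        assert deposition_rate(ant, c, source_index=0) == pytest.approx(1.0)


class TestPheromoneStep:
    def test_pure_decay_interior(self):
        c = cfg(gamma=0.001, dt=0.001)
        f = PheromoneField(c=np.ones((10, 10)))
        f2 = pheromone_step(f, [], c)
        assert f2.c[5, 5] == pytest.approx(1 - 0.001 * 0.001, abs=1e-15)

    def test_single_deposit(self):
        c = cfg(A_dep=1.0, dt=0.001)
        f = PheromoneField.zeros(c)
        f2 = pheromone_step(f, [AntState(pos=(8, 8), mode="carrier")], c)
        assert f2.c[7, 7] == pytest.approx(0.001)
        assert f2.c.sum() == pytest.approx(0.001)

    def test_zero_field_fixed_point(self):
        c = cfg()
        f2 = pheromone_step(PheromoneField.zeros(c), [], c)
        assert not f2.c.any()

    def test_stability_violation_rejected_at_construction(self):
        with pytest.raises(ConfigError, match="stability"):
            cfg(D=300.0, dt=0.001)

    def test_boundary_outflow_balance(self):
        # Robin contract: with gamma = 0 and no carriers, the mass lost in
        # one step equals dt * (discrete boundary outflow).
        c = cfg(gamma=0.0)
        rng = np.random.default_rng(0)
        f = PheromoneField(c=rng.random((10, 10)))
        mass0 = f.total_mass(c.dx)
        out = boundary_outflow(f, c)
        f2 = pheromone_step(f, [], c)
        assert mass0 - f2.total_mass(c.dx) == pytest.approx(c.dt * out, abs=1e-9)
        assert f2.total_mass(c.dx) <= mass0

    def test_nonnegativity_preserved(self):
        c = cfg()
        rng = np.random.default_rng(1)
        f = PheromoneField(c=rng.random((10, 10)))
        for _ in range(200):
            f = pheromone_step(f, [AntState(pos=(8, 8), mode="carrier")], c)
        assert f.c.min() >= 0


class TestUpdateMode:
    def test_forager_on_food_converts(self):
        out = update_mode(AntState(pos=(8, 8), mode="forager"), cfg())
        assert out.mode == "carrier"

    def test_carrier_at_nest_converts(self):
        out = update_mode(AntState(pos=(3, 3), mode="carrier"), cfg())
        assert out.mode == "forager"

    def test_elsewhere_unchanged(self):
        ant = AntState(pos=(5, 5), mode="forager", steps_since_conversion=4)
        assert update_mode(ant, cfg()) is ant
        carrier = AntState(pos=(8, 8), mode="carrier")
        assert update_mode(carrier, cfg()) is carrier


class TestSimulate:
    def test_determinism(self, small_config):
        r1 = simulate(small_config, [0, 10, 20])
        r2 = simulate(small_config, [0, 10, 20])
        for a, b in zip(r1.snapshots, r2.snapshots):
            assert np.array_equal(a.positions, b.positions)
            assert np.array_equal(a.modes, b.modes)
            assert np.array_equal(a.field.c, b.field.c)

    def test_ant_conservation_and_bounds(self, small_config):
        r = simulate(small_config, [0, 5, 10, 15, 20])
        for s in r.snapshots:
            assert len(s.positions) == small_config.n
            assert (s.positions >= 1).all()
            assert (s.positions[:, 0] <= small_config.M).all()
            assert (s.positions[:, 1] <= small_config.N).all()
            assert s.field.c.min() >= 0

    def test_all_start_at_nest(self, small_config):
        r = simulate(small_config, [0])
        assert (r.snapshots[0].positions == np.array(small_config.x0)).all()
        assert r.snapshots[0].n_carriers == 0

    def test_foodless_run_never_discovers(self, foodless_config):
        r = simulate(foodless_config, [10])
        assert r.discovery_time == -1.0
        assert not r.final.discovery_flag
        assert r.final.n_carriers == 0
        assert not r.final.field.c.any()

    def test_snapshot_beyond_run_rejected(self, small_config):
        with pytest.raises(ValueError):
            simulate(small_config, [small_config.T_max + 1])

    def test_trips_match_chebyshev_distance(self):
        # every completed return is exactly as long as the Chebyshev
        # distance from the conversion site to the nest
        c = cfg(M=20, N=20, n=50, x0=(5, 5), food_sources=[(15, 9)], T_max=150, seed=2)
        r = simulate(c)
        assert len(r.trips) > 10
        assert (r.trips[:, 0] == max(10, 4)).all()
        assert (r.trips[:, 1] == r.trips[:, 0]).all()

    def test_discovery_flag_tracks_time(self):
        c = cfg(M=20, N=20, n=50, x0=(5, 5), food_sources=[(7, 5)], T_max=50, seed=1)
        r = simulate(c, [0, 50])
        assert not r.snapshots[0].discovery_flag
        assert r.snapshots[-1].discovery_flag
        assert 0 < r.discovery_time < 50

    def test_fixed_beeline_variant_runs(self):
        c = cfg(
            M=20, N=20, n=50, x0=(5, 5), food_sources=[(15, 5)], T_max=100,
            seed=3, beeline="fixed",
        )
        r = simulate(c)
        # on-axis geometry: the fixed-vector ray coincides with the
        # adaptive beeline, so returns still take exactly 10 moves
        assert len(r.trips) > 0
        assert (r.trips[:, 1] == 10).all()
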