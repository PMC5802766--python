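"""Spatial rules: female lattice, male dispersal, availability, targeting
and movement."""
import numpy as np
import pytest
import scipy.stats

from matesim import (SimulationParams, World, place_females, place_males,
                     is_available, select_target, step_male, make_fixture)
from matesim.engine import lattice_shape
from matesim.params import ConfigError


def cheb(a, b):
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


class TestFemaleLattice:
    def test_single_female_centered(self):
        lat = place_females(SimulationParams(number_of_females=1,
                                             female_radius=5))
        assert (lat.width, lat.height) == (5, 5)
        assert lat.positions.tolist() == [[2, 2]]

    @pytest.mark.parametrize("radius", [5, 35])
    def test_twenty_females_5x4_lattice(self, radius):
        lat = place_females(SimulationParams(number_of_females=20,
                                             female_radius=radius))
        assert (lat.width, lat.height) == (5 * radius, 4 * radius)
        xs = sorted(set(lat.positions[:, 0].tolist()))
        ys = sorted(set(lat.positions[:, 1].tolist()))
        assert len(xs) == 5 and len(ys) == 4
        assert all(b - a == radius for a, b in zip(xs, xs[1:]))
        assert all(b - a == radius for a, b in zip(ys, ys[1:]))
        # nearest-neighbour distance is exactly the radius, for everyone
        pos = lat.positions
        for i in range(20):
            dists = [cheb(pos[i], pos[j]) for j in range(20) if j != i]
            assert min(dists) == radius

    def test_lattice_shape_most_square(self):
        assert lattice_shape(20) == (4, 5)
        assert lattice_shape(1) == (1, 1)
        assert lattice_shape(7) == (3, 3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationParams(number_of_females=0)
        with pytest.raises(ConfigError):
            SimulationParams(female_radius=-1)

    def test_females_fixed_for_whole_run(self, tiny_world):
        from tests_util import run_world_generations
        before = (tiny_world.female_x.copy(), tiny_world.female_y.copy())
        run_world_generations(tiny_world, generations=2)
        assert np.array_equal(tiny_world.female_x, before[0])
        assert np.array_equal(tiny_world.female_y, before[1])


class TestMalePlacement:
    def test_deterministic_under_seeding(self):
        p = SimulationParams(seed=42)
        w1, w2 = World(p), World(p)
        assert np.array_equal(w1.male_x, w2.male_x)
        assert np.array_equal(w1.male_y, w2.male_y)

    def test_uniform_over_patches(self):
        # 10^4 placements on the 25x20 world; chi-square goodness of fit
        p = SimulationParams(number_of_males=20, number_of_females=20,
                             female_radius=5, seed=3)
        w = World(p)
        counts = np.zeros((w.width, w.height), dtype=int)
        for _ in range(500):
            place_males(w)
            np.add.at(counts, (w.male_x, w.male_y), 1)
        stat, pval = scipy.stats.chisquare(counts.ravel())
        assert counts.sum() == 10_000
        assert pval > 1e-3

    def test_season_start_rerandomizes_and_clears_bonds(self, tiny_world):
        tiny_world.partner[:] = 0
        tiny_world.guard_of[:] = 0
        old = tiny_world.male_x.copy()
        place_males(tiny_world)
        assert (tiny_world.partner == -1).all()
        assert (tiny_world.guard_of == -1).all()
        assert not np.array_equal(tiny_world.male_x, old)  # w.h.p.


class TestAvailability:
    def test_pregnant_female_unavailable_to_everyone(self, tiny_world):
        tiny_world.pregnant[0] = True
        for m in range(tiny_world.params.number_of_males):
            assert not is_available(tiny_world, 0, m)

    def test_refractory_female_unavailable(self, tiny_world):
        tiny_world.refractory[1] = 3
        assert not is_available(tiny_world, 1, 0)

    def test_closer_free_male_blocks_farther_male(self):
        # male 1 at distance 3 is the female's nearest free suitor; the
        # male at distance 6 fans out instead of crowding her
        w = make_fixture("toy_world_2m1f")
        assert is_available(w, 0, 1)
        assert not is_available(w, 0, 0)
        assert select_target(w, 1) == 0
        assert select_target(w, 0) is None

    def test_engaged_rival_does_not_block_acquisition(self):
        # once the near male is engaged (to this same female) he stops
        # blocking: a latecomer may join the pursuit rather than drift
        w = make_fixture("toy_world_2m1f")
        w.target[1] = 0
        assert is_available(w, 0, 0)
        assert select_target(w, 0) == 0

    def test_guarded_female_unavailable_to_all_but_her_guard(self):
        w = make_fixture("toy_world_2m1f")
        w.genotype[1] = 1
        w.partner[1] = 0
        w.guard_of[0] = 1
        assert is_available(w, 0, 1)       # the guard himself
        assert not is_available(w, 0, 0)   # everyone else shut out
        assert select_target(w, 0) is None

    def test_matches_plain_python_rule_on_random_configs(self):
        """Kernel availability and target selection agree with a direct
        restatement of the rule: nearest receptive unguarded female
        with no strictly closer free male, lowest id on ties."""
        rng = np.random.default_rng(7)
        p = SimulationParams(number_of_males=5, number_of_females=4,
                             female_radius=5, seed=0)
        w = World(p)
        for _ in range(300):
            w.male_x[:] = rng.integers(0, w.width, 5)
            w.male_y[:] = rng.integers(0, w.height, 5)
            w.pregnant[:] = rng.random(4) < 0.3
            w.refractory[:] = rng.integers(0, 3, 4) * (rng.random(4) < 0.5)
            w.partner[:] = -1
            w.guard_of[:] = -1
            w.target[:] = -1
            w.target[0] = rng.integers(0, 4)  # one engaged rival
            if rng.random() < 0.5 and not w.pregnant[0]:
                w.genotype[4] = 1
                w.partner[4] = 0
                w.guard_of[0] = 4
            for m in range(1, 5):
                best, best_f = None, None
                for f in range(4):
                    if w.pregnant[f] or w.refractory[f] > 0:
                        continue
                    if w.guard_of[f] != -1 and w.guard_of[f] != m:
                        continue
                    dm = cheb((w.male_x[m], w.male_y[m]),
                              (w.female_x[f], w.female_y[f]))
                    blocked = any(
                        cheb((w.male_x[o], w.male_y[o]),
                             (w.female_x[f], w.female_y[f])) < dm
                        for o in range(5)
                        if o != m and w.target[o] == -1
                        and w.partner[o] == -1)
                    assert is_available(w, f, m) == (not blocked)
                    if blocked:
                        continue
                    if best is None or dm < best:
                        best, best_f = dm, f
                assert select_target(w, m) == best_f

    def test_equal_distance_tie_goes_to_lowest_id(self):
        p = SimulationParams(number_of_males=1, number_of_females=4,
                             female_radius=4, seed=0)
        w = World(p)
        # place the male equidistant from females 1 and 2
        w.male_x[0] = (w.female_x[1] + w.female_x[2]) // 2
        w.male_y[0] = (w.female_y[1] + w.female_y[2]) // 2
        w.pregnant[0] = True
        w.pregnant[3] = True
        d1 = cheb((w.male_x[0], w.male_y[0]), (w.female_x[1], w.female_y[1]))
        d2 = cheb((w.male_x[0], w.male_y[0]), (w.female_x[2], w.female_y[2]))
        assert d1 == d2
        assert select_target(w, 0) == 1

    def test_all_females_pregnant_means_no_target(self, tiny_world):
        tiny_world.pregnant[:] = True
        for m in range(4):
            assert select_target(tiny_world, m) is None


class TestMovement:
    def test_one_patch_per_tick_toward_target(self):
        w = make_fixture("toy_world_1m1f")
        w.genotype[0] = 0  # polygamous searcher
        d0 = cheb(w.male(0).position, w.female(0).position)
        assert d0 == 6
        for k in range(1, 7):
            step_male(w, 0)
            d = cheb(w.male(0).position, w.female(0).position)
            assert d == d0 - k
        # meeting at tick 6 forces a copulation (pregnancy_chance = 0)
        assert w.refractory[0] == w.params.refractory_period_duration + 1

    def test_random_walk_when_no_female_available(self):
        w = make_fixture("toy_world_1m1f")
        w.pregnant[0] = True
        rngpos = []
        for _ in range(20):
            before = w.male(0).position
            step_male(w, 0)
            after = w.male(0).position
            assert cheb(before, after) == 1
            rngpos.append(after)
        assert len(set(rngpos)) > 1

    def test_moves_stay_in_bounds(self):
        p = SimulationParams(number_of_males=6, number_of_females=4,
                             female_radius=3, season_duration=200, seed=5)
        w = World(p)
        from conftest import drive_season_python

        def check(world, tick):
            assert (world.male_x >= 0).all()
            assert (world.male_x < world.width).all()
            assert (world.male_y >= 0).all()
            assert (world.male_y < world.height).all()

        drive_season_python(w, record=check)
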