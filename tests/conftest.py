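import numpy as np
import pytest

from matesim import SimulationParams, World


@pytest.fixture
def tiny_params() -> SimulationParams:
    """A fast, small configuration for step-level tests."""
    return SimulationParams(
        number_of_males=4, number_of_females=4, female_radius=5,
        season_duration=50, refractory_period_duration=3,
        longevity=2, generations=3, seed=11)


@pytest.fixture
def tiny_world(tiny_params) -> World:
    return World(tiny_params)


def drive_season_python(world, record=None):
    """Tick-by-tick season driver written at the Python API level.

    Mirrors the kernel's scheduling (decrement refractory counters,
    then step every male in a shuffled order) but leaves room for
    per-tick invariant checks via ``record(world, tick)``.
    """
    from matesim import step_male

    p = world.params
    for tick in range(p.season_duration):
        world.refractory[world.refractory > 0] -= 1
        order = np.arange(p.number_of_males)
        world.rng.shuffle(order)
        for m in order:
            step_male(world, int(m))
        if record is not None:
            record(world, tick)
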