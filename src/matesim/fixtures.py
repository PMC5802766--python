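"""Deterministic miniature fixtures for oracle tests.

Each fixture is tiny, built programmatically, and exercises one rule in
isolation: a forced meeting on an empty corridor, a contested female, a
noiseless planted-coefficient sweep table, and a neutral-drift config.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import World
from .params import SimulationParams

__all__ = ["make_fixture", "FIXTURE_NAMES"]

#: Planted coefficients of the linear sweep table, in predictor order
#: (female_radius, season_duration, number_of_males, extra_pair).
PLANTED_BETA = (0.6, 0.3, -0.2, -0.15)

FIXTURE_NAMES = ("toy_world_1m1f", "toy_world_2m1f", "linear_sweep_table",
                 "neutral_mode_config")


def _toy_world(n_males: int) -> World:
    params = SimulationParams(
        number_of_males=n_males, number_of_females=1, female_radius=7,
        season_duration=20, refractory_period_duration=3,
        pregnancy_chance=0.0, seed=123)
    world = World(params)
    # deterministic positions overriding the random season-start spread
    world.female_x[0], world.female_y[0] = 6, 0
    world.male_x[0], world.male_y[0] = 0, 0
    if n_males > 1:
        world.male_x[1], world.male_y[1] = 3, 0
    return world


def make_fixture(name: str):
    """Build one of the named validation fixtures.

    - ``toy_world_1m1f``: one male at (0,0), one female at (6,0) on an
      empty 7×7 corridor world; unit steps force a meeting at tick 6.
    - ``toy_world_2m1f``: adds a second male at (3,0), strictly closer,
      so the far male is blocked by the availability rule.
    - ``linear_sweep_table``: a noiseless long-format sweep table whose
      predictors sit on their min-max-normalized values and whose
      response is exactly linear in them with coefficients
      ``PLANTED_BETA`` (intercept 0.35, response already on the
      normalized scale); OLS must recover the coefficients exactly.
    - ``neutral_mode_config``: a small config whose genotypes behave
      identically (no selection), for drift validation.
    """
    if name == "toy_world_1m1f":
        return _toy_world(1)
    if name == "toy_world_2m1f":
        return _toy_world(2)
    if name == "linear_sweep_table":
        radii = [5, 20, 35]
        durations = [200, 800]
        males = [15, 25]
        extra = [False, True]
        rows = []
        for r in radii:
            for d in durations:
                for m in males:
                    for e in extra:
                        xr = (r - 5) / 30
                        xd = (d - 200) / 600
                        xm = (m - 15) / 10
                        xe = float(e)
                        y = (0.35 + PLANTED_BETA[0] * xr
                             + PLANTED_BETA[1] * xd
                             + PLANTED_BETA[2] * xm
                             + PLANTED_BETA[3] * xe)
                        rows.append({
                            "female_radius": r, "season_duration": d,
                            "number_of_males": m,
                            "refractory_period_duration": 10,
                            "mate_guarding": not e, "extra_pair": e,
                            "replicate": 0, "seed": 0,
                            "percentage_monogamy": y})
        return pd.DataFrame(rows)
    if name == "neutral_mode_config":
        return SimulationParams(
            number_of_males=10, number_of_females=8, female_radius=4,
            season_duration=60, longevity=2, generations=15,
            neutral_mode=True, seed=0)
    raise ValueError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
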