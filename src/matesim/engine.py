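"""Spatial engine: world construction and the per-tick behavioral rules.

The world is a bounded rectangular grid of integer patches. Females sit
on a fixed regular lattice whose spacing is the female-dispersion
parameter; males are re-dispersed uniformly at random at the start of
every breeding season and move one patch per tick (8-neighbour moves,
Chebyshev metric). Monogamous males (genotype 1) pair-bond with the
first female they copulate with; polygamous males (genotype 0) keep
searching for the nearest available female; a searching male commits
to his chosen target until she becomes pregnant or guarded.

All stochastic behavior is driven by a single ``np.random.Generator``
owned by the :class:`World`, and the actual rules are numba kernels in
:mod:`matesim._kernel`, shared with the fast whole-run driver
:func:`run_simulation`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from . import _kernel as K
from .params import ConfigError, SimulationParams

__all__ = [
    "FemaleLattice", "FemaleState", "MaleState", "World", "SeasonSummary",
    "place_females", "place_males", "is_available", "select_target",
    "step_male", "attempt_copulation", "run_season", "run_simulation",
    "SimulationOutput",
]


class FemaleLattice(NamedTuple):
    positions: np.ndarray  # (n, 2) int64 patch coordinates
    width: int
    height: int


def lattice_shape(n: int) -> tuple[int, int]:
    """Most-square (rows, cols) factorization with cols = ceil(sqrt(n))."""
    cols = math.isqrt(n)
    if cols * cols < n:
        cols += 1
    rows = -(-n // cols)
    return rows, cols


def place_females(params: SimulationParams) -> FemaleLattice:
    """Fixed female positions: a regular lattice with nearest-neighbour
    spacing ``female_radius``, centered in a world sized to fit it.

    The world measures (cols·radius) × (rows·radius) patches, so each
    female sits at the center of her own radius×radius territory.
    """
    n = params.number_of_females
    r = params.female_radius
    if n < 1 or r < 1:
        raise ConfigError("number_of_females and female_radius must be >= 1")
    rows, cols = lattice_shape(n)
    width, height = cols * r, rows * r
    off = r // 2
    pos = np.empty((n, 2), dtype=np.int64)
    for i in range(n):
        row, col = divmod(i, cols)
        pos[i, 0] = off + col * r
        pos[i, 1] = off + row * r
    return FemaleLattice(pos, width, height)


@dataclass
class FemaleState:
    """Read-only snapshot of one female agent."""
    id: int
    position: tuple[int, int]
    pregnant: bool
    refractory_remaining: int
    father_genotype: Optional[int]  # set on conception, else None


@dataclass
class MaleState:
    """Read-only snapshot of one male agent."""
    id: int
    position: tuple[int, int]
    genotype: int  # 0 polygamous, 1 monogamous
    partner_id: Optional[int]
    seasons_lived: int


@dataclass
class SeasonSummary:
    season: int
    copulations: int
    pregnancies: int
    monogamous_count: int


class World:
    """Mutable simulation state: geometry, agents, trait pool, counters."""

    def __init__(self, params: SimulationParams):
        self.params = params
        lattice = place_females(params)
        self.width = lattice.width
        self.height = lattice.height
        self.female_x = lattice.positions[:, 0].copy()
        self.female_y = lattice.positions[:, 1].copy()
        nf = params.number_of_females
        nm = params.number_of_males
        self.pregnant = np.zeros(nf, dtype=np.bool_)
        self.refractory = np.zeros(nf, dtype=np.int64)
        self.father = np.full(nf, -1, dtype=np.int64)
        self.guard_of = np.full(nf, -1, dtype=np.int64)
        self.male_x = np.zeros(nm, dtype=np.int64)
        self.male_y = np.zeros(nm, dtype=np.int64)
        self.partner = np.full(nm, -1, dtype=np.int64)
        self.target = np.full(nm, -1, dtype=np.int64)
        self.seasons_lived = np.zeros(nm, dtype=np.int64)
        self.rng = np.random.default_rng(params.seed)
        # genetics.init_first_generation draws scalar-by-scalar so the
        # RNG stream matches the fast kernel exactly
        from .genetics import init_first_generation
        self.genotype = init_first_generation(params, self.rng)
        self.trait_pool: list[int] = []
        self.tick = 0
        self.season = 0
        self.generation = 0
        self._order = np.arange(nm)
        place_males(self)

    # -- snapshots -------------------------------------------------------
    def female(self, f: int) -> FemaleState:
        return FemaleState(
            id=f,
            position=(int(self.female_x[f]), int(self.female_y[f])),
            pregnant=bool(self.pregnant[f]),
            refractory_remaining=int(self.refractory[f]),
            father_genotype=int(self.father[f]) if self.pregnant[f] else None,
        )

    def male(self, m: int) -> MaleState:
        p = int(self.partner[m])
        return MaleState(
            id=m,
            position=(int(self.male_x[m]), int(self.male_y[m])),
            genotype=int(self.genotype[m]),
            partner_id=p if p >= 0 else None,
            seasons_lived=int(self.seasons_lived[m]),
        )

    @property
    def monogamous_count(self) -> int:
        return int(self.genotype.sum())


def place_males(world: World) -> World:
    """Disperse all males uniformly at random and dissolve all bonds.

    Runs at the start of every breeding season.
    """
    world.partner[:] = -1
    world.target[:] = -1
    world.guard_of[:] = -1
    K.place_males_random(world.rng, world.male_x, world.male_y,
                         world.width, world.height)
    return world


def is_available(world: World, female_id: int, male_id: int) -> bool:
    """Can ``male_id`` acquire ``female_id`` as a courtship target?

    True iff she is neither pregnant nor refractory, is not the partner
    of a guarding male other than the candidate, and no competing male
    (unpaired or polygamous) is strictly closer to her; equal distances
    do not block. Evaluated at target acquisition only.
    """
    return bool(K.is_available(
        female_id, male_id, world.pregnant, world.refractory,
        world.genotype, world.partner, world.target,
        world.params.mate_guarding,
        world.params.neutral_mode, world.male_x, world.male_y,
        world.female_x, world.female_y, world.width, world.height,
        world.params.wrap))


def select_target(world: World, male_id: int) -> Optional[int]:
    """Nearest available female, distance ties broken by lowest id."""
    t = K.select_target(male_id, world.male_x, world.male_y,
                        world.female_x, world.female_y, world.pregnant,
                        world.refractory, world.genotype, world.partner,
                        world.target, world.guard_of, world.width,
                        world.height,
                        world.params.wrap, world.params.mate_guarding,
                        world.params.neutral_mode)
    return int(t) if t >= 0 else None


def attempt_copulation(world: World, male_id: int, female_id: int) -> str:
    """Copulation on a shared patch: returns "pregnant" or "refractory".

    An unpaired monogamous male pair-bonds with this female regardless
    of the outcome. Calling this for a pregnant or refractory female,
    or for agents on different patches, is a programming error.
    """
    p = world.params
    if world.pregnant[female_id] or world.refractory[female_id] > 0:
        raise ValueError(
            f"female {female_id} is pregnant or refractory; copulation "
            "precondition violated")
    if (world.male_x[male_id] != world.female_x[female_id]
            or world.male_y[male_id] != world.female_y[female_id]):
        raise ValueError("copulation requires co-located agents")
    got = K.attempt_copulation(
        world.rng, male_id, female_id, world.genotype, world.partner,
        world.guard_of, world.pregnant, world.refractory, world.father,
        p.pregnancy_chance, p.refractory_period_duration, p.mate_guarding,
        p.neutral_mode)
    return "pregnant" if got else "refractory"


def step_male(world: World, male_id: int) -> tuple[int, int]:
    """Advance one male by one tick; returns (copulations, conceptions)."""
    p = world.params
    c, g = K.step_male(
        world.rng, male_id, world.male_x, world.male_y, world.genotype,
        world.partner, world.target, world.guard_of, world.female_x,
        world.female_y, world.pregnant, world.refractory, world.father,
        world.width, world.height, p.wrap, p.pregnancy_chance,
        p.refractory_period_duration, p.mate_guarding, p.neutral_mode)
    return int(c), int(g)


def run_season(world: World) -> SeasonSummary:
    """One full breeding season of ``season_duration`` ticks.

    Each tick decrements positive refractory counters, then steps every
    male in a freshly shuffled order. At season end every pregnant
    female contributes one progeny genotype to the trait pool,
    pregnancies are cleared and ``seasons_lived`` advances.
    """
    from .genetics import contribute_progeny
    p = world.params
    cops, _ = K.season_ticks(
        world.rng, p.season_duration, world.male_x, world.male_y,
        world.genotype, world.partner, world.target, world.guard_of,
        world.female_x, world.female_y, world.pregnant, world.refractory,
        world.father, world._order, world.width, world.height, p.wrap,
        p.pregnancy_chance, p.refractory_period_duration, p.mate_guarding,
        p.neutral_mode)
    pregnancies = int(world.pregnant.sum())
    mono = world.monogamous_count
    contribute_progeny(world)
    world.pregnant[:] = False
    world.father[:] = -1
    world.refractory[:] = 0
    world.seasons_lived += 1
    summary = SeasonSummary(season=world.season, copulations=int(cops),
                            pregnancies=pregnancies, monogamous_count=mono)
    world.season += 1
    world.tick = 0
    return summary


@dataclass
class SimulationOutput:
    """Raw per-season and per-generation trajectories of one run."""
    params: SimulationParams
    monogamous_counts: np.ndarray  # (seasons,)
    copulations: np.ndarray        # (seasons,)
    pregnancies: np.ndarray        # (seasons,)
    pool_sizes: np.ndarray         # (generations,)
    pool_monogamy_fraction: np.ndarray  # (generations,), NaN if pool empty


def run_simulation(params: SimulationParams,
                   seed: Optional[int] = None) -> SimulationOutput:
    """Run a complete simulation (generations × longevity seasons).

    This is the fast path used by sweeps; it executes the same kernels
    as the step-by-step :class:`World` API and is bit-reproducible for a
    given seed.
    """
    if seed is None:
        seed = params.seed
    lattice = place_females(params)
    rng = np.random.default_rng(seed)
    monog, cops, pregs, pool_sizes, pool_frac = K.simulate(
        rng, params.number_of_males,
        lattice.positions[:, 0].copy(), lattice.positions[:, 1].copy(),
        lattice.width, lattice.height, params.wrap,
        params.generations, params.longevity, params.season_duration,
        params.pregnancy_chance, params.refractory_period_duration,
        params.mate_guarding, params.mutation_sigma, params.neutral_mode)
    return SimulationOutput(params=params, monogamous_counts=monog,
                            copulations=cops, pregnancies=pregs,
                            pool_sizes=pool_sizes,
                            pool_monogamy_fraction=pool_frac)
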