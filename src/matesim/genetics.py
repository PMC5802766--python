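"""Trait inheritance, the trait pool, and generation turnover.

The mating strategy is a single heritable binary trait: 1 = monogamous,
0 = polygamous. When a pregnant female contributes a progeny to the
trait pool, the father's genotype is perturbed by Gaussian noise and
threshold-rounded,

    G1 = round(G0 + N(mu=0, sigma)),   round(x) = 1 if x >= 0.5 else 0,

so with the default sigma = 0.35 a genotype flips with probability
1 - Phi(0.5 / 0.35) ≈ 0.0766, symmetrically in both directions. The
noise keeps the population from locking into a monomorphic state while
staying small enough not to swamp selection.

Males all die together every ``longevity`` seasons and are replaced by
genotypes drawn uniformly with replacement from the accumulated pool,
keeping the male count (and hence the adult sex ratio) constant.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .params import SimulationParams

__all__ = ["MutationModel", "mutate_genotype", "contribute_progeny",
           "generation_turnover", "init_first_generation"]


@dataclass(frozen=True)
class MutationModel:
    """Gaussian-perturbation mutation with threshold rounding at 0.5."""
    mu: float = 0.0
    sigma: float = 0.35


def mutate_genotype(g0: int, model: MutationModel,
                    rng: np.random.Generator) -> int:
    """Progeny genotype from father genotype ``g0`` (0 or 1)."""
    if g0 not in (0, 1):
        raise ValueError(f"genotype must be 0 or 1, got {g0!r}")
    return int(K.mutate_genotype(rng, g0, model.sigma))


def contribute_progeny(world) -> list[int]:
    """Append one progeny genotype per pregnant female to the trait pool.

    Runs once at season end, before pregnancies are reset. Mutation is
    applied here, at contribution time: the pool stores post-mutation
    genotypes and sampling at turnover adds no further noise.
    """
    sigma = world.params.mutation_sigma
    for f in range(world.params.number_of_females):
        if world.pregnant[f]:
            world.trait_pool.append(
                int(K.mutate_genotype(world.rng, int(world.father[f]), sigma)))
    return world.trait_pool


def generation_turnover(world) -> None:
    """Replace the whole male population from the trait pool.

    Every new genotype is drawn uniformly with replacement from the
    pool; the pool is then cleared and seasons_lived reset. If the pool
    is empty (no pregnancy occurred all generation) the dying
    generation's genotypes carry over unchanged — no selection happened,
    so the composition is preserved. Positions are refreshed by the
    season-start dispersal that immediately follows a turnover.
    """
    pool = world.trait_pool
    n = len(pool)
    if n > 0:
        for m in range(world.params.number_of_males):
            world.genotype[m] = pool[int(world.rng.integers(0, n))]
    world.trait_pool = []
    world.seasons_lived[:] = 0
    world.generation += 1


def init_first_generation(params: SimulationParams,
                          rng: np.random.Generator) -> np.ndarray:
    """Founding male genotypes: independent fair coin flips."""
    geno = np.empty(params.number_of_males, dtype=np.int64)
    for m in range(params.number_of_males):
        geno[m] = 1 if rng.random() < 0.5 else 0
    return geno
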