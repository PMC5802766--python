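"""Simulation parameters and the published sweep grid.

The defaults reproduce the reference study conditions: 20 females on a
regular lattice, a 5% per-copulation pregnancy chance, male longevity of
4 breeding seasons, Gaussian mutation with sigma = 0.35, and 150
generations per run.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

__all__ = ["SimulationParams", "SweepConfig", "PAPER_GRID", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a parameter violates its documented constraint."""


#: The published parameter grid: every swept value per parameter.
PAPER_GRID: dict[str, list] = {
    "number_of_males": [15, 20, 25],
    "female_radius": [5, 10, 15, 20, 25, 30, 35],
    "season_duration": [200, 400, 600, 800],
    "refractory_period_duration": [10, 30],
    "mate_guarding": [True, False],
}


@dataclass(frozen=True)
class SimulationParams:
    """Full configuration of a single simulation run.

    Attributes
    ----------
    pregnancy_chance
        Probability that any single copulation results in pregnancy.
    number_of_males, number_of_females
        Population sizes; both held constant for the whole run, which
        fixes the adult sex ratio.
    longevity
        Breeding seasons per male generation; all males are replaced
        together after this many seasons.
    female_radius
        Lattice spacing (in patches) between adjacent females — the
        female-dispersion knob.
    season_duration
        Ticks per breeding season; a male moves one patch per tick.
    refractory_period_duration
        Ticks a female rejects all males after a non-conceptive
        copulation.
    mate_guarding
        If True, a paired monogamous male stays on his partner's patch,
        making extra-pair copulation impossible; if False he wanders
        while she is refractory, opening a window for extra-pair
        copulation.
    generations
        Male generations per run.
    mutation_sigma
        Std. dev. of the Gaussian perturbation applied to the father's
        genotype when a progeny is added to the trait pool.
    seed
        RNG seed for the run.
    wrap
        Toroidal world topology (sensitivity flag; default bounded).
    neutral_mode
        Debug flag: both genotypes behave polygamously, so the trait is
        selectively neutral. Used by drift-validation tests only.
    """

    pregnancy_chance: float = 0.05
    number_of_males: int = 20
    number_of_females: int = 20
    longevity: int = 4
    female_radius: int = 15
    season_duration: int = 300
    refractory_period_duration: int = 10
    mate_guarding: bool = True
    generations: int = 150
    mutation_sigma: float = 0.35
    seed: int = 0
    wrap: bool = False
    neutral_mode: bool = False

    def __post_init__(self) -> None:
        for name in ("number_of_males", "number_of_females", "longevity",
                     "female_radius", "generations"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("season_duration", "refractory_period_duration", "seed"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        if not (0.0 <= self.pregnancy_chance <= 1.0):
            raise ConfigError(
                f"pregnancy_chance must lie in [0, 1], got {self.pregnancy_chance!r}")
        if self.mutation_sigma < 0:
            raise ConfigError(
                f"mutation_sigma must be >= 0, got {self.mutation_sigma!r}")

    @property
    def adult_sex_ratio(self) -> float:
        """Proportion of males among all adults (stable within a run)."""
        return self.number_of_males / (self.number_of_males
                                       + self.number_of_females)

    def replace(self, **kwargs: Any) -> "SimulationParams":
        d = asdict(self)
        d.update(kwargs)
        return SimulationParams(**d)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class SweepConfig:
    """Cross-product sweep: lists of values per swept parameter.

    ``grid`` maps SimulationParams field names to lists of values; every
    combination (cell) is run ``replicates`` times with seeds derived
    from ``base_seed``. ``base_params`` supplies all non-swept fields.
    """

    grid: dict[str, list] = field(default_factory=lambda: dict(PAPER_GRID))
    replicates: int = 5
    base_seed: int = 0
    base_params: SimulationParams = field(default_factory=SimulationParams)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        valid = set(SimulationParams.__dataclass_fields__)
        for key, values in self.grid.items():
            if key not in valid:
                raise ConfigError(f"unknown sweep parameter {key!r}")
            if not values:
                raise ConfigError(f"sweep parameter {key!r} has no values")

    @property
    def n_cells(self) -> int:
        n = 1
        for values in self.grid.values():
            n *= len(values)
        return n
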