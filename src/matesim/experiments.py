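"""Experimental harness: outcome statistic, parameter sweep, summaries,
and the normalized multiple-regression sensitivity analysis.

The primary outcome of a run is *percentage monogamy*: the percentage
of breeding seasons in which strictly more than half the male
population carried the monogamous genotype. The sweep crosses female
dispersion, season duration, number of males, refractory duration and
mate guarding, and the sensitivity analysis regresses the outcome on
four min-max-normalized predictors (female radius, season duration,
number of males, and an extra-pair-copulation dummy = mate guarding
off) by OLS.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .config import derive_seed
from .engine import run_simulation
from .params import SimulationParams, SweepConfig

__all__ = [
    "RunResult", "RegressionResult", "percentage_monogamy", "run_single",
    "run_sweep", "summarize_cells", "normalize_columns", "fit_regression",
    "subset_regressions", "dispersion_fit", "PREDICTORS", "RESPONSE",
]

#: The four sensitivity-analysis predictors, in reporting order.
PREDICTORS = ("female_radius", "season_duration", "number_of_males",
              "extra_pair")
RESPONSE = "percentage_monogamy"

#: Canonical ordering of sweep dimensions (defines cell indices).
_DIM_ORDER = ("number_of_males", "female_radius", "season_duration",
              "refractory_period_duration", "mate_guarding")


def percentage_monogamy(season_counts: Sequence[int],
                        number_of_males: int) -> float:
    """Percent of seasons with a strict monogamous majority of males."""
    counts = np.asarray(season_counts)
    if counts.size == 0:
        raise ValueError("season_counts must be non-empty")
    # integer-exact strict majority: count > n/2  <=>  2*count > n
    return 100.0 * float(np.mean(2 * counts > number_of_males))


@dataclass
class RunResult:
    """Outcome of a single simulation run."""
    params: SimulationParams
    seed: int
    monogamous_counts: np.ndarray
    percentage_monogamy: float


def run_single(params: SimulationParams, seed: Optional[int] = None) -> RunResult:
    if seed is None:
        seed = params.seed
    out = run_simulation(params, seed=seed)
    pm = percentage_monogamy(out.monogamous_counts, params.number_of_males)
    return RunResult(params=params, seed=seed,
                     monogamous_counts=out.monogamous_counts,
                     percentage_monogamy=pm)


def _ordered_dims(grid: dict) -> list[str]:
    known = [d for d in _DIM_ORDER if d in grid]
    extra = sorted(k for k in grid if k not in _DIM_ORDER)
    return known + extra


def iter_cells(config: SweepConfig) -> Iterable[tuple[int, dict]]:
    """Deterministic enumeration of the sweep's cross-product cells."""
    dims = _ordered_dims(config.grid)
    for idx, values in enumerate(itertools.product(
            *(config.grid[d] for d in dims))):
        yield idx, dict(zip(dims, values))


def run_sweep(config: SweepConfig, scale: float = 1.0,
              progress: bool = False) -> pd.DataFrame:
    """Run every cell × replicate of the sweep; one long-format row each.

    Seeds are derived from ``base_seed`` per (cell, replicate), so rows
    are independent of execution order and the table is reproducible
    bit-for-bit. ``scale`` < 1 shrinks generations and replicates
    proportionally for desk-scale runs.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must lie in (0, 1]")
    replicates = max(1, round(config.replicates * scale))
    generations = max(1, round(config.base_params.generations * scale))
    base = config.base_params.replace(generations=generations)
    rows = []
    for idx, cell in iter_cells(config):
        params = base.replace(**cell)
        for rep in range(replicates):
            seed = derive_seed(config.base_seed, idx, rep)
            try:
                res = run_single(params, seed=seed)
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"sweep cell {idx} {cell!r}, replicate {rep} failed"
                ) from exc
            # every standard dimension is echoed even when not swept,
            # so slices and subset fits work on any table
            dims = {d: getattr(params, d) for d in _DIM_ORDER}
            row = {"cell_index": idx, **dims, **cell,
                   "extra_pair": not params.mate_guarding,
                   "replicate": rep, "seed": seed,
                   "percentage_monogamy": res.percentage_monogamy}
            rows.append(row)
            if progress:
                print(f"cell {idx} rep {rep}: "
                      f"{res.percentage_monogamy:.1f}% monogamy")
    return pd.DataFrame(rows)


def summarize_cells(table: pd.DataFrame,
                    confidence: float = 0.95) -> pd.DataFrame:
    """Per-cell mean and Student-t confidence interval over replicates.

    With a single replicate the mean is reported and the CI columns are
    NaN. Mirrors the per-panel points-with-95%-CI-bars presentation of
    sweep results.
    """
    dims = [d for d in _DIM_ORDER if d in table.columns]
    out = []
    for key, grp in table.groupby(dims, sort=True):
        vals = grp["percentage_monogamy"].to_numpy(float)
        n = vals.size
        mean = float(vals.mean())
        if n >= 2:
            sem = float(vals.std(ddof=1)) / np.sqrt(n)
            tcrit = float(scipy.stats.t.ppf(0.5 + confidence / 2, n - 1))
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
        else:
            lo = hi = float("nan")
        rec = dict(zip(dims, key if isinstance(key, tuple) else (key,)))
        rec.update(mean_percentage_monogamy=mean, ci_low=lo, ci_high=hi,
                   n_replicates=n)
        out.append(rec)
    return pd.DataFrame(out)


def normalize_columns(table: pd.DataFrame,
                      columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Min-max scale the given columns (default: the four predictors and
    the response) to [0, 1]. A constant column cannot be scaled and
    raises, naming the column."""
    if columns is None:
        columns = [c for c in (*PREDICTORS, RESPONSE) if c in table.columns]
    out = table.copy()
    for col in columns:
        vals = table[col].to_numpy(float)
        lo, hi = float(np.min(vals)), float(np.max(vals))
        if hi == lo:
            raise ValueError(f"column {col!r} is constant; cannot normalize")
        out[col] = (vals - lo) / (hi - lo)
    return out


@dataclass
class RegressionResult:
    """OLS fit summary: per-predictor estimate/SE/t/p plus R²."""
    predictors: list[str]
    estimates: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    adj_r_squared: float
    nobs: int
    intercept: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "predictors": {
                name: {"estimate": self.estimates[name],
                       "std_error": self.std_errors[name],
                       "t_value": self.t_values[name],
                       "p_value": self.p_values[name]}
                for name in self.predictors},
            "multiple_r_squared": self.r_squared,
            "adjusted_r_squared": self.adj_r_squared,
            "n_observations": self.nobs,
        }
        if self.intercept is not None:
            d["intercept"] = self.intercept
        return d


def fit_regression(table: pd.DataFrame,
                   predictors: Sequence[str] = PREDICTORS,
                   response: str = RESPONSE,
                   intercept: bool = True) -> RegressionResult:
    """OLS of the (normalized) response on the given predictors.

    An intercept is included by default; pass ``intercept=False`` to
    compare with fits that omit it.
    """
    X = table.loc[:, list(predictors)].to_numpy(float)
    y = table[response].to_numpy(float)
    design = sm.add_constant(X, has_constant="raise") if intercept else X
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    fit = sm.OLS(y, design).fit()
    off = 1 if intercept else 0
    names = list(predictors)
    return RegressionResult(
        predictors=names,
        estimates={n: float(fit.params[off + i]) for i, n in enumerate(names)},
        std_errors={n: float(fit.bse[off + i]) for i, n in enumerate(names)},
        t_values={n: float(fit.tvalues[off + i]) for i, n in enumerate(names)},
        p_values={n: float(fit.pvalues[off + i]) for i, n in enumerate(names)},
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        nobs=int(fit.nobs),
        intercept=float(fit.params[0]) if intercept else None,
    )


def subset_regressions(table: pd.DataFrame,
                       refractory_value: int = 10) -> dict:
    """Refractory-subset analyses: the full 4-predictor model and each
    predictor in isolation, on rows with the given refractory duration.

    Returns ``{"full": RegressionResult, "isolated": {name: result}}``.
    """
    sub = table[table["refractory_period_duration"] == refractory_value]
    if sub.empty:
        raise ValueError(
            f"no rows with refractory_period_duration == {refractory_value}")
    norm = normalize_columns(sub)
    full = fit_regression(norm)
    isolated = {name: fit_regression(norm, predictors=[name])
                for name in PREDICTORS}
    return {"full": full, "isolated": isolated}


def dispersion_fit(table: pd.DataFrame, number_of_males: int = 15,
                   season_duration: int = 200, mate_guarding: bool = True,
                   refractory_period: Optional[int] = 10) -> float:
    """R² of per-run percentage monogamy regressed on female radius,
    within one (males, duration, guarding) slice of the sweep.

    This quantifies how well female dispersion alone predicts monogamy
    in the regime where it matters: few males and a short season.
    """
    mask = ((table["number_of_males"] == number_of_males)
            & (table["season_duration"] == season_duration)
            & (table["mate_guarding"] == mate_guarding))
    if (refractory_period is not None
            and "refractory_period_duration" in table.columns):
        mask &= table["refractory_period_duration"] == refractory_period
    sub = table[mask]
    if sub.empty:
        raise ValueError("requested sweep slice is empty")
    y = sub["percentage_monogamy"].to_numpy(float)
    x = sub["female_radius"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("female_radius is constant in the slice")
    if np.ptp(y) == 0:
        return 0.0
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.rsquared)
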