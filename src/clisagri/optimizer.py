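"""Variety optimization: TSUM grid scans and a genetic-algorithm search.

Two complementary tools explore the space of variety thermal requirements:

* :func:`grid_scan` exhaustively evaluates TSUM1/TSUM2 combinations of the
  two-phase model and tabulates the resulting indicator values (the data
  behind hazard maps);
* :func:`ga_optimize` searches the six-dimensional space of sub-phase
  thermal requirements of the multi-phase model with a seeded real-valued
  genetic algorithm (tournament selection, uniform crossover, Gaussian
  mutation clipped to bounds, elitism), maximizing a fitness score built
  from selected indicators.

The fitness is a negated sum of penalties: each selected hydrological
indicator contributes ``max(0, |SPEI| - 1)`` (zero while the season is
neither in drought nor excessively wet), each day-count indicator
contributes the fraction of its window occupied by stress days, and a
season that fails to mature incurs a large fixed penalty.  The maximum
attainable score is therefore 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import phenology as ph
from .indicators import IndicatorResult, builtin_registry, compute_indicators
from .spei import MIN_REFERENCE_N
from .water_balance import WaterBalanceSeries, climatic_water_balance
from .weather import WeatherEnsemble, WeatherSeries

__all__ = [
    "TsumGrid",
    "GAConfig",
    "FitnessScore",
    "FitnessEvaluator",
    "grid_scan",
    "fitness",
    "ga_optimize",
    "ga_optimize_ensemble",
    "GAResult",
]

#: fitness penalty for a season that never reaches maturity; dominates any
#: feasible combination of indicator penalties
INCOMPLETE_SEASON_PENALTY = 10.0


@dataclass
class TsumGrid:
    """Exhaustive TSUM1 x TSUM2 evaluation of the two-phase model."""

    tsum1_values: tuple[float, ...]
    tsum2_values: tuple[float, ...]
    table: pd.DataFrame  # long format: tsum1, tsum2, id, value, season_complete

    def pivot(self, indicator_id: int) -> pd.DataFrame:
        """TSUM1-by-TSUM2 matrix of one indicator (hazard-map data)."""
        sub = self.table[self.table["id"] == indicator_id]
        return sub.pivot(index="tsum1", columns="tsum2", values="value")


def grid_scan(
    series: WeatherSeries,
    params: ph.VarietyParams2,
    tsum1_values: Sequence[float],
    tsum2_values: Sequence[float],
    selection: Sequence[int] | None = None,
    mode: str = "dynamic",
    **indicator_kwargs,
) -> TsumGrid:
    """Evaluate every TSUM1/TSUM2 combination; incomplete seasons are flagged
    (value NaN), never fatal, so scans over extreme requirements stay total."""
    from .indicators import clis_agri

    if not len(tsum1_values) or not len(tsum2_values):
        raise ValueError("tsum value lists must be non-empty")
    rows = []
    for t1 in tsum1_values:
        for t2 in tsum2_values:
            p = replace(params, tsum1=float(t1), tsum2=float(t2))
            results = clis_agri(series, p, selection=selection, mode=mode, **indicator_kwargs)
            for r in results:
                rows.append(
                    {
                        "tsum1": float(t1),
                        "tsum2": float(t2),
                        "id": r.id,
                        "value": r.value,
                        "season_complete": r.season_complete,
                    }
                )
    return TsumGrid(
        tuple(float(t) for t in tsum1_values),
        tuple(float(t) for t in tsum2_values),
        pd.DataFrame(rows),
    )


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    ``indicator_ids`` selects the indicators entering the fitness (default:
    hydrological balance during stem elongation-booting and
    heading-maturity plus the two heat-stress counts).  ``weights`` maps
    indicator id to penalty weight (default 1 for every selected id).
    """

    population_size: int = 50
    n_generations: int = 200
    crossover_prob: float = 0.7
    mutation_prob: float = 0.2
    mutation_sigma_frac: float = 0.1
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0
    indicator_ids: tuple[int, ...] = (4, 5, 15, 16)
    weights: Mapping[int, float] | None = None
    incomplete_penalty: float = INCOMPLETE_SEASON_PENALTY
    min_reference: int = MIN_REFERENCE_N

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def weight(self, indicator_id: int) -> float:
        if self.weights is None:
            return 1.0
        return float(self.weights.get(indicator_id, 1.0))


@dataclass
class FitnessScore:
    """Fitness of one chromosome: total = -(sum of non-negative penalties)."""

    total: float
    penalties: dict[int | str, float] = field(default_factory=dict)
    season_complete: bool = True


class FitnessEvaluator:
    """Precomputes the water balance once and scores six-gene chromosomes.

    A chromosome is the vector of six sub-phase thermal requirements (GDD);
    base temperatures, vernalization/photoperiod response and sowing date
    come from ``base_params``.
    """

    def __init__(
        self,
        series: WeatherSeries,
        base_params: ph.VarietyParamsMulti,
        config: GAConfig,
        stage_map: Mapping[str, float] | None = None,
    ):
        self.series = series
        self.base_params = base_params
        self.config = config
        self.stage_map = dict(stage_map or ph.DEFAULT_STAGE_DVS_MULTI)
        self._registry = {s.id: s for s in builtin_registry()}
        unknown = [i for i in config.indicator_ids if i not in self._registry]
        if unknown:
            raise KeyError(f"unknown indicator id(s) in fitness: {unknown}")
        self._needs_spei = any(
            self._registry[i].statistic == "spei" for i in config.indicator_ids
        )
        self.wb: WaterBalanceSeries | None = (
            climatic_water_balance(series) if self._needs_spei else None
        )

    def score(self, chromosome: Sequence[float]) -> FitnessScore:
        cfg = self.config
        params = replace(self.base_params, tsums=tuple(float(g) for g in chromosome))
        track = ph.simulate_multiphase(self.series, params, stage_map=self.stage_map)
        if not track.complete:
            return FitnessScore(
                total=-cfg.incomplete_penalty,
                penalties={"incomplete_season": cfg.incomplete_penalty},
                season_complete=False,
            )
        results = compute_indicators(
            self.series,
            params.sowing_date,
            track,
            self.stage_map,
            selection=list(cfg.indicator_ids),
            mode="dynamic",
            wb=self.wb,
            min_reference=cfg.min_reference,
        )
        penalties: dict[int | str, float] = {}
        for r in results:
            penalties[r.id] = self._penalty(r) * cfg.weight(r.id)
        total = -float(sum(penalties.values()))
        return FitnessScore(total=total, penalties=penalties, season_complete=True)

    def _penalty(self, result: IndicatorResult) -> float:
        spec = self._registry[result.id]
        if spec.statistic == "spei":
            return max(0.0, abs(result.value) - 1.0)
        # day-count indicators: stress days as a fraction of the window
        n_days = (result.window[1] - result.window[0]).days + 1
        return float(result.value) / max(n_days, 1)


def fitness(
    chromosome: Sequence[float],
    series: WeatherSeries,
    config: GAConfig,
    base_params: ph.VarietyParamsMulti,
    bounds: Sequence[tuple[float, float]] | None = None,
    stage_map: Mapping[str, float] | None = None,
) -> FitnessScore:
    """Score a single chromosome (six sub-phase TSUMs, GDD).

    ``bounds`` (default: the typical Italian durum ranges) are enforced;
    out-of-bounds genes are an error rather than silently clipped.
    """
    bounds = tuple(bounds or ph.TABLE_TSUM_BOUNDS)
    for g, (lo, hi) in zip(chromosome, bounds):
        if not lo <= g <= hi:
            raise ValueError(f"gene {g:g} outside bounds [{lo:g}, {hi:g}]")
    return FitnessEvaluator(series, base_params, config, stage_map).score(chromosome)


@dataclass
class GAResult:
    best_chromosome: tuple[float, ...]
    best_fitness: float
    best_score: FitnessScore
    trace: pd.DataFrame  # generation, best, mean, median
    best_track: ph.PhenologyTrack | None


def _ga_run(
    evaluate,
    bounds: Sequence[tuple[float, float]],
    config: GAConfig,
    levels: Sequence[Sequence[float]] | None = None,
) -> tuple[tuple[float, ...], float, pd.DataFrame]:
    """Core GA loop over an arbitrary evaluation callable.

    ``levels`` restricts genes to discrete allowed values (used for
    exhaustive-oracle comparisons); otherwise genes are continuous within
    bounds.
    """
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    for lo, hi in bounds:
        if lo > hi:
            raise ValueError(f"infeasible bounds: [{lo:g}, {hi:g}]")
    n_genes = len(bounds)
    rng = np.random.default_rng(config.seed)

    def random_gene(j: int) -> float:
        if levels is not None:
            return float(rng.choice(levels[j]))
        lo, hi = bounds[j]
        return float(rng.uniform(lo, hi))

    def mutate_gene(j: int, value: float) -> float:
        if levels is not None:
            return float(rng.choice(levels[j]))
        lo, hi = bounds[j]
        sigma = config.mutation_sigma_frac * (hi - lo)
        return float(np.clip(value + rng.normal(0.0, sigma), lo, hi))

    pop = [tuple(random_gene(j) for j in range(n_genes)) for _ in range(config.population_size)]
    fits = [evaluate(ind) for ind in pop]

    trace_rows = []
    best_ind, best_fit = max(zip(pop, fits), key=lambda t: t[1])
    for gen in range(config.n_generations):
        order = np.argsort(fits)[::-1]
        elite = [pop[i] for i in order[: config.elitism]]
        children: list[tuple[float, ...]] = list(elite)
        while len(children) < config.population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(pop), size=config.tournament_size)
                winner = max(contenders, key=lambda i: fits[i])
                parents.append(pop[winner])
            a, b = parents
            if rng.random() < config.crossover_prob:
                mask = rng.random(n_genes) < 0.5
                child = tuple(a[j] if mask[j] else b[j] for j in range(n_genes))
            else:
                child = a
            child = tuple(
                mutate_gene(j, g) if rng.random() < config.mutation_prob else g
                for j, g in enumerate(child)
            )
            children.append(child)
        pop = children
        fits = [evaluate(ind) for ind in pop]
        gen_best_i = int(np.argmax(fits))
        if fits[gen_best_i] > best_fit:
            best_fit = fits[gen_best_i]
            best_ind = pop[gen_best_i]
        trace_rows.append(
            {
                "generation": gen,
                "best": best_fit,
                "mean": float(np.mean(fits)),
                "median": float(np.median(fits)),
            }
        )
    return best_ind, best_fit, pd.DataFrame(trace_rows)


def ga_optimize(
    series: WeatherSeries,
    base_params: ph.VarietyParamsMulti,
    config: GAConfig,
    bounds: Sequence[tuple[float, float]] | None = None,
    stage_map: Mapping[str, float] | None = None,
    levels: Sequence[Sequence[float]] | None = None,
) -> GAResult:
    """GA search for the six sub-phase thermal requirements maximizing the
    fitness on one weather series.  Deterministic given ``config.seed``.

    With ``elitism >= 1`` the best-so-far fitness is non-decreasing across
    generations.
    """
    bounds = tuple(bounds or ph.TABLE_TSUM_BOUNDS)
    evaluator = FitnessEvaluator(series, base_params, config, stage_map)
    cache: dict[tuple[float, ...], float] = {}

    def evaluate(ind: tuple[float, ...]) -> float:
        if ind not in cache:
            cache[ind] = evaluator.score(ind).total
        return cache[ind]

    best_ind, best_fit, trace = _ga_run(evaluate, bounds, config, levels=levels)
    best_score = evaluator.score(best_ind)
    params = replace(base_params, tsums=best_ind)
    track = ph.simulate_multiphase(series, params, stage_map=evaluator.stage_map)
    return GAResult(
        best_chromosome=best_ind,
        best_fitness=best_fit,
        best_score=best_score,
        trace=trace,
        best_track=track,
    )


def ga_optimize_ensemble(
    ensemble: WeatherEnsemble,
    base_params: ph.VarietyParamsMulti,
    config: GAConfig,
    bounds: Sequence[tuple[float, float]] | None = None,
    stage_map: Mapping[str, float] | None = None,
    levels: Sequence[Sequence[float]] | None = None,
) -> GAResult:
    """GA search where fitness is the unweighted mean over ensemble members
    (every climate realization counts equally)."""
    bounds = tuple(bounds or ph.TABLE_TSUM_BOUNDS)
    evaluators = [
        FitnessEvaluator(m, base_params, config, stage_map) for m in ensemble.members
    ]
    cache: dict[tuple[float, ...], float] = {}

    def evaluate(ind: tuple[float, ...]) -> float:
        if ind not in cache:
            cache[ind] = float(np.mean([ev.score(ind).total for ev in evaluators]))
        return cache[ind]

    best_ind, best_fit, trace = _ga_run(evaluate, bounds, config, levels=levels)
    member_scores = [ev.score(best_ind) for ev in evaluators]
    mean_total = float(np.mean([s.total for s in member_scores]))
    best_score = FitnessScore(
        total=mean_total,
        penalties={"per_member_totals": [s.total for s in member_scores]},  # type: ignore[dict-item]
        season_complete=all(s.season_complete for s in member_scores),
    )
    return GAResult(
        best_chromosome=best_ind,
        best_fitness=best_fit,
        best_score=best_score,
        trace=trace,
        best_track=None,
    )
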