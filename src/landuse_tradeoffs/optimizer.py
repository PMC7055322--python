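"""Profit-constrained landscape-composition optimization.

A conceptual landscape has L slots (32 by default, matching the plot
count) filled *with replacement* from the study plots, so the search space
is the set of L-multisets — C(n + L - 1, L) combinations, about 9.16e17
for n = L = 32.  A binary genetic algorithm searches this space: each of
the n plots is replicated L times as one gene, giving an n*L chromosome
(1024 genes by default); gene g maps to plot g mod n, and a chromosome
with exactly L ones decodes to a multiset of L plot choices.

A candidate landscape is feasible when its multiplicity-weighted mean
profit reaches the profit expectation; infeasible candidates rank strictly
below every feasible one.  An exhaustive enumerator serves as the exact
oracle on small instances, and a sweep over increasing profit expectations
traces the production-possibility (Pareto) frontier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import GAConfig, LAND_USE_SYSTEMS
from .dataset import Dataset
from .errors import (BudgetExceededError, DomainError, EncodingError,
                     NoFeasibleSolutionError)
from .indices import (direction_corrected, multidiversity_sweep,
                      multifunctionality_sweep)
from .config import ThresholdConfig
from .rng import substream

__all__ = [
    "ObjectiveSpec", "LandscapeSolution", "ParetoSet",
    "search_space_size", "chromosome_length", "decode_chromosome",
    "mean_profit", "run_ga", "brute_force_optimize", "pareto_frontier",
    "composition_shares",
]

GROUP_RICHNESS = "group_richness"
FUNCTION_LEVEL = "function_level"
MULTIDIVERSITY = "multidiversity"
MULTIFUNCTIONALITY = "multifunctionality"

_INFEASIBLE = -1.0  # any feasible fitness lies in [0, 1]


@dataclass(frozen=True)
class ObjectiveSpec:
    """What a landscape is optimized for.

    ``kind`` is one of ``group_richness`` (union species richness of one
    taxonomic group), ``function_level`` (mean standardized indicator
    value of one ecosystem function), ``multidiversity`` or
    ``multifunctionality`` (mean plot-level index at ``threshold``).
    """

    kind: str
    target: str | None = None
    threshold: float = 0.5

    def label(self) -> str:
        return f"{self.kind}:{self.target}" if self.target else self.kind


@dataclass
class LandscapeSolution:
    """A multiset of plot choices with its realized objective and profit."""

    counts: Mapping[str, int]  # plot_id -> multiplicity, summing to L
    realized: float  # objective scaled to [0, 1]
    mean_profit: float  # USD ha-1 yr-1
    shares: Mapping[str, float]  # land-use composition, summing to 1
    expectation: float
    feasible: bool = True

    @property
    def landscape_size(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class ParetoSet:
    """Best solution per profit expectation (None where infeasible)."""

    objective: ObjectiveSpec
    solutions: dict[float, LandscapeSolution | None]

    def realized(self) -> dict[float, float]:
        return {e: s.realized for e, s in self.solutions.items()
                if s is not None}


def search_space_size(L: int, n_plots: int) -> int:
    """Number of L-multisets over n_plots items: C(n_plots + L - 1, L)."""
    if L < 1 or n_plots < 1:
        raise DomainError("L and n_plots must be >= 1")
    return comb(n_plots + L - 1, L)


def chromosome_length(n_plots: int, L: int | None = None) -> int:
    """Genes on one chromosome: each plot replicated once per slot."""
    return n_plots * (L if L is not None else n_plots)


def decode_chromosome(chromosome, n_plots: int) -> np.ndarray:
    """Per-plot multiplicities; gene g contributes to plot g mod n_plots."""
    chrom = np.asarray(chromosome)
    if chrom.ndim != 1 or chrom.size % n_plots != 0:
        raise EncodingError(
            f"chromosome length {chrom.size} is not a multiple of {n_plots}"
        )
    return np.bincount(np.flatnonzero(chrom) % n_plots, minlength=n_plots)


class _Problem:
    """Vectorized objective/profit evaluation over count matrices."""

    def __init__(self, dataset: Dataset, spec: ObjectiveSpec,
                 plot_profits: pd.DataFrame):
        self.spec = spec
        if spec.kind == GROUP_RICHNESS:
            if spec.target not in dataset.incidence:
                raise LookupError(f"unknown taxonomic group {spec.target!r}")
            mat = dataset.incidence[spec.target]
            self.plot_ids = list(mat.index)
            self._M = mat.to_numpy(dtype=bool)
            if self._M.shape[1] == 0:
                raise DomainError(f"group {spec.target!r} has no species")
            self._values = None
        elif spec.kind == FUNCTION_LEVEL:
            meta = dataset.functions_meta
            inds = meta.index[meta["function_group"] == spec.target]
            if len(inds) == 0:
                raise LookupError(f"unknown function group {spec.target!r}")
            corrected = direction_corrected(dataset.functions[list(inds)],
                                            meta.loc[inds])
            lo, hi = corrected.min(axis=0), corrected.max(axis=0)
            span = (hi - lo).replace(0.0, 1.0)
            std = (corrected - lo) / span  # min-max per indicator, in [0,1]
            self.plot_ids = list(dataset.functions.index)
            self._values = std.mean(axis=1).to_numpy(dtype=float)
            self._M = None
        elif spec.kind in (MULTIDIVERSITY, MULTIFUNCTIONALITY):
            cfg = ThresholdConfig(thresholds=(spec.threshold,))
            if spec.kind == MULTIDIVERSITY:
                table = multidiversity_sweep(dataset.richness(), cfg)
            else:
                table = multifunctionality_sweep(
                    dataset.functions, dataset.functions_meta, cfg)
            self.plot_ids = list(table.index)
            self._values = table.iloc[:, 0].to_numpy(dtype=float)
            self._M = None
        else:
            raise LookupError(f"unknown objective kind {spec.kind!r}")

        missing = [p for p in self.plot_ids if p not in plot_profits.index]
        if missing:
            raise LookupError(f"no profit estimate for plots {missing}")
        self.mu = plot_profits.loc[self.plot_ids, "profit_mean"].to_numpy(float)

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    def realized(self, counts: np.ndarray) -> np.ndarray:
        """Objective in [0, 1] for each row of a (K, n_plots) count matrix."""
        counts = np.atleast_2d(counts)
        L = counts.sum(axis=1)
        if self.spec.kind == GROUP_RICHNESS:
            union = ((counts > 0) @ self._M) > 0
            return union.sum(axis=1) / self._M.shape[1]
        return (counts @ self._values) / L

    def profit(self, counts: np.ndarray) -> np.ndarray:
        counts = np.atleast_2d(counts)
        return (counts @ self.mu) / counts.sum(axis=1)


def mean_profit(counts: Mapping[str, int] | np.ndarray,
                plot_profits: pd.DataFrame,
                plot_ids: Sequence[str] | None = None) -> float:
    """Multiplicity-weighted mean plot profit of a landscape multiset."""
    if isinstance(counts, Mapping):
        items = [(p, c) for p, c in counts.items() if c > 0]
        total = sum(c for _, c in items)
        if total == 0:
            raise DomainError("empty landscape multiset")
        missing = [p for p, _ in items if p not in plot_profits.index]
        if missing:
            raise LookupError(f"no profit for plots {missing}")
        return float(sum(plot_profits.loc[p, "profit_mean"] * c
                         for p, c in items) / total)
    counts = np.asarray(counts)
    if counts.sum() == 0:
        raise DomainError("empty landscape multiset")
    mu = plot_profits.loc[list(plot_ids), "profit_mean"].to_numpy(float)
    return float((counts @ mu) / counts.sum())


def composition_shares(counts: Mapping[str, int],
                       plots: pd.DataFrame) -> dict[str, float]:
    """Share of slots per land-use system (all four systems reported)."""
    total = sum(counts.values())
    if total == 0:
        raise DomainError("empty landscape multiset")
    shares = {lu: 0.0 for lu in LAND_USE_SYSTEMS}
    for pid, c in counts.items():
        shares[plots.loc[pid, "land_use"]] += c / total
    return shares


def _solution(problem: _Problem, counts: np.ndarray, plots: pd.DataFrame,
              expectation: float) -> LandscapeSolution:
    counts = np.asarray(counts)
    realized = float(problem.realized(counts)[0])
    prof = float(problem.profit(counts)[0])
    cmap = {p: int(c) for p, c in zip(problem.plot_ids, counts) if c > 0}
    return LandscapeSolution(
        counts=cmap, realized=realized, mean_profit=prof,
        shares=composition_shares(cmap, plots), expectation=float(expectation),
        feasible=prof >= expectation,
    )


def _fitness(realized: np.ndarray, profit: np.ndarray,
             expectation: float) -> np.ndarray:
    """Constraint dominance: feasible candidates keep their objective,
    infeasible ones rank strictly below, graded by profit shortfall."""
    shortfall = (expectation - profit) / (abs(expectation) + 1.0)
    return np.where(profit >= expectation, realized,
                    _INFEASIBLE - shortfall)


def run_ga(spec: ObjectiveSpec, expectation: float, dataset: Dataset,
           config: GAConfig | None = None,
           plot_profits: pd.DataFrame | None = None) -> LandscapeSolution:
    """Best feasible landscape found by the binary genetic algorithm.

    Deterministic for a given seed.  Raises
    :class:`NoFeasibleSolutionError` when no evaluated landscape met the
    profit expectation.
    """
    config = config or GAConfig()
    config.validate()
    profits = plot_profits if plot_profits is not None else dataset.plot_profits
    if profits is None:
        raise LookupError("dataset has no plot profits")
    problem = _Problem(dataset, spec, profits)
    n = problem.n_plots
    L = config.landscape_size if config.landscape_size is not None else n
    if not 1 <= L <= n * n:
        raise DomainError(f"landscape_size {L} out of range")
    glen = n * L
    rate = (config.mutation_rate if config.mutation_rate is not None
            else 1.0 / (glen + 1))
    rng = substream(config.seed, f"ga:{spec.label()}:{expectation}")

    P = config.population_size
    n_elite = max(1, int(round(config.elitism_fraction * P)))

    # exactly-L-ones initial population
    pop = np.zeros((P, glen), dtype=bool)
    order = np.argsort(rng.random((P, glen)), axis=1)
    np.put_along_axis(pop, order[:, :L], True, axis=1)

    def decode(pop_matrix: np.ndarray) -> np.ndarray:
        idx = np.arange(glen) % n
        counts = np.zeros((pop_matrix.shape[0], n), dtype=np.int32)
        np.add.at(counts.T, idx, pop_matrix.T)  # scatter genes onto plots
        return counts

    def repair(row: np.ndarray) -> None:
        d = int(row.sum()) - L
        if d > 0:
            ones = np.flatnonzero(row)
            row[rng.choice(ones, size=d, replace=False)] = False
        elif d < 0:
            zeros = np.flatnonzero(~row)
            row[rng.choice(zeros, size=-d, replace=False)] = True

    best_counts, best_fit = None, -np.inf
    for _ in range(config.generations):
        counts = decode(pop)
        realized = problem.realized(counts)
        profit = problem.profit(counts)
        fitness = _fitness(realized, profit, expectation)

        gbest = int(np.argmax(fitness))
        if fitness[gbest] > best_fit and profit[gbest] >= expectation:
            best_fit = float(fitness[gbest])
            best_counts = counts[gbest].copy()

        order = np.argsort(-fitness, kind="stable")
        elites = pop[order[:n_elite]]

        # tournament(2) parent selection
        n_off = P - n_elite
        cand = rng.integers(0, P, size=(2, 2 * n_off))
        parents_idx = np.where(fitness[cand[0]] >= fitness[cand[1]],
                               cand[0], cand[1])
        pa, pb = parents_idx[:n_off], parents_idx[n_off:]
        # single-point crossover
        points = rng.integers(1, glen, size=n_off)
        mask = np.arange(glen)[None, :] < points[:, None]
        children = np.where(mask, pop[pa], pop[pb])
        # bit-flip mutation
        flips = rng.random((n_off, glen)) < rate
        children ^= flips
        for row in children:
            repair(row)
        pop = np.concatenate([elites, children], axis=0)

    # final evaluation of the last generation
    counts = decode(pop)
    fitness = _fitness(problem.realized(counts), problem.profit(counts),
                       expectation)
    gbest = int(np.argmax(fitness))
    if fitness[gbest] > best_fit and fitness[gbest] >= 0:
        best_counts = counts[gbest].copy()

    if best_counts is None:
        raise NoFeasibleSolutionError(
            f"no landscape reached expectation {expectation} "
            f"(max plot profit {problem.mu.max():.1f})"
        )
    return _solution(problem, best_counts, dataset.plots, expectation)


def brute_force_optimize(spec: ObjectiveSpec, expectation: float,
                         dataset: Dataset, L: int | None = None,
                         plot_profits: pd.DataFrame | None = None,
                         budget: int = 10**6) -> LandscapeSolution:
    """Exact optimum by full multiset enumeration (small instances only).

    Ties are broken toward the lexicographically smallest multiset of plot
    indices.  Refuses with a size report when the enumeration would exceed
    ``budget`` candidates.
    """
    profits = plot_profits if plot_profits is not None else dataset.plot_profits
    if profits is None:
        raise LookupError("dataset has no plot profits")
    problem = _Problem(dataset, spec, profits)
    n = problem.n_plots
    L = L if L is not None else n
    size = search_space_size(L, n)
    if size > budget:
        raise BudgetExceededError(
            f"enumeration of {size} multisets exceeds budget {budget}"
        )
    best_counts, best_val = None, -np.inf
    for combo in combinations_with_replacement(range(n), L):
        counts = np.bincount(combo, minlength=n)
        if float(problem.profit(counts)[0]) < expectation:
            continue
        val = float(problem.realized(counts)[0])
        if val > best_val:  # strict: first (lex-smallest) multiset wins ties
            best_val, best_counts = val, counts
    if best_counts is None:
        raise NoFeasibleSolutionError(
            f"no multiset of size {L} reaches expectation {expectation}"
        )
    return _solution(problem, best_counts, dataset.plots, expectation)


DEFAULT_EXPECTATIONS = (0.0, 200.0, 400.0, 600.0, 800.0, 1000.0)


def pareto_frontier(spec: ObjectiveSpec,
                    expectations: Sequence[float] = DEFAULT_EXPECTATIONS,
                    dataset: Dataset | None = None,
                    config: GAConfig | None = None,
                    plot_profits: pd.DataFrame | None = None) -> ParetoSet:
    """One optimized landscape per profit expectation.

    Because feasible sets are nested (a landscape feasible at a high
    expectation is feasible at every lower one), monotonicity of the
    realized objective is repaired post hoc: a better solution found at a
    higher expectation replaces a worse one at a lower expectation.
    """
    exps = list(expectations)
    if sorted(exps) != exps:
        raise DomainError("expectations must be sorted ascending")
    solutions: dict[float, LandscapeSolution | None] = {}
    for e in exps:
        try:
            solutions[e] = run_ga(spec, e, dataset, config,
                                  plot_profits=plot_profits)
        except NoFeasibleSolutionError:
            solutions[e] = None
    # nested-feasibility repair, walking from high to low expectation
    for hi, lo in zip(reversed(exps[1:]), reversed(exps[:-1])):
        s_hi, s_lo = solutions[hi], solutions[lo]
        if s_hi is not None and (s_lo is None or
                                 s_hi.realized > s_lo.realized):
            solutions[lo] = LandscapeSolution(
                counts=dict(s_hi.counts), realized=s_hi.realized,
                mean_profit=s_hi.mean_profit, shares=dict(s_hi.shares),
                expectation=lo, feasible=True,
            )
    return ParetoSet(objective=spec, solutions=solutions)
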