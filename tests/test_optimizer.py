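"""Landscape optimizer: encoding, objectives, GA vs exhaustive oracle."""

from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landuse_tradeoffs import GAConfig, ObjectiveSpec
from landuse_tradeoffs.dataset import Dataset
from landuse_tradeoffs.errors import (BudgetExceededError, DomainError,
                                      EncodingError, NoFeasibleSolutionError)
from landuse_tradeoffs.optimizer import (_fitness, brute_force_optimize,
                                         chromosome_length,
                                         composition_shares,
                                         decode_chromosome, mean_profit,
                                         pareto_frontier, run_ga,
                                         search_space_size)

from conftest import make_toy_dataset


def test_search_space_size_values():
    assert search_space_size(2, 2) == 3  # {AA, AB, BB}
    assert search_space_size(1, 7) == 7
    assert search_space_size(32, 32) == 916312070471295267


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(1, 6), st.integers(1, 6))
def test_search_space_size_matches_enumeration(L, n):
    count = sum(1 for _ in combinations_with_replacement(range(n), L))
    assert search_space_size(L, n) == count


def test_chromosome_length_binary_encoding():
    assert chromosome_length(32) == 1024


def test_decode_chromosome():
    chrom = np.zeros(1024, dtype=int)
    chrom[[0, 33]] = 1
    counts = decode_chromosome(chrom, 32)
    assert counts[0] == 1 and counts[1] == 1 and counts.sum() == 2
    assert (decode_chromosome(np.ones(1024, dtype=int), 32) == 32).all()
    assert decode_chromosome(np.zeros(1024, dtype=int), 32).sum() == 0
    with pytest.raises(EncodingError):
        decode_chromosome(np.zeros(1000, dtype=int), 32)


def test_mean_profit_examples(toy_ds):
    pp = toy_ds.plot_profits
    assert mean_profit({"p5": 32}, pp) == pytest.approx(1000.0)
    assert mean_profit({"p0": 16, "p5": 16}, pp) == pytest.approx(500.0)
    with pytest.raises(DomainError):
        mean_profit({}, pp)
    with pytest.raises(LookupError):
        mean_profit({"nope": 3}, pp)


def test_fitness_constraint_dominance():
    realized = np.array([0.8, 1.0])
    profit = np.array([600.0, 300.0])
    fit = _fitness(realized, profit, expectation=500.0)
    assert fit[0] > fit[1]  # feasible 0.8 outranks infeasible 1.0
    assert _fitness(np.array([0.0]), np.array([0.0]), 0.0)[0] == 0.0


def test_union_richness_semantics():
    """Duplicated plots contribute no extra species; union over distinct
    included plots divided by the group's pool."""
    ds = make_toy_dataset()
    inc = pd.DataFrame([[1, 1, 0], [0, 1, 1]],
                       index=pd.Index(["p0", "p1"], name="plot_id"),
                       columns=["s1", "s2", "s3"])
    plots = ds.plots.loc[["p0", "p1"]]
    pp = ds.plot_profits.loc[["p0", "p1"]]
    small = Dataset(plots, {"g": inc}, ds.functions.loc[["p0", "p1"]],
                    ds.functions_meta, plot_profits=pp)
    spec = ObjectiveSpec("group_richness", "g")
    both = brute_force_optimize(spec, 0.0, small, L=2)
    assert both.realized == pytest.approx(1.0)  # union of A and B = 3/3
    # profit constraint forcing two copies of the first plot: duplicates
    # contribute no additional species
    only_a = brute_force_optimize(spec, 10.0, small, L=2,
                                  plot_profits=pp.assign(
                                      profit_mean=[10.0, 0.0]))
    assert only_a.counts == {"p0": 2}
    assert only_a.realized == pytest.approx(2 / 3)


def test_function_level_objective_standardization(toy_ds):
    """One-indicator function: realized is the mean min-max-standardized
    slot value, so the best plot alone scores 1."""
    spec = ObjectiveSpec("function_level", "alpha")
    best = brute_force_optimize(spec, 0.0, toy_ds, L=2)
    assert best.realized == pytest.approx(1.0, abs=1e-9)


def test_two_plot_private_species_tradeoff():
    """{P1: profit 0, 10 private species; P2: profit 1000, 2 private},
    L = 2, expectation 500: the optimum takes one of each."""
    ids = pd.Index(["P1", "P2"], name="plot_id")
    plots = pd.DataFrame({"land_use": ["F", "O"], "landscape": "L1",
                          "yield_kg_ha_yr": [0.0, 100.0]}, index=ids)
    inc = np.zeros((2, 12), dtype=int)
    inc[0, :10] = 1
    inc[1, 10:] = 1
    incidence = {"g": pd.DataFrame(inc, index=ids)}
    functions = pd.DataFrame({"f": [1.0, 2.0]}, index=ids)
    meta = pd.DataFrame({"function_group": ["A"],
                         "direction": ["higher_better"]},
                        index=pd.Index(["f"], name="indicator"))
    pp = pd.DataFrame({"profit_mean": [0.0, 1000.0], "me_variance": 0.0},
                      index=ids)
    ds = Dataset(plots, incidence, functions, meta, plot_profits=pp)
    sol = brute_force_optimize(ObjectiveSpec("group_richness", "g"), 500.0,
                               ds, L=2)
    assert sol.counts == {"P1": 1, "P2": 1}
    assert sol.mean_profit == pytest.approx(500.0)
    assert sol.realized == pytest.approx(1.0)


@pytest.mark.parametrize("kind,target", [
    ("group_richness", "toygroup"),
    ("multidiversity", None),
])
def test_ga_matches_exhaustive_oracle(toy_ds, kind, target):
    """GA attains the enumeration optimum on the 126-candidate toy."""
    spec = ObjectiveSpec(kind, target)
    for expectation in (0.0, 500.0):
        oracle = brute_force_optimize(spec, expectation, toy_ds, L=4)
        for seed in range(5):
            sol = run_ga(spec, expectation, toy_ds,
                         GAConfig(population_size=100, generations=50,
                                  landscape_size=4, seed=seed))
            assert sol.realized == pytest.approx(oracle.realized, abs=1e-12)
            assert sol.mean_profit >= expectation


def test_ga_seeded_determinism(toy_ds):
    spec = ObjectiveSpec("group_richness", "toygroup")
    cfg = GAConfig(population_size=60, generations=30, landscape_size=4,
                   seed=11)
    a = run_ga(spec, 300.0, toy_ds, cfg)
    b = run_ga(spec, 300.0, toy_ds, cfg)
    assert a.counts == b.counts and a.realized == b.realized


def test_infeasible_expectation_raises(toy_ds):
    spec = ObjectiveSpec("group_richness", "toygroup")
    with pytest.raises(NoFeasibleSolutionError):
        run_ga(spec, 5000.0, toy_ds,
               GAConfig(population_size=20, generations=5, landscape_size=4))
    with pytest.raises(NoFeasibleSolutionError):
        brute_force_optimize(spec, 5000.0, toy_ds, L=4)


def test_brute_force_budget(toy_ds):
    with pytest.raises(BudgetExceededError):
        brute_force_optimize(ObjectiveSpec("group_richness", "toygroup"),
                             0.0, toy_ds, L=4, budget=100)


def test_landscape_size_follows_group_coverage(default_ds):
    """Groups sampled on fewer plots get correspondingly smaller landscapes."""
    sol = run_ga(ObjectiveSpec("group_richness", "soil_fungi"), 0.0,
                 default_ds, GAConfig(population_size=30, generations=5,
                                      seed=0))
    assert sol.landscape_size == 30
    sol31 = run_ga(ObjectiveSpec("group_richness", "birds"), 0.0,
                   default_ds, GAConfig(population_size=30, generations=5,
                                        seed=0))
    assert sol31.landscape_size == 31


def test_adding_a_plot_never_decreases_union_richness(default_ds):
    from landuse_tradeoffs.optimizer import _Problem
    problem = _Problem(default_ds, ObjectiveSpec("group_richness", "trees"),
                       default_ds.plot_profits)
    rng = np.random.default_rng(0)
    n = problem.n_plots
    for _ in range(50):
        counts = rng.integers(0, 3, n)
        if counts.sum() == 0:
            counts[0] = 1
        base = problem.realized(counts)[0]
        extra = counts.copy()
        extra[rng.integers(n)] += 1
        assert problem.realized(extra)[0] >= base - 1e-12


def test_composition_shares(toy_ds):
    shares = composition_shares({"p0": 16, "p3": 16}, toy_ds.plots)
    assert shares == {"F": 0.5, "J": 0.0, "R": 0.0, "O": 0.5}
    assert composition_shares({"p2": 30}, toy_ds.plots)["R"] == 1.0


def test_pareto_monotone_on_toy(toy_ds):
    spec = ObjectiveSpec("group_richness", "toygroup")
    fr = pareto_frontier(spec, (0.0, 300.0, 600.0, 900.0), toy_ds,
                         GAConfig(population_size=80, generations=40,
                                  landscape_size=4, seed=2))
    realized = [s.realized for s in fr.solutions.values() if s is not None]
    assert all(a >= b - 1e-12 for a, b in zip(realized, realized[1:]))
    for sol in fr.solutions.values():
        if sol is not None:
            assert sum(sol.shares.values()) == pytest.approx(1.0)
            assert sol.landscape_size == 4
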