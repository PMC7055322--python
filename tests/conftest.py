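import numpy as np
import pandas as pd
import pytest

from landuse_tradeoffs import generate_dataset
from landuse_tradeoffs.dataset import Dataset
from landuse_tradeoffs.profits import fit_all_crops, predict_plot_profits


@pytest.fixture(scope="session")
def default_ds():
    """Default synthetic dataset (seed 1) with plot profits attached."""
    ds = generate_dataset(seed=1)
    fits = fit_all_crops(ds.households)
    ds.plot_profits = predict_plot_profits(ds.plots, fits)
    return ds


def make_toy_dataset(profits=(0, 100, 300, 500, 800, 1000), seed=0):
    """Six-plot dataset with one taxon group and two function indicators.

    Small enough that a landscape of four slots has only C(9, 4) = 126
    candidate compositions, so the exhaustive optimizer can serve as an
    exact oracle for the genetic algorithm.
    """
    rng = np.random.default_rng(seed)
    n = len(profits)
    ids = [f"p{i}" for i in range(n)]
    land_use = (["F", "J", "R", "O"] * 2)[:n]
    plots = pd.DataFrame(
        {"land_use": land_use, "landscape": "L1",
         "yield_kg_ha_yr": [0.0 if lu == "F" else 100.0 for lu in land_use]},
        index=pd.Index(ids, name="plot_id"))
    # every species present somewhere; richer low-profit plots
    n_sp = 12
    probs = np.linspace(0.9, 0.3, n)
    inc = (rng.random((n, n_sp)) < probs[:, None]).astype(int)
    for j in range(n_sp):  # guarantee each species occurs at least once
        if inc[:, j].sum() == 0:
            inc[rng.integers(n), j] = 1
    incidence = {"toygroup": pd.DataFrame(
        inc, index=plots.index, columns=[f"s{j}" for j in range(n_sp)])}
    functions = pd.DataFrame(
        {"f_good": np.linspace(10.0, 2.0, n) + rng.normal(0, 0.1, n),
         "f_bad": np.linspace(1.0, 5.0, n) + rng.normal(0, 0.1, n)},
        index=plots.index)
    meta = pd.DataFrame(
        {"function_group": ["alpha", "beta"],
         "direction": ["higher_better", "lower_better"]},
        index=pd.Index(["f_good", "f_bad"], name="indicator"))
    plot_profits = pd.DataFrame(
        {"profit_mean": np.asarray(profits, dtype=float),
         "me_variance": 0.0}, index=plots.index)
    return Dataset(plots, incidence, functions, meta,
                   plot_profits=plot_profits)


@pytest.fixture
def toy_ds():
    return make_toy_dataset()
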