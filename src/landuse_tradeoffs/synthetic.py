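"""Seeded synthetic-data generator for the 32-plot study design.

Generates plot metadata, per-taxon species-incidence matrices with partial
turnover between forest and monoculture species pools, ecosystem-function
indicator tables, and a farm-household survey with a linear yield-profit
relation whose residual spread grows proportionally with yield.  Every
generator draws from its own named substream of the root seed, so the
dataset is bit-reproducible and adding a generator never perturbs the
draws of the others.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CROPS, SynthConfig
from .dataset import Dataset
from .errors import ConfigurationError
from .rng import substream

__all__ = [
    "generate_plots",
    "generate_species_incidence",
    "generate_function_indicators",
    "generate_households",
    "generate_dataset",
]


def generate_plots(config: SynthConfig) -> pd.DataFrame:
    """Plot table: land use x landscape block x replicate, with crop yields.

    Yields are Gaussian draws truncated at zero (kg ha^-1 yr^-1); forest
    plots have no crop and carry yield 0.
    """
    config.validate()
    rng = substream(config.seed, "plots")
    rows = []
    for block in range(1, config.n_landscapes + 1):
        landscape = f"L{block}"
        for lu in config.land_use_systems:
            for rep in range(1, config.n_replicates_per_system + 1):
                pid = f"{lu}_{landscape}_{rep}"
                if lu == "F":
                    y = 0.0
                else:
                    spec = config.yields[lu]
                    y = max(0.0, spec.mean + spec.sd * rng.standard_normal())
                rows.append((pid, lu, landscape, y))
    df = pd.DataFrame(rows, columns=["plot_id", "land_use", "landscape",
                                     "yield_kg_ha_yr"])
    return df.set_index("plot_id")


def generate_species_incidence(
    plots: pd.DataFrame, config: SynthConfig
) -> dict[str, pd.DataFrame]:
    """Per-group plot x species presence/absence matrices.

    Each group has a species pool split into a forest pool and a disjoint
    pool of non-forest species.  A plot's expected richness is the
    configured land-use mean; the forest-overlap fraction of it is drawn
    from the forest pool (all of it, for forest plots), the rest from the
    non-forest pool, each species independently (Poisson-binomial
    richness).  Species never observed anywhere are dropped, and a group's
    missing plots are removed from its matrix entirely.
    """
    if not config.taxa:
        raise ConfigurationError("taxa_spec must be non-empty")
    out: dict[str, pd.DataFrame] = {}
    non_f = [p for p in plots.index if plots.loc[p, "land_use"] != "F"]
    for spec in config.taxa:
        rng = substream(config.seed, f"incidence:{spec.name}")
        s_forest = spec.forest_pool_size
        s_total = spec.pool_size
        cols = [f"{spec.name}_sp{i:04d}" for i in range(s_total)]
        mat = np.zeros((len(plots), s_total), dtype=np.int64)
        for i, pid in enumerate(plots.index):
            lu = plots.loc[pid, "land_use"]
            m = float(spec.mean_richness[lu])
            ov = 1.0 if lu == "F" else spec.forest_overlap
            p_forest = (m * ov / s_forest) if s_forest else 0.0
            s_other = s_total - s_forest
            p_other = (m * (1.0 - ov) / s_other) if s_other else 0.0
            if p_forest > 1.0 or p_other > 1.0:
                raise ConfigurationError(
                    f"{spec.name}: mean richness {m} for {lu} exceeds pool"
                )
            u = rng.random(s_total)
            mat[i, :s_forest] = u[:s_forest] < p_forest
            mat[i, s_forest:] = u[s_forest:] < p_other
        df = pd.DataFrame(mat, index=plots.index.copy(), columns=cols)
        if spec.n_missing_plots:
            # sampling gaps occur in managed plots, not in the forest
            drop = rng.choice(non_f, size=spec.n_missing_plots, replace=False)
            df = df.drop(index=list(drop))
        df = df.loc[:, df.sum(axis=0) > 0]  # unseen species do not exist
        out[spec.name] = df
    return out


def generate_function_indicators(
    plots: pd.DataFrame, config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Indicator values (land-use mean + Gaussian noise) and their metadata.

    Returns ``(functions, functions_meta)``; metadata maps each indicator
    to its function group and direction flag.
    """
    rng = substream(config.seed, "functions")
    values = {}
    for spec in config.indicators:
        mu = plots["land_use"].map(spec.means).to_numpy(dtype=float)
        values[spec.name] = mu + spec.sd * rng.standard_normal(len(plots))
    functions = pd.DataFrame(values, index=plots.index.copy())
    meta = pd.DataFrame(
        {
            "function_group": [s.function_group for s in config.indicators],
            "direction": [s.direction for s in config.indicators],
        },
        index=pd.Index([s.name for s in config.indicators], name="indicator"),
    )
    return functions, meta


def generate_households(config: SynthConfig) -> pd.DataFrame:
    """Farm-household survey: per-crop yields and heteroscedastic profits.

    profit = a_c + b_c * yield + e with sd(e) = gamma_c * yield, so the
    profit spread grows linearly in yield and vanishes at yield zero.
    """
    config.validate()
    rng = substream(config.seed, "households")
    rows = []
    hid = 0
    for crop in CROPS:
        hh = config.households[crop]
        ys = config.yields[crop]
        yields = np.maximum(0.0, ys.mean + ys.sd * rng.standard_normal(hh.n))
        noise = rng.standard_normal(hh.n) * hh.gamma * yields
        profits = hh.intercept + hh.slope * yields + noise
        for y, p in zip(yields, profits):
            rows.append((f"hh{hid:04d}", crop, y, p))
            hid += 1
    df = pd.DataFrame(rows, columns=["household_id", "crop", "yield_kg_ha_yr",
                                     "profit_usd_ha_yr"])
    return df.set_index("household_id")


def generate_dataset(config: SynthConfig | None = None,
                     seed: int | None = None) -> Dataset:
    """Generate the full bundle (plots, incidence, functions, households)."""
    config = config or SynthConfig()
    if seed is not None:
        config = config.with_seed(seed)
    plots = generate_plots(config)
    incidence = generate_species_incidence(plots, config)
    functions, meta = generate_function_indicators(plots, config)
    households = generate_households(config)
    return Dataset(plots, incidence, functions, meta, households)
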