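"""Multidiversity and multifunctionality threshold indices.

Both indices score a plot by the proportion of its measured taxonomic
groups (multidiversity) or ecosystem functions (multifunctionality) whose
performance reaches a threshold fraction of the group's or indicator's
maximum performance level — the mean of the top five plot values, which
damps outliers.  Indicators for which high values mean *less* desirable
functioning are direction-corrected first by range reflection
(max + min - x), an order-reversing, range-preserving involution; within a
function the indicators share the function's weight equally, so each of
the 10 functions contributes equally to multifunctionality.  The indices
are computed across the full threshold range (1-99% by default) and
related to plot profits with simple linear regression, with slopes
expressed per 100 USD ha^-1 yr^-1.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import LOWER_BETTER, ThresholdConfig
from .dataset import Dataset
from .errors import (DegenerateDesignError, DomainError,
                     InsufficientDataError, ValidationError)

__all__ = [
    "forest_species_subset",
    "max_performance_level",
    "invert_indicator",
    "multidiversity",
    "multifunctionality",
    "multidiversity_sweep",
    "multifunctionality_sweep",
    "threshold_sweep",
    "index_profit_slope",
]


def forest_species_subset(incidence: pd.DataFrame,
                          plots: pd.DataFrame) -> pd.DataFrame:
    """Keep only species recorded on at least one forest (F) plot."""
    forest_ids = [p for p in incidence.index
                  if p in plots.index and plots.loc[p, "land_use"] == "F"]
    if not forest_ids:
        raise DomainError("no forest plots available for the subset")
    keep = incidence.loc[forest_ids].sum(axis=0) > 0
    return incidence.loc[:, keep]


def max_performance_level(values, top_k: int = 5) -> float:
    """Mean of the ``top_k`` highest finite values (all of them if fewer)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise DomainError("no finite values for the performance level")
    k = min(int(top_k), v.size)
    return float(np.mean(np.sort(v)[-k:]))


def invert_indicator(values):
    """Range reflection x' = max(x) + min(x) - x.

    Order-reversing and range-preserving; applying it twice restores the
    input.  Used to direction-correct indicators where high raw values are
    undesirable (e.g. nutrient leaching) before thresholding.
    """
    v = np.asarray(values, dtype=float)
    return v.max() + v.min() - v


def multidiversity(richness: Mapping[str, float],
                   levels: Mapping[str, float],
                   threshold: float) -> float:
    """Proportion of measured groups at or above threshold * level.

    Groups with missing (NaN) richness on this plot are excluded from both
    numerator and denominator.
    """
    if not 0 < threshold < 1:
        raise DomainError("threshold must lie in (0, 1)")
    measured = [g for g, r in richness.items() if np.isfinite(r)]
    if not measured:
        raise DomainError("no groups measured on this plot")
    passed = sum(richness[g] >= threshold * levels[g] for g in measured)
    return passed / len(measured)


def _weights(meta: pd.DataFrame) -> pd.Series:
    counts = meta.groupby("function_group")["direction"].transform("size")
    w = 1.0 / counts
    sums = w.groupby(meta["function_group"]).sum()
    if not np.allclose(sums, 1.0):
        raise ValidationError("indicator weights must sum to 1 per function")
    return w


def multifunctionality(indicators: Mapping[str, float],
                       meta: pd.DataFrame,
                       levels: Mapping[str, float],
                       threshold: float) -> float:
    """Weighted proportion of direction-corrected indicators passing the
    threshold, normalized by the number of function groups.

    ``indicators`` must already be direction-corrected (same transform
    under which ``levels`` were computed).
    """
    if not 0 < threshold < 1:
        raise DomainError("threshold must lie in (0, 1)")
    w = _weights(meta)
    n_functions = meta["function_group"].nunique()
    total = 0.0
    for ind, x in indicators.items():
        if np.isfinite(x) and x >= threshold * levels[ind]:
            total += w[ind]
    return total / n_functions


def direction_corrected(functions: pd.DataFrame,
                        meta: pd.DataFrame) -> pd.DataFrame:
    """Reflect every lower-is-better indicator column."""
    out = functions.copy()
    for ind in meta.index[meta["direction"] == LOWER_BETTER]:
        out[ind] = invert_indicator(out[ind].to_numpy())
    return out


def multidiversity_sweep(richness: pd.DataFrame,
                         config: ThresholdConfig | None = None) -> pd.DataFrame:
    """Plot x threshold multidiversity table from a plot x group richness
    table (NaN marks a group not measured on a plot)."""
    config = config or ThresholdConfig()
    config.validate()
    thr = np.asarray(config.thresholds, dtype=float)
    levels = np.array([max_performance_level(richness[g], config.top_k)
                       for g in richness.columns])
    R = richness.to_numpy(dtype=float)  # P x G
    measured = np.isfinite(R)
    if not measured.any(axis=1).all():
        raise DomainError("a plot has no measured groups")
    # P x G x T pass indicator, averaged over measured groups
    passes = R[:, :, None] >= thr[None, None, :] * levels[None, :, None]
    passes &= measured[:, :, None]
    values = passes.sum(axis=1) / measured.sum(axis=1)[:, None]
    return pd.DataFrame(values, index=richness.index, columns=thr)


def multifunctionality_sweep(functions: pd.DataFrame,
                             meta: pd.DataFrame,
                             config: ThresholdConfig | None = None,
                             ) -> pd.DataFrame:
    """Plot x threshold multifunctionality table."""
    config = config or ThresholdConfig()
    config.validate()
    thr = np.asarray(config.thresholds, dtype=float)
    meta = meta.loc[functions.columns]
    w = _weights(meta).to_numpy()
    n_functions = meta["function_group"].nunique()
    corrected = direction_corrected(functions, meta)
    levels = np.array([max_performance_level(corrected[i], config.top_k)
                       for i in corrected.columns])
    X = corrected.to_numpy(dtype=float)  # P x I
    passes = X[:, :, None] >= thr[None, None, :] * levels[None, :, None]
    values = (passes * w[None, :, None]).sum(axis=1) / n_functions
    return pd.DataFrame(values, index=functions.index, columns=thr)


def threshold_sweep(dataset: Dataset, kind: str,
                    config: ThresholdConfig | None = None,
                    forest_only: bool = False) -> pd.DataFrame:
    """Index table for ``kind`` in {multidiversity, multifunctionality}."""
    if kind == "multidiversity":
        return multidiversity_sweep(dataset.richness(forest_only), config)
    if kind == "multifunctionality":
        return multifunctionality_sweep(dataset.functions,
                                        dataset.functions_meta, config)
    raise LookupError(f"unknown index kind {kind!r}")


def index_profit_slope(index_table: pd.DataFrame,
                       profits: pd.DataFrame) -> pd.DataFrame:
    """Per-threshold OLS slope of the index on profit, per 100 USD.

    Returns a table with columns ``slope_per_100usd``, ``lo``, ``hi``
    (95% confidence bounds), indexed by threshold.
    """
    common = index_table.index.intersection(profits.index)
    if len(common) < 3:
        raise InsufficientDataError("need >= 3 plots with profits")
    x = profits.loc[common, "profit_mean"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant profits")
    tcrit = stats.t.ppf(0.975, len(common) - 2)
    rows = []
    for thr in index_table.columns:
        yv = index_table.loc[common, thr].to_numpy(dtype=float)
        res = stats.linregress(x, yv)
        slope = res.slope * 100.0
        half = tcrit * res.stderr * 100.0
        rows.append((float(thr), slope, slope - half, slope + half))
    return pd.DataFrame(rows, columns=["threshold", "slope_per_100usd",
                                       "lo", "hi"]).set_index("threshold")
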