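"""Dataset bundle: loading, validation, and CSV round-trip.

A dataset directory holds plain CSV tables::

    plots.csv            plot_id, land_use, landscape, yield_kg_ha_yr
    incidence_<group>.csv  plot_id + one 0/1 column per species
    functions.csv        plot_id + one column per indicator
    functions_meta.csv   indicator, function_group, direction
    households.csv       household_id, crop, yield_kg_ha_yr, profit_usd_ha_yr
    plot_profits.csv     plot_id, profit_mean, me_variance   (optional)

Incidence tables may omit plot rows for groups that were not sampled on
every plot; all other tables must cover every plot.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import HIGHER_BETTER, LOWER_BETTER, LAND_USE_SYSTEMS
from .errors import ValidationError

_GROUP_FILE_RE = re.compile(r"incidence_(.+)\.csv$")


@dataclass
class Dataset:
    """In-memory bundle of all plot-level tables, indexed by plot_id."""

    plots: pd.DataFrame
    incidence: Mapping[str, pd.DataFrame]
    functions: pd.DataFrame
    functions_meta: pd.DataFrame
    households: pd.DataFrame | None = None
    plot_profits: pd.DataFrame | None = None

    @property
    def plot_ids(self) -> list[str]:
        return list(self.plots.index)

    @property
    def taxon_groups(self) -> list[str]:
        return list(self.incidence)

    def richness(self, forest_only: bool = False) -> pd.DataFrame:
        """Plot x group species-richness table (NaN where a group is missing).

        With ``forest_only`` richness counts only species recorded on at
        least one forest plot.
        """
        from .indices import forest_species_subset

        out = pd.DataFrame(index=self.plots.index, dtype=float)
        for group, mat in self.incidence.items():
            if forest_only:
                mat = forest_species_subset(mat, self.plots)
            out[group] = mat.sum(axis=1).reindex(self.plots.index)
        return out

    def write(self, outdir) -> list[Path]:
        """Write every table as CSV; returns the written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def _w(df: pd.DataFrame, name: str, index_label=None):
            p = outdir / name
            df.to_csv(p, index=index_label is not None, index_label=index_label)
            written.append(p)

        _w(self.plots, "plots.csv", "plot_id")
        for group, mat in self.incidence.items():
            _w(mat, f"incidence_{group}.csv", "plot_id")
        _w(self.functions, "functions.csv", "plot_id")
        _w(self.functions_meta, "functions_meta.csv", "indicator")
        if self.households is not None:
            _w(self.households, "households.csv", "household_id")
        if self.plot_profits is not None:
            _w(self.plot_profits, "plot_profits.csv", "plot_id")
        return written


def _err(problems: list[str]) -> None:
    if problems:
        raise ValidationError("dataset validation failed:\n  " +
                              "\n  ".join(problems))


def validate_dataset(ds: Dataset) -> None:
    """Cross-check every table; raise :class:`ValidationError` listing all
    problems with file, column and row context."""
    problems: list[str] = []
    plots = ds.plots
    for col in ("land_use", "landscape", "yield_kg_ha_yr"):
        if col not in plots.columns:
            problems.append(f"plots.csv: missing column {col!r}")
    if problems:
        _err(problems)

    bad_lu = plots.index[~plots["land_use"].isin(LAND_USE_SYSTEMS)]
    for pid in bad_lu:
        problems.append(f"plots.csv: row {pid!r}: unknown land_use "
                        f"{plots.loc[pid, 'land_use']!r}")
    y = pd.to_numeric(plots["yield_kg_ha_yr"], errors="coerce")
    for pid in plots.index[y.isna() | (y < 0)]:
        problems.append(f"plots.csv: row {pid!r}: invalid yield")
    forest_nonzero = plots.index[(plots["land_use"] == "F") & (y != 0)]
    for pid in forest_nonzero:
        problems.append(f"plots.csv: row {pid!r}: forest plot with non-zero yield")

    plot_set = set(plots.index)
    for group, mat in ds.incidence.items():
        fname = f"incidence_{group}.csv"
        extra = set(mat.index) - plot_set
        for pid in sorted(extra):
            problems.append(f"{fname}: row {pid!r}: plot not in plots.csv")
        vals = mat.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            problems.append(
                f"{fname}: row {mat.index[i]!r}, column {mat.columns[j]!r}: "
                f"value {vals[i, j]!r} is not 0/1"
            )
        if mat.shape[1] and (mat.sum(axis=0) == 0).any():
            col = mat.columns[(mat.sum(axis=0) == 0).argmax()]
            problems.append(f"{fname}: column {col!r}: species never present")

    extra = set(ds.functions.index) - plot_set
    for pid in sorted(extra):
        problems.append(f"functions.csv: row {pid!r}: plot not in plots.csv")
    missing = plot_set - set(ds.functions.index)
    for pid in sorted(missing):
        problems.append(f"functions.csv: missing plot {pid!r}")
    if ds.functions.isna().any().any():
        col = ds.functions.columns[ds.functions.isna().any().argmax()]
        problems.append(f"functions.csv: column {col!r}: missing values")

    meta = ds.functions_meta
    for col in ("function_group", "direction"):
        if col not in meta.columns:
            problems.append(f"functions_meta.csv: missing column {col!r}")
    if not problems:
        bad_dir = meta.index[~meta["direction"].isin((HIGHER_BETTER, LOWER_BETTER))]
        for ind in bad_dir:
            problems.append(f"functions_meta.csv: row {ind!r}: invalid direction")
        unmatched = set(ds.functions.columns) ^ set(meta.index)
        for ind in sorted(unmatched):
            problems.append(
                f"functions_meta.csv: indicator {ind!r} not matched between "
                "functions.csv and functions_meta.csv"
            )

    if ds.households is not None:
        hh = ds.households
        for col in ("crop", "yield_kg_ha_yr", "profit_usd_ha_yr"):
            if col not in hh.columns:
                problems.append(f"households.csv: missing column {col!r}")
        if "crop" in hh.columns:
            bad = hh.index[~hh["crop"].isin(("J", "R", "O"))]
            for hid in bad:
                problems.append(f"households.csv: row {hid!r}: unknown crop")

    if ds.plot_profits is not None:
        pp = ds.plot_profits
        extra = set(pp.index) - plot_set
        for pid in sorted(extra):
            problems.append(f"plot_profits.csv: row {pid!r}: plot not in plots.csv")
        if "me_variance" in pp.columns and (pp["me_variance"] < 0).any():
            pid = pp.index[(pp["me_variance"] < 0).argmax()]
            problems.append(f"plot_profits.csv: row {pid!r}: negative me_variance")

    _err(problems)


def load_dataset(path, validate: bool = True) -> Dataset:
    """Load a dataset directory written by :meth:`Dataset.write`."""
    path = Path(path)
    plots = pd.read_csv(path / "plots.csv", index_col="plot_id")
    incidence = {}
    for f in sorted(path.glob("incidence_*.csv")):
        group = _GROUP_FILE_RE.search(f.name).group(1)
        incidence[group] = pd.read_csv(f, index_col="plot_id")
    functions = pd.read_csv(path / "functions.csv", index_col="plot_id")
    functions_meta = pd.read_csv(path / "functions_meta.csv", index_col="indicator")
    households = None
    if (path / "households.csv").exists():
        households = pd.read_csv(path / "households.csv", index_col="household_id")
    plot_profits = None
    if (path / "plot_profits.csv").exists():
        plot_profits = pd.read_csv(path / "plot_profits.csv", index_col="plot_id")
    ds = Dataset(plots, incidence, functions, functions_meta,
                 households, plot_profits)
    if validate:
        validate_dataset(ds)
    return ds
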