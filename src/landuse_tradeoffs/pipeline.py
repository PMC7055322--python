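"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages run in dependency order: simulate -> profits -> simex / indices ->
optimize.  One root seed is split into named per-stage substreams, so the
set of enabled stages never changes any stage's randomness, and re-running
with the same configuration and seed reproduces every output byte for
byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .config import GAConfig, SimexConfig, SynthConfig, ThresholdConfig
from .dataset import Dataset, load_dataset
from .errors import ConfigurationError
from .indices import index_profit_slope, threshold_sweep
from .optimizer import (DEFAULT_EXPECTATIONS, ObjectiveSpec, pareto_frontier)
from .profits import fit_all_crops, predict_plot_profits, write_fits
from .simex import response_profit_curves
from .synthetic import generate_dataset

log = logging.getLogger("landuse_tradeoffs")

ALL_STAGES = ("simulate", "profits", "simex", "indices", "optimize")


@dataclass
class RunConfig:
    """Which stages to run, with per-stage settings and one root seed."""

    out_dir: Path
    stages: Sequence[str] = ALL_STAGES
    seed: int = 0
    data_dir: Path | None = None  # pre-existing dataset when not simulating
    synth: SynthConfig | None = None
    simex: SimexConfig | None = None
    thresholds: ThresholdConfig | None = None
    ga: GAConfig | None = None
    simex_targets: Sequence[str] | None = None
    objective: ObjectiveSpec = field(
        default_factory=lambda: ObjectiveSpec("multidiversity"))
    expectations: Sequence[float] = DEFAULT_EXPECTATIONS

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages and self.data_dir is None:
            raise ConfigurationError(
                "data_dir is required when the simulate stage is disabled"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}}

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": sorted(str(p.relative_to(out)) for p in outputs)
        }
        log.info("stage %s: %d output(s)", stage, len(outputs))

    dataset: Dataset
    if "simulate" in config.stages:
        synth = (config.synth or SynthConfig()).with_seed(config.seed)
        dataset = generate_dataset(synth)
        data_dir = out / "dataset"
        written = dataset.write(data_dir)
        record("simulate", written)
    else:
        dataset = load_dataset(config.data_dir)
        log.info("loaded dataset from %s", config.data_dir)

    if "profits" in config.stages:
        if dataset.households is None:
            raise ConfigurationError("profits stage requires households data")
        fits = fit_all_crops(dataset.households)
        dataset.plot_profits = predict_plot_profits(dataset.plots, fits)
        pp_path = out / "plot_profits.csv"
        dataset.plot_profits.to_csv(pp_path, index_label="plot_id")
        fits_path = out / "fits.json"
        write_fits(fits, fits_path)
        record("profits", [pp_path, fits_path])
    elif dataset.plot_profits is None and (
            {"simex", "indices", "optimize"} & set(config.stages)):
        raise ConfigurationError(
            "simex/indices/optimize require plot profits; enable the "
            "profits stage or provide plot_profits.csv"
        )

    if "simex" in config.stages:
        scfg = config.simex or SimexConfig()
        scfg = SimexConfig(**{**scfg.__dict__, "seed": config.seed})
        curves = response_profit_curves(dataset, dataset.plot_profits,
                                        targets=config.simex_targets,
                                        config=scfg)
        sdir = out / "simex"
        sdir.mkdir(exist_ok=True)
        outputs = []
        for name, fit in curves.items():
            p = sdir / (name.replace(":", "_") + ".json")
            p.write_text(json.dumps(fit.to_dict(), indent=2))
            outputs.append(p)
        record("simex", outputs)

    if "indices" in config.stages:
        tcfg = config.thresholds or ThresholdConfig()
        outputs = []
        for kind in ("multidiversity", "multifunctionality"):
            table = threshold_sweep(dataset, kind, tcfg)
            p = out / f"{kind}.csv"
            table.to_csv(p, index_label="plot_id")
            outputs.append(p)
            slopes = index_profit_slope(table, dataset.plot_profits)
            ps = out / f"{kind}_slopes.csv"
            slopes.to_csv(ps)
            outputs.append(ps)
        record("indices", outputs)

    if "optimize" in config.stages:
        gcfg = config.ga or GAConfig()
        gcfg = GAConfig(**{**gcfg.__dict__, "seed": config.seed})
        frontier = pareto_frontier(config.objective, config.expectations,
                                   dataset, gcfg)
        payload = {
            "objective": {"kind": config.objective.kind,
                          "target": config.objective.target,
                          "threshold": config.objective.threshold},
            "seed": config.seed,
            "solutions": {
                str(e): (None if s is None else {
                    "counts": s.counts, "realized": s.realized,
                    "mean_profit": s.mean_profit, "shares": s.shares,
                }) for e, s in frontier.solutions.items()
            },
        }
        p = out / "solutions.json"
        p.write_text(json.dumps(payload, indent=2))
        rows = [(e, s.realized, s.mean_profit) if s is not None
                else (e, np.nan, np.nan)
                for e, s in frontier.solutions.items()]
        import pandas as pd
        fr = pd.DataFrame(rows, columns=["expectation", "realized",
                                         "mean_profit"])
        pf = out / "frontier.csv"
        fr.to_csv(pf, index=False)
        record("optimize", [p, pf])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
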