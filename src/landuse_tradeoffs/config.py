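"""Configuration objects for every pipeline stage.

The synthetic-data configuration encodes the study design this package
emulates: two landscape blocks, four land-use systems (primary degraded
lowland rainforest F, jungle-rubber agroforestry J, rubber monoculture R,
oil-palm monoculture O) with four replicate plots each — 32 plots in
total — plus 14 taxonomic groups, 36 ecosystem-function indicators in 10
function groups, and a farm-household survey of 701 households used to
translate crop yields into profits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError

LAND_USE_SYSTEMS = ("F", "J", "R", "O")
#: crops with a market yield (forest F has none; profit is fixed at zero)
CROPS = ("J", "R", "O")

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"

# Average 2015 exchange rate used when profits are quoted in USD.
IDR_PER_USD = 13389.413


@dataclass(frozen=True)
class TaxonSpec:
    """Species-richness structure of one taxonomic group.

    ``mean_richness`` gives the expected plot-level richness per land-use
    system.  ``forest_overlap`` is the fraction of a non-forest plot's
    expected richness drawn from the forest species pool (the remainder
    comes from a disjoint pool of habitat generalists / exotics), which
    produces partial species turnover between systems.  ``n_missing_plots``
    plots carry no observation for this group (sampling gaps).
    """

    name: str
    pool_size: int
    mean_richness: Mapping[str, float]
    forest_overlap: float
    n_missing_plots: int = 0

    @property
    def forest_pool_size(self) -> int:
        # forest pool is half the group pool (rounded up); roughly half of
        # all species being recorded in rainforest matches the study system
        return int(np.ceil(self.pool_size / 2))

    def validate(self) -> None:
        if self.pool_size < 1:
            raise ConfigurationError(f"{self.name}: pool_size must be >= 1")
        if not 0.0 <= self.forest_overlap <= 1.0:
            raise ConfigurationError(
                f"{self.name}: forest_overlap must lie in [0, 1]"
            )
        if self.n_missing_plots < 0:
            raise ConfigurationError(f"{self.name}: n_missing_plots < 0")
        missing = set(LAND_USE_SYSTEMS) - set(self.mean_richness)
        if missing:
            raise ConfigurationError(
                f"{self.name}: mean_richness missing land uses {sorted(missing)}"
            )
        s_forest = self.forest_pool_size
        s_other = self.pool_size - s_forest
        for lu, m in self.mean_richness.items():
            if m < 0:
                raise ConfigurationError(f"{self.name}: negative richness mean")
            ov = 1.0 if lu == "F" else self.forest_overlap
            if m * ov > s_forest or m * (1.0 - ov) > s_other:
                raise ConfigurationError(
                    f"{self.name}: mean richness {m} for {lu} exceeds the "
                    f"species pool (forest pool {s_forest}, other {s_other})"
                )


@dataclass(frozen=True)
class IndicatorSpec:
    """One ecosystem-function indicator: land-use means plus Gaussian noise."""

    name: str
    function_group: str
    direction: str
    means: Mapping[str, float]
    sd: float

    def validate(self) -> None:
        if self.direction not in (HIGHER_BETTER, LOWER_BETTER):
            raise ConfigurationError(
                f"{self.name}: direction must be {HIGHER_BETTER!r} or "
                f"{LOWER_BETTER!r}, got {self.direction!r}"
            )
        if self.sd < 0:
            raise ConfigurationError(f"{self.name}: sd must be >= 0")
        missing = set(LAND_USE_SYSTEMS) - set(self.means)
        if missing:
            raise ConfigurationError(
                f"{self.name}: means missing land uses {sorted(missing)}"
            )


@dataclass(frozen=True)
class YieldSpec:
    """Gaussian plot-yield model (kg ha^-1 yr^-1), truncated at zero."""

    mean: float
    sd: float

    def validate(self, crop: str) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ConfigurationError(f"yield spec for {crop}: mean/sd must be >= 0")


@dataclass(frozen=True)
class HouseholdSpec:
    """Linear yield-profit relation with sd(profit | yield) = gamma * yield."""

    n: int
    intercept: float
    slope: float
    gamma: float

    def validate(self, crop: str) -> None:
        if self.n < 1:
            raise ConfigurationError(f"household spec for {crop}: n must be >= 1")
        if self.gamma < 0:
            raise ConfigurationError(
                f"household spec for {crop}: gamma must be >= 0"
            )


def _default_taxa() -> tuple[TaxonSpec, ...]:
    def t(name, pool, f, j, r, o, ov, miss=0):
        return TaxonSpec(name, pool, {"F": f, "J": j, "R": r, "O": o}, ov, miss)

    # Richness means decline from forest/jungle rubber to monocultures for
    # most groups; soil prokaryotes are flat-to-increasing, mirroring the
    # one group whose total richness did not trade off against profit.
    return (
        t("trees", 150, 55, 35, 12, 6, 0.50),
        t("understorey_plants", 200, 60, 50, 30, 20, 0.45),
        t("canopy_ants", 120, 40, 32, 18, 12, 0.50),
        t("parasitoid_wasps", 300, 80, 60, 35, 25, 0.40),
        t("birds", 140, 45, 35, 18, 10, 0.50, 1),
        t("bats", 40, 12, 10, 5, 3, 0.60),
        t("butterflies", 110, 35, 30, 18, 12, 0.50),
        t("litter_invertebrates", 180, 50, 40, 22, 15, 0.45),
        t("testate_amoebae", 90, 30, 26, 18, 14, 0.50, 1),
        t("oribatid_mites", 100, 32, 26, 16, 11, 0.50),
        t("mesostigmata", 70, 22, 18, 10, 7, 0.50),
        t("soil_fungi", 250, 70, 60, 45, 40, 0.45, 2),
        t("soil_bacteria", 260, 70, 72, 74, 78, 0.55),
        t("soil_archaea", 60, 18, 17, 16, 17, 0.60, 2),
    )


def _default_indicators() -> tuple[IndicatorSpec, ...]:
    def ind(name, group, direction, f, j, r, o, sd):
        return IndicatorSpec(name, group, direction,
                             {"F": f, "J": j, "R": r, "O": o}, sd)

    H, L = HIGHER_BETTER, LOWER_BETTER
    return (
        # net primary production (Mg C ha-1 yr-1 scale)
        ind("litterfall_production", "net_primary_production", H, 9, 7, 6, 8, 1.0),
        ind("stem_increment", "net_primary_production", H, 4, 3, 3.5, 5, 0.8),
        ind("fine_root_production", "net_primary_production", H, 3, 2.5, 2, 2.2, 0.5),
        ind("harvest_export", "net_primary_production", H, 0, 1.5, 2.5, 6, 0.8),
        # organic carbon in plant biomass (Mg C ha-1)
        ind("aboveground_carbon", "biomass_carbon", H, 160, 90, 45, 35, 15),
        ind("coarse_root_carbon", "biomass_carbon", H, 35, 20, 10, 8, 4),
        ind("fine_root_carbon", "biomass_carbon", H, 4, 3, 2, 2, 0.5),
        # soil organic carbon (Mg C ha-1)
        ind("soc_0_50cm", "soil_carbon", H, 70, 60, 50, 45, 6),
        ind("soc_50_200cm", "soil_carbon", H, 45, 42, 38, 35, 5),
        ind("litter_layer_carbon", "soil_carbon", H, 8, 6, 4, 2, 1),
        # soil fertility (topsoil; improves under oil palm via amendments)
        ind("net_n_mineralization", "soil_fertility", H, 8, 7, 6, 9, 1.5),
        ind("extractable_p", "soil_fertility", H, 5, 5, 6, 12, 2),
        ind("exchangeable_ca", "soil_fertility", H, 2.0, 1.8, 1.6, 4.0, 0.6),
        ind("exchangeable_k", "soil_fertility", H, 0.30, 0.28, 0.25, 0.50, 0.08),
        ind("exchangeable_mg", "soil_fertility", H, 0.8, 0.7, 0.6, 1.2, 0.2),
        ind("base_saturation", "soil_fertility", H, 30, 28, 25, 45, 6),
        # soil respiration (Mg C ha-1 yr-1)
        ind("soil_co2_efflux", "soil_respiration", H, 5.2, 4.8, 4.2, 3.6, 0.5),
        # soil greenhouse-gas fluxes (undesirable)
        ind("n2o_flux", "greenhouse_gas_flux", L, 0.5, 0.7, 0.9, 1.6, 0.2),
        ind("ch4_flux", "greenhouse_gas_flux", L, 0.2, 0.3, 0.5, 0.9, 0.15),
        # nutrient-leaching fluxes at 1.5 m depth (undesirable)
        ind("leaching_tdn", "nutrient_leaching", L, 2.0, 3.0, 5.0, 9.0, 1.0),
        ind("leaching_no3", "nutrient_leaching", L, 1.0, 1.8, 3.5, 7.0, 0.9),
        ind("leaching_nh4", "nutrient_leaching", L, 0.4, 0.5, 0.8, 1.2, 0.2),
        ind("leaching_doc", "nutrient_leaching", L, 8, 10, 13, 18, 2.5),
        ind("leaching_ca", "nutrient_leaching", L, 3, 4, 6, 11, 1.5),
        ind("leaching_mg", "nutrient_leaching", L, 1.5, 2.0, 3.0, 5.0, 0.8),
        ind("leaching_na", "nutrient_leaching", L, 2.0, 2.5, 3.5, 5.5, 0.8),
        ind("leaching_p", "nutrient_leaching", L, 0.1, 0.15, 0.25, 0.5, 0.08),
        # decomposition (% litter mass loss in 6 months)
        ind("litter_mass_loss", "decomposition", H, 60, 55, 40, 35, 5),
        # plant transpiration (mm d-1; hump/U-shaped across systems)
        ind("stand_transpiration", "transpiration", H, 2.4, 2.0, 1.3, 2.2, 0.3),
        # below-canopy microclimate (buffered conditions are desirable)
        ind("air_temperature_mean", "microclimate", L, 25.0, 26.0, 27.5, 28.5, 0.5),
        ind("air_humidity_mean", "microclimate", H, 92, 88, 82, 78, 3),
        ind("air_humidity_min", "microclimate", H, 70, 62, 55, 50, 4),
        ind("soil_temperature_mean", "microclimate", L, 25.0, 25.8, 26.8, 27.5, 0.5),
        ind("soil_moisture_mean", "microclimate", H, 0.35, 0.32, 0.28, 0.25, 0.04),
        ind("diurnal_temperature_range", "microclimate", L, 4, 6, 9, 10, 1),
        ind("vpd_max", "microclimate", L, 0.8, 1.2, 1.8, 2.2, 0.3),
    )


def _default_yields() -> dict[str, YieldSpec]:
    # J/R: dry rubber; O: fresh fruit bunches (kg ha-1 yr-1)
    return {
        "J": YieldSpec(600.0, 150.0),
        "R": YieldSpec(1300.0, 300.0),
        "O": YieldSpec(16000.0, 3000.0),
    }


def _default_households() -> dict[str, HouseholdSpec]:
    # 701 surveyed households; per-crop linear yield-profit relations
    # (USD ha-1 yr-1) with residual sd proportional to yield.
    return {
        "J": HouseholdSpec(101, 0.0, 0.30, 0.10),
        "R": HouseholdSpec(300, -30.0, 0.45, 0.15),
        "O": HouseholdSpec(300, 50.0, 0.06, 0.02),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Full configuration of the synthetic study-design generator."""

    n_landscapes: int = 2
    n_replicates_per_system: int = 4
    land_use_systems: tuple[str, ...] = LAND_USE_SYSTEMS
    taxa: tuple[TaxonSpec, ...] = field(default_factory=_default_taxa)
    indicators: tuple[IndicatorSpec, ...] = field(default_factory=_default_indicators)
    yields: Mapping[str, YieldSpec] = field(default_factory=_default_yields)
    households: Mapping[str, HouseholdSpec] = field(default_factory=_default_households)
    seed: int = 0

    @property
    def n_plots(self) -> int:
        return (self.n_landscapes * len(self.land_use_systems)
                * self.n_replicates_per_system)

    def validate(self) -> None:
        if self.n_landscapes < 1 or self.n_replicates_per_system < 1:
            raise ConfigurationError("counts must be >= 1")
        if tuple(self.land_use_systems) != LAND_USE_SYSTEMS:
            raise ConfigurationError(
                f"land_use_systems must be exactly {LAND_USE_SYSTEMS}"
            )
        names = [t.name for t in self.taxa]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate taxon group names")
        for t in self.taxa:
            t.validate()
            if t.n_missing_plots >= self.n_plots:
                raise ConfigurationError(
                    f"{t.name}: n_missing_plots >= number of plots"
                )
        ind_names = [i.name for i in self.indicators]
        if len(ind_names) != len(set(ind_names)):
            raise ConfigurationError("duplicate indicator names")
        for i in self.indicators:
            i.validate()
        for crop in CROPS:
            if crop not in self.yields:
                raise ConfigurationError(f"missing yield spec for crop {crop}")
            self.yields[crop].validate(crop)
            if crop not in self.households:
                raise ConfigurationError(f"missing household spec for crop {crop}")
            self.households[crop].validate(crop)

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class SimexConfig:
    """Settings of the simulation-extrapolation correction.

    The default grid of measurement-error inflation factors is 10
    equidistant values of lambda between 0.1 and 3, with B = 200 simulation
    replicates per lambda and a quadratic extrapolant evaluated at
    lambda = -1.
    """

    lambda_grid: tuple[float, ...] = tuple(np.linspace(0.1, 3.0, 10))
    B: int = 200
    extrapolant_degree: int = 2
    eval_grid: tuple[float, ...] | None = None
    n_eval: int = 40
    seed: int = 0

    def validate(self) -> None:
        lam = np.asarray(self.lambda_grid, dtype=float)
        if lam.size < 2 or np.any(lam <= 0) or np.any(np.diff(lam) <= 0):
            raise ConfigurationError(
                "lambda_grid must be >= 2 strictly increasing positive values"
            )
        if self.B < 2:
            raise ConfigurationError("B must be >= 2")
        if self.extrapolant_degree not in (1, 2):
            raise ConfigurationError("extrapolant_degree must be 1 or 2")
        if self.eval_grid is not None:
            g = np.asarray(self.eval_grid, dtype=float)
            if g.size < 2 or np.any(np.diff(g) <= 0):
                raise ConfigurationError("eval_grid must be strictly increasing")
        elif self.n_eval < 2:
            raise ConfigurationError("n_eval must be >= 2")


@dataclass(frozen=True)
class ThresholdConfig:
    """Threshold sweep for multidiversity / multifunctionality.

    Thresholds are fractions of each group's or indicator's maximum
    performance level; the level itself is the mean of the ``top_k``
    highest plot values (top five by default, damping outliers).
    """

    thresholds: tuple[float, ...] = tuple(np.arange(1, 100) / 100.0)
    top_k: int = 5

    def validate(self) -> None:
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.size == 0:
            raise ConfigurationError("thresholds must be non-empty")
        if np.any(thr < 0.01 - 1e-12) or np.any(thr > 0.99 + 1e-12):
            raise ConfigurationError("thresholds must lie in [0.01, 0.99]")
        if np.any(np.diff(thr) <= 0):
            raise ConfigurationError("thresholds must be strictly increasing")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")


@dataclass(frozen=True)
class GAConfig:
    """Binary genetic algorithm settings (500 chromosomes, 100 generations)."""

    population_size: int = 500
    generations: int = 100
    landscape_size: int | None = None  # None: one slot per available plot
    mutation_rate: float | None = None  # None: 1 / (chromosome length + 1)
    elitism_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if self.landscape_size is not None and self.landscape_size < 1:
            raise ConfigurationError("landscape_size must be >= 1")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ConfigurationError("mutation_rate must lie in [0, 1]")
        if not 0 <= self.elitism_fraction < 1:
            raise ConfigurationError("elitism_fraction must lie in [0, 1)")


# ---------------------------------------------------------------------------
# YAML round-trip


def synth_config_from_dict(d: Mapping) -> SynthConfig:
    """Build a :class:`SynthConfig` from a plain (YAML-loaded) mapping.

    Omitted sections fall back to the defaults, so a config file only needs
    to name the pieces it changes.
    """
    kwargs: dict = {}
    for key in ("n_landscapes", "n_replicates_per_system", "seed"):
        if key in d:
            kwargs[key] = int(d[key])
    if "land_use_systems" in d:
        kwargs["land_use_systems"] = tuple(d["land_use_systems"])
    if "taxa" in d:
        kwargs["taxa"] = tuple(
            TaxonSpec(
                name=t["name"],
                pool_size=int(t["pool_size"]),
                mean_richness=dict(t["mean_richness"]),
                forest_overlap=float(t["forest_overlap"]),
                n_missing_plots=int(t.get("n_missing_plots", 0)),
            )
            for t in d["taxa"]
        )
    if "indicators" in d:
        kwargs["indicators"] = tuple(
            IndicatorSpec(
                name=i["name"],
                function_group=i["function_group"],
                direction=i["direction"],
                means=dict(i["means"]),
                sd=float(i["sd"]),
            )
            for i in d["indicators"]
        )
    if "yields" in d:
        kwargs["yields"] = {
            c: YieldSpec(float(v["mean"]), float(v["sd"]))
            for c, v in d["yields"].items()
        }
    if "households" in d:
        kwargs["households"] = {
            c: HouseholdSpec(int(v["n"]), float(v["intercept"]),
                             float(v["slope"]), float(v["gamma"]))
            for c, v in d["households"].items()
        }
    cfg = SynthConfig(**kwargs)
    cfg.validate()
    return cfg


def load_synth_config(path) -> SynthConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return synth_config_from_dict(data)
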