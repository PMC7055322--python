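"""Simulation-extrapolation (SIMEX) correction for smooth profit-response
curves with heteroscedastic measurement error in the profit axis.

For each inflation factor lambda in a grid, additional Gaussian noise with
per-plot variance lambda * sigma_e_i^2 is added to the estimated profits;
the penalized-spline smooth is refitted B times and the fitted curves are
averaged, giving the bias path G(lambda) at each evaluation point.  A
polynomial (quadratic by default) in lambda is then fitted through
{(0, naive)} and the simulated points and extrapolated to lambda = -1,
the zero-measurement-error limit — the SIMEX-corrected curve.

The extrapolation acts on fitted values over a fixed evaluation grid
(pointwise, on the response scale), with the spline basis, penalty weight
and negative-binomial dispersion all frozen at their naive-fit values so
that smoothing-level jitter cannot contaminate the extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SimexConfig
from .dataset import Dataset
from .errors import DomainError
from .pspline import (GAUSSIAN, NEGATIVE_BINOMIAL, GamFit, SplineBasis,
                      fit_penalized_gam)
from .rng import substream

__all__ = ["SimexFit", "simex_correct", "response_profit_curves"]


@dataclass
class SimexFit:
    """Naive and SIMEX-corrected curves of one response against profit."""

    response: str
    family: str
    eval_grid: np.ndarray
    lambdas: np.ndarray  # includes 0 first; G(0) is the naive curve
    curves: np.ndarray  # len(lambdas) x len(eval_grid) mean curves G(lambda)
    curve_vars: np.ndarray  # variance of each mean curve, same shape
    corrected: np.ndarray  # extrapolated curve at lambda = -1
    band_lo: np.ndarray
    band_hi: np.ndarray
    extrapolant_degree: int
    B: int
    seed: int

    @property
    def naive(self) -> np.ndarray:
        return self.curves[0]

    def endpoint_slope(self, corrected: bool = True) -> float:
        """Secant slope of the curve between the grid endpoints."""
        c = self.corrected if corrected else self.naive
        return float((c[-1] - c[0]) / (self.eval_grid[-1] - self.eval_grid[0]))

    def fitted_slope(self, corrected: bool = True) -> float:
        """OLS slope of the curve values against the evaluation grid."""
        c = self.corrected if corrected else self.naive
        return float(np.polyfit(self.eval_grid, c, 1)[0])

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "family": self.family,
            "lambda_grid": [float(v) for v in self.lambdas[1:]],
            "B": self.B,
            "eval_grid": self.eval_grid.tolist(),
            "naive_curve": self.naive.tolist(),
            "corrected_curve": self.corrected.tolist(),
            "band_lo": self.band_lo.tolist(),
            "band_hi": self.band_hi.tolist(),
            "seed": self.seed,
        }


def _extrapolation_weights(lambdas: np.ndarray, degree: int) -> np.ndarray:
    """Linear weights w with prediction(-1) = w @ G(lambdas)."""
    A = np.vander(lambdas, degree + 1, increasing=True)
    a_minus1 = np.power(-1.0, np.arange(degree + 1))
    return a_minus1 @ np.linalg.pinv(A)


def simex_correct(
    x,
    y,
    me_variances,
    family: str = GAUSSIAN,
    config: SimexConfig | None = None,
    response: str = "response",
    rng: np.random.Generator | None = None,
) -> SimexFit:
    """SIMEX-corrected smooth of ``y`` on the error-prone covariate ``x``.

    ``me_variances`` holds the per-observation measurement-error variance
    sigma_e_i^2 of ``x``.  With all variances zero the corrected curve
    equals the naive curve exactly.
    """
    config = config or SimexConfig()
    config.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    me = np.asarray(me_variances, dtype=float)
    if me.shape != x.shape:
        raise DomainError("me_variances must align with x")
    if np.any(me < 0):
        raise DomainError("measurement-error variances must be >= 0")

    lam_grid = np.asarray(config.lambda_grid, dtype=float)
    # boundary margin so perturbed profits stay inside the knot span
    margin = 3.0 * np.sqrt((1.0 + lam_grid[-1]) * me.max()) if me.max() > 0 else 0.0
    basis = SplineBasis.from_x(x, margin=margin)
    naive: GamFit = fit_penalized_gam(x, y, family=family, basis=basis)

    if config.eval_grid is not None:
        grid = np.asarray(config.eval_grid, dtype=float)
    else:
        grid = np.linspace(x.min(), x.max(), config.n_eval)
    naive_curve, naive_se = naive.curve(grid)

    rng = rng if rng is not None else substream(config.seed, f"simex:{response}")
    sd = np.sqrt(me)
    curves = [naive_curve]
    curve_vars = [naive_se**2]
    for lam in lam_grid:
        reps = np.empty((config.B, len(grid)))
        for b in range(config.B):
            x_star = x + np.sqrt(lam) * sd * rng.standard_normal(len(x))
            fit = fit_penalized_gam(
                x_star, y, family=family, basis=basis,
                penalty_weight=naive.penalty_weight, alpha=naive.alpha,
            )
            reps[b] = fit.predict(grid)
        curves.append(reps.mean(axis=0))
        curve_vars.append(reps.var(axis=0, ddof=1) / config.B)

    lambdas = np.concatenate([[0.0], lam_grid])
    curves = np.asarray(curves)
    curve_vars = np.asarray(curve_vars)
    w = _extrapolation_weights(lambdas, config.extrapolant_degree)
    corrected = w @ curves
    var_corr = (w**2) @ curve_vars
    half = 1.96 * np.sqrt(np.maximum(var_corr, 0.0))
    return SimexFit(
        response=response, family=family, eval_grid=grid, lambdas=lambdas,
        curves=curves, curve_vars=curve_vars, corrected=corrected,
        band_lo=corrected - half, band_hi=corrected + half,
        extrapolant_degree=config.extrapolant_degree, B=config.B,
        seed=config.seed,
    )


def response_profit_curves(
    dataset: Dataset,
    plot_profits: pd.DataFrame,
    targets: list[str] | None = None,
    config: SimexConfig | None = None,
) -> Mapping[str, SimexFit]:
    """SIMEX curves for every per-plot response against estimated profit.

    Responses are named ``richness_all:<group>`` and
    ``richness_forest:<group>`` (negative-binomial family) for each
    taxonomic group, and ``indicator:<name>`` (Gaussian) for each
    ecosystem-function indicator.  ``targets`` restricts the set.
    """
    config = config or SimexConfig()
    responses: dict[str, tuple[pd.Series, str]] = {}
    rich_all = dataset.richness(forest_only=False)
    rich_forest = dataset.richness(forest_only=True)
    for group in dataset.taxon_groups:
        responses[f"richness_all:{group}"] = (rich_all[group], NEGATIVE_BINOMIAL)
        responses[f"richness_forest:{group}"] = (
            rich_forest[group], NEGATIVE_BINOMIAL)
    for ind in dataset.functions.columns:
        responses[f"indicator:{ind}"] = (dataset.functions[ind], GAUSSIAN)

    if targets is not None:
        unknown = set(targets) - set(responses)
        if unknown:
            raise LookupError(f"unknown responses: {sorted(unknown)}")
        responses = {t: responses[t] for t in targets}

    out: dict[str, SimexFit] = {}
    for name, (series, family) in responses.items():
        series = series.dropna()
        prof = plot_profits.loc[series.index]
        out[name] = simex_correct(
            prof["profit_mean"].to_numpy(),
            series.to_numpy(),
            prof["me_variance"].to_numpy(),
            family=family,
            config=config,
            response=name,
        )
    return out
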