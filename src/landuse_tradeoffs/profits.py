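"""Plot-level profit estimation from household yield-profit relations.

Two steps: (1) per crop, an ordinary least-squares regression of household
profit on yield, plus an estimate of the heteroscedastic residual spread
sd(e | yield) = g * yield; (2) prediction of each ecological plot's profit
mean and measurement-error variance from its measured yield.  Forest plots
carry profit 0 with zero error variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, InsufficientDataError

__all__ = ["YieldProfitFit", "fit_yield_profit", "fit_all_crops",
           "predict_plot_profits"]


@dataclass(frozen=True)
class YieldProfitFit:
    """Per-crop linear yield-profit fit with multiplicative error spread."""

    crop: str
    intercept: float  # USD ha-1 yr-1
    slope: float  # USD per kg
    gamma: float  # sd(profit | yield) = gamma * yield
    n_used: int
    r_squared: float

    def predict(self, yields) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(yields, dtype=float)

    def variance_fn(self, yields) -> np.ndarray:
        """Measurement-error variance at a given yield: (gamma * yield)^2."""
        y = np.asarray(yields, dtype=float)
        return (self.gamma * y) ** 2


def fit_yield_profit(households: pd.DataFrame, crop: str) -> YieldProfitFit:
    """OLS of profit on yield for one crop, with residual-spread estimate.

    The spread coefficient g is estimated by regressing |residual| through
    the origin on yield and rescaling by sqrt(pi/2), which is unbiased for
    g under Gaussian residuals with sd = g * yield and more robust to heavy
    tails than a squared-residual regression.
    """
    sub = households.loc[households["crop"] == crop]
    y = pd.to_numeric(sub["yield_kg_ha_yr"], errors="coerce")
    p = pd.to_numeric(sub["profit_usd_ha_yr"], errors="coerce")
    ok = np.isfinite(y) & np.isfinite(p)
    y, p = y[ok].to_numpy(), p[ok].to_numpy()
    if len(y) < 3:
        raise InsufficientDataError(
            f"crop {crop}: need >= 3 households, got {len(y)}"
        )
    if np.ptp(y) == 0:
        raise DegenerateDesignError(f"crop {crop}: zero yield variance")

    slope, intercept = np.polyfit(y, p, 1)
    resid = p - (intercept + slope * y)
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    denom = float(np.sum(y**2))
    if denom == 0:
        raise DegenerateDesignError(f"crop {crop}: all yields zero")
    gamma = float(np.sqrt(np.pi / 2) * np.sum(np.abs(resid) * y) / denom)
    return YieldProfitFit(crop, float(intercept), float(slope), gamma,
                          int(len(y)), float(r2))


def fit_all_crops(households: pd.DataFrame) -> dict[str, YieldProfitFit]:
    return {c: fit_yield_profit(households, c)
            for c in sorted(households["crop"].unique())}


def predict_plot_profits(
    plots: pd.DataFrame, fits: dict[str, YieldProfitFit]
) -> pd.DataFrame:
    """Per-plot profit mean and measurement-error variance.

    Forest plots get (0, 0); other plots use their land-use system's crop
    fit.  Raises :class:`LookupError` when a plot's crop has no fit.
    """
    means, variances = [], []
    for pid, row in plots.iterrows():
        lu = row["land_use"]
        if lu == "F":
            means.append(0.0)
            variances.append(0.0)
            continue
        if lu not in fits:
            raise LookupError(f"plot {pid!r}: no yield-profit fit for crop {lu!r}")
        fit = fits[lu]
        y = float(row["yield_kg_ha_yr"])
        means.append(float(fit.predict(y)))
        variances.append(float(fit.variance_fn(y)))
    return pd.DataFrame(
        {"profit_mean": means, "me_variance": variances}, index=plots.index.copy()
    )


def write_fits(fits: dict[str, YieldProfitFit], path) -> None:
    payload = {
        c: {"intercept": f.intercept, "slope": f.slope, "gamma": f.gamma,
            "n_used": f.n_used, "r_squared": f.r_squared}
        for c, f in fits.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))
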