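# landuse-tradeoffs

Economic–ecological trade-off analysis for tropical smallholder
landscapes.

Smallholder land-use transitions — from lowland rainforest and
jungle-rubber agroforestry to rubber and oil-palm monocultures — raise
farm profits while eroding biodiversity and ecosystem functioning.  This
package implements, as a tested and reusable pipeline, the statistical
chain needed to quantify those trade-offs at the plot and landscape scale
for a 32-plot study design (4 land-use systems × 2 landscape blocks × 4
replicates), and ships a seeded synthetic-data generator that emulates
the design so every stage is testable end to end without any field data.

It is aimed at quantitative ecologists and ecological economists working
with plot-level biodiversity/function panels linked to household survey
economics.

## What it computes

1. **Plot profits with measurement error** (`profits`).  Per crop *c*, a
   household-survey regression `profit = a_c + b_c·yield + e` with
   heteroscedastic residuals `sd(e | yield) = g_c·yield`; plot-level profit
   means `μ_i = a_c + b_c·yield_i` and measurement-error variances
   `σ²_e,i = (g_c·yield_i)²`.  Forest plots are fixed at (0, 0).
2. **SIMEX-corrected smooths** (`simex`).  Responses (species richness per
   taxonomic group, negative binomial; function indicators, Gaussian) are
   regressed on profit with penalized cubic splines.  Because profit is
   error-prone, naive smooths are attenuated; simulation–extrapolation
   refits the smooth B = 200 times per inflation factor λ (10 equidistant
   values in [0.1, 3]) with extra noise of variance `λ·σ²_e,i`, models the
   bias path `G(λ)` pointwise, and extrapolates a quadratic to λ = −1 — the
   zero-error limit.
3. **Multidiversity / multifunctionality** (`indices`).  Per plot, the
   proportion of taxonomic groups (or function-weighted indicators, each
   of 10 functions weighted equally) reaching a threshold fraction of the
   maximum performance level (mean of the top five plot values), swept
   over thresholds 1–99%, then regressed on profit (slope per
   100 USD ha⁻¹ yr⁻¹).
4. **Landscape optimization** (`optimize`).  A conceptual landscape of 32
   slots filled *with replacement* from the study plots
   (C(63, 32) ≈ 9.16 × 10¹⁷ compositions) is optimized by a binary genetic
   algorithm (1024-gene chromosomes, 500 individuals, 100 generations)
   for richness, function level, multidiversity or multifunctionality,
   subject to a minimum mean-profit expectation
   ({0, 200, …, 1000} USD ha⁻¹ yr⁻¹), tracing the production-possibility
   (Pareto) frontier.  An exhaustive enumerator provides the exact optimum
   on small instances.

## Worked example

```python
from landuse_tradeoffs import (GAConfig, ObjectiveSpec, generate_dataset,
                               pareto_frontier)
from landuse_tradeoffs.indices import index_profit_slope, threshold_sweep
from landuse_tradeoffs.profits import fit_all_crops, predict_plot_profits

ds = generate_dataset(seed=1)                       # 32 plots, 701 households
fits = fit_all_crops(ds.households)
for crop, f in fits.items():
    print(f"{crop}: profit = {f.intercept:.1f} + {f.slope:.3f} * yield, "
          f"sd = {f.gamma:.3f} * yield  (n={f.n_used}, R^2={f.r_squared:.2f})")
ds.plot_profits = predict_plot_profits(ds.plots, fits)

row = index_profit_slope(threshold_sweep(ds, "multidiversity"),
                         ds.plot_profits).loc[0.5]
print(f"multidiversity slope at 50% threshold: "
      f"{row['slope_per_100usd']:.3f} per 100 USD "
      f"[{row['lo']:.3f}, {row['hi']:.3f}]")

frontier = pareto_frontier(ObjectiveSpec("multidiversity"), dataset=ds,
                           config=GAConfig(seed=1))
for e, sol in frontier.solutions.items():
    print(f"expectation {e:6.0f}: multidiversity {sol.realized:.3f}, "
          f"profit {sol.mean_profit:7.1f}, forest share {sol.shares['F']:.2f}")
```

prints (seed 1):

```
J: profit = 30.2 + 0.252 * yield, sd = 0.096 * yield  (n=101, R^2=0.27)
O: profit = 128.1 + 0.054 * yield, sd = 0.021 * yield  (n=300, R^2=0.18)
R: profit = -58.6 + 0.493 * yield, sd = 0.154 * yield  (n=300, R^2=0.33)
multidiversity slope at 50% threshold: -0.084 per 100 USD [-0.097, -0.070]
expectation      0: multidiversity 1.000, profit    35.8, forest share 0.81
expectation    200: multidiversity 0.978, profit   210.6, forest share 0.09
expectation    400: multidiversity 0.866, profit   406.6, forest share 0.09
expectation    600: multidiversity 0.754, profit   602.4, forest share 0.09
expectation    800: multidiversity 0.643, profit   802.2, forest share 0.06
expectation   1000: multidiversity 0.529, profit  1000.7, forest share 0.03
```

Reading: raising the profit expectation from 0 to 1000 USD ha⁻¹ yr⁻¹
forces rainforest out of the optimal landscape and multidiversity (at the
50% threshold) falls from 1.00 to 0.53; each additional 100 USD of plot
profit costs about 0.08 multidiversity units — a monotone
biodiversity–profit trade-off.

## Command line

```sh
tradeoffs simulate --seed 1 --out run/
tradeoffs profits  --data run/dataset --out run/
tradeoffs simex    --data run/dataset -B 200 --out run/
tradeoffs indices  --data run/dataset --thresholds 1:99:1 --out run/
tradeoffs optimize --data run/dataset --objective multidiversity --out run/
tradeoffs all      --seed 1 --out run/
```

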