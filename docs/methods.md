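# Methods

This note documents the statistical models, defaults, and numerical
choices behind each pipeline stage, and what the synthetic-data generator
does and does not emulate.

## Study design emulated by the generator

The generator reproduces the structure of a paired-landscape plot study
of tropical smallholder land use: two landscape blocks, each with four
replicate 50 m × 50 m plots in four land-use systems — primary degraded
lowland rainforest (F), jungle-rubber agroforestry (J), rubber
monoculture (R), and oil-palm monoculture (O) — giving 32 plots, plus a
701-household farm survey used to price crop yields.  All randomness
flows from one root seed through named substreams (`rng.substream`), one
per generator, so adding a generator never changes another's draws and
every table is bit-reproducible.

**Plots and yields.**  Crop yields (kg ha⁻¹ yr⁻¹; dry rubber for J/R,
fresh fruit bunches for O) are Gaussian draws truncated at zero —
truncation rather than resampling preserves a fixed draw count and hence
seeded determinism.  Defaults: J 600 ± 150, R 1300 ± 300, O 16000 ± 3000.
Forest plots have no crop; yield and profit are identically zero.

**Species incidence.**  Each of the 14 taxonomic groups (trees,
understorey plants, canopy ants, parasitoid wasps, birds, bats,
butterflies, litter invertebrates, testate amoebae, oribatid mites,
mesostigmata, soil fungi, bacteria, archaea) has a species pool split
into a *forest pool* (half the pool, rounded up) and a disjoint pool of
generalists/exotics.  A plot includes each species independently with a
pool-specific probability chosen so the expected richness equals the
configured land-use mean (Poisson-binomial richness; no distributional
family is claimed beyond this construction).  Forest plots draw only from
the forest pool; other plots draw a configurable *forest-overlap*
fraction of their expected richness from it, producing partial turnover:
monocultures keep some community but lose forest species.  Default means
decline F ≥ J > R > O for all groups except soil bacteria
(flat-to-increasing), matching the qualitative pattern that prokaryote
richness need not trade off against profit.  Species never observed are
dropped, so every surviving column has ≥ 1 presence.  Sampling gaps are
part of the default design: soil fungi and archaea are missing on two
plots, birds and testate amoebae on one, drawn among non-forest plots.

**Function indicators.**  36 indicators in 10 function groups (net
primary production, biomass carbon, soil carbon, soil fertility, soil
respiration, greenhouse-gas fluxes, nutrient leaching, decomposition,
transpiration, microclimate); each value is its land-use mean plus
Gaussian noise.  Directions are declared per indicator
(`higher_better`/`lower_better`); leaching and greenhouse-gas fluxes
increase toward monocultures and are flagged undesirable, soil fertility
improves under oil palm (fertilized), transpiration is non-monotone.

**Households.**  Per crop: `profit = a_c + b_c·yield + e` with
`sd(e) = γ_c·yield` — the simplest heteroscedasticity form consistent
with spread growing in yield and vanishing at zero yield.  Defaults
(USD ha⁻¹ yr⁻¹): J (n=101, a=0, b=0.30, γ=0.10), R (n=300, a=−30,
b=0.45, γ=0.15), O (n=300, a=50, b=0.06, γ=0.02), i.e. 701 households
and land-use profit means near 0 / 180 / 550 / 1000 USD ha⁻¹ yr⁻¹ for
F/J/R/O — the observed profitability ordering and range.

**What the generator does not emulate:** spatial autocorrelation and
block effects, species abundance (incidence only), non-Gaussian indicator
noise, covariance between taxa or functions beyond their shared land-use
means, survey economics (input costs, prices, labor valuation).  Passing
tests therefore demonstrate correctness of the *methods* under the
assumed generating process, not field-data effect sizes.

## Profit estimation

OLS per crop (≥ 3 households, non-degenerate yields).  The spread
coefficient g of `sd(residual | yield) = g·yield` is estimated by
regressing |residual| through the origin on yield and rescaling by
√(π/2) (unbiased under Gaussian residuals, more robust to heavy tails
than squared-residual regression at a few hundred households per crop).
Plot predictions: `μ_i = a_c + b_c·yield_i`,
`σ²_e,i = (ĝ·yield_i)²`; forest plots are set to (0, 0), which the
variance form honors automatically since it vanishes at yield 0.
Currency is USD; the configured conversion constant (13389.413 IDR/USD,
2015 average) is metadata only.

## Penalized-spline smoothers

Cubic B-splines with 5 interior knots at covariate quantiles; penalty is
the integrated squared second derivative ∫f″(x)²dx (computed exactly by
3-point Gauss–Legendre per knot interval and normalized to unit mean
diagonal so penalty-weight grids are scale-free).  Its null space is
exactly the linear functions, so infinite smoothing recovers the
(weighted) least-squares line regardless of knot placement.  The penalty
weight is selected once, on the naive fit, by GCV over a 25-point
log-spaced grid.  Families: Gaussian (identity link) and negative
binomial (log link) for counts; the NB dispersion α (var = μ + αμ²) is a
moment estimate from a pilot Poisson fit and then held fixed.
Coefficient covariance uses the sandwich form
(X′WX + aP)⁻¹X′WX(X′WX + aP)⁻¹.  Evaluation clips covariates to the knot
span; degenerate designs and n < 8 raise explicit errors.

## SIMEX correction

For each λ in the grid (default: 10 equidistant values from 0.1 to 3),
B = 200 replicates add independent noise N(0, λσ²_e,i) to the estimated
profits and refit the smooth; per-λ mean fitted curves on a fixed
evaluation grid (40 points spanning the observed profits) form the bias
path G(λ), anchored at λ = 0 by the naive curve exactly.  A quadratic in
λ (degree configurable to 1) is fitted pointwise by least squares and
evaluated at λ = −1 — the corrected curve.  Stability choices: spline
knots (with a boundary margin of 3·√((1+λmax)·max σ²ₑ) so perturbed
profits stay in-span), penalty weight and NB dispersion are all frozen at
their naive-fit values across every replicate, preventing
smoothing-level jitter from contaminating the extrapolation.  The 95%
band is a delta-method propagation of the Monte-Carlo variances of the
per-λ mean curves (naive sandwich variance at λ = 0) through the linear
extrapolation weights; this band construction is an implementation
choice of this package, as is extrapolating fitted values rather than
spline coefficients (coefficient-space extrapolation is
basis-dependent; displayed results are curves).  With all σ²ₑ = 0 the
corrected curve equals the naive curve identically.  On the
linear-Gaussian special case the naive slope attenuates by
σ²ₓ/(σ²ₓ+σ²ₑ), which serves as a closed-form oracle in the tests.

`response_profit_curves` fits 14 taxa × 2 richness measures (all
species; species also present in rainforest) as negative binomial plus
36 indicators as Gaussian — 64 curves.

## Multidiversity and multifunctionality

The 100% reference level per group/indicator is the mean of the top five
plot values (outlier damping; fewer than five uses all).  Lower-is-better
indicators are direction-corrected *before* levels are computed, by range
reflection x′ = max + min − x: an order-reversing, range-preserving
involution chosen over the reciprocal 1/x, which is undefined at zero
(fluxes can be 0) — only order reversal matters before thresholding.
Multidiversity at threshold t is the share of measured groups with
richness ≥ t·level (attainment at exactly the threshold counts); groups
unsampled on a plot leave both numerator and denominator.
Multifunctionality weights each indicator by 1/(indicators in its
function), so each of the 10 functions contributes equally (an
8-indicator function weights each at 12.5%), normalized by the number of
functions.  The default sweep is 99 thresholds at one-percentage-point
steps over 1–99% (step configurable; an arbitrarily fine sweep is
supported but adds no information at 32 plots).  Index–profit relations
use simple OLS of the index on the *raw predicted* profit means (not the
SIMEX-corrected curves), with slopes scaled per 100 USD ha⁻¹ yr⁻¹ and
t-based 95% CIs.

## Landscape optimization

Search space: multisets of L slots over n plots, C(n+L−1, L) — exactly
916,312,070,471,295,267 ≈ 9.16 × 10¹⁷ for n = L = 32, computed in exact
integer arithmetic.  Encoding: each plot replicated L times as one gene;
gene g maps to plot g mod n (1024 genes at n = L = 32).  Chromosomes are
kept at exactly L ones by a seeded repair (random flips toward L) before
evaluation, keeping the population feasible in encoding space instead of
penalizing counts.  Objectives, all scaled to [0, 1]:

- `group_richness`: |union of species over *distinct* included plots| /
  group pool — duplicates add profit weight but no species (union
  semantics; 1.0 = every sampled species present);
- `function_level`: mean over slots (with multiplicity) of the plot's
  mean min–max-standardized, direction-corrected indicator value of one
  function;
- `multidiversity` / `multifunctionality`: multiplicity-weighted mean of
  the plot-level index at a configurable threshold (default 50%) — the
  plot-mean form was chosen as the landscape-scale definition; a
  landscape-level thresholding variant would also be defensible.

Feasibility: mean profit (multiplicity-weighted) ≥ expectation.
Infeasible candidates receive a fitness strictly below any feasible one,
graded by profit shortfall so the population can climb toward
feasibility ("discard" semantics via constraint dominance).  GA defaults:
500 chromosomes, 100 generations, 20% elitism, tournament-of-two
selection, single-point crossover, bit-flip mutation at 1/(genes+1) —
genre defaults, all configurable; runs are deterministic given the seed,
and a run with no feasible solution raises an explicit error.  Groups
with missing plots shrink both the plot set and L (30 for soil
fungi/archaea, 31 for birds/testate amoebae).  The exhaustive enumerator
(budget-capped, default 10⁶ candidates; lexicographically smallest
multiset wins ties) is the exact oracle in the tests.  The Pareto sweep
over expectations {0, 200, 400, 600, 800, 1000} repairs monotonicity
post hoc: feasible sets are nested, so a better solution found at a
higher expectation replaces a worse one below it.

## Orchestration

`run_pipeline` executes simulate → profits → simex/indices → optimize
with one root seed split per stage, validates loaded datasets totally
(every malformed cell is reported with file/column/row before any stage
runs), and writes a manifest of stage outputs; identical config + seed
reproduces outputs byte-identically.  The `tradeoffs` CLI is a thin
click layer over these functions.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` exercise the full stated
design sizes where the computation is the point (B = 200, 10 λ values,
500 × 100 GA runs, 500-observation attenuation experiments over up to
100 seeds) and reduced replicate counts (e.g. B = 2–8, small populations)
where a test only checks bookkeeping or invariance; the acceptance script
uses 30 seeds for the attenuation experiment and 50 for the
sign-structure fractions, sizes at which the Monte-Carlo error of the
reported means is well below the effects being demonstrated.

## Known limitations

- The SIMEX band is pointwise and ignores between-λ correlation of the
  Monte-Carlo curves induced by shared data; it is honest about
  simulation noise but is not a simultaneous band.
- The quadratic extrapolant removes most but not all attenuation (an
  inherent SIMEX approximation); tests assert ≥ 50% bias reduction, not
  elimination.
- Threshold indices assume direction-corrected indicator values are
  nonnegative at the thresholding step, which the reflection guarantees
  only within the observed range.
- GA optimality is only verified against enumeration on small instances;
  on the full 9.16 × 10¹⁷ space the result is a heuristic best, as with
  any evolutionary method.
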