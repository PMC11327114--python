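# Methods

This note documents the model, the synthetic study system, the
estimation machinery and the numerical choices behind `envenom`, in the
package's own terms. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The envenoming model

Envenoming incidence per cell and year is the product of three factors:
the susceptible population `H`, a mass-action bite probability
`1 − exp(−h)`, and a conditional envenoming probability `Penv`:

```
ΔHe_i   = H_i (1 − e^{−h_i}) Penv_i
h_i     = max(0, β_i Σ_s c_s S_{s,i} + ρ_i)
β_i     = exp(β0[L_i] + β1[L_i] log(1 + H2010_i))
logit Penv_i = B0 + B[L_i] + Σ_s b_s S_{s,i}
```

Assumptions: humans and snakes mix homogeneously within a cell (mass
action); the contact rate `β` varies by land cover class and with the
baseline (2010) population density, absorbing occupational exposure and
the crowding-out of snakes in dense settlements; `S_s` is a relative
abundance *index* per species, not a census count; the spatial effect
`ρ` is an intrinsic CAR (ICAR) field on the rook lattice — each cell's
effect is conditionally Gaussian around its neighbours' mean with
precision `τ · n_neighbours` — with a sum-to-zero constraint for
identifiability; the susceptible population is the total population (no
depletion), appropriate when annual incidence is a small fraction of
the population.

The log-linear form of `β` in `log(1 + H2010)` with class-specific
intercept and slope is the simplest specification that is a function of
land cover and baseline density and yields a 17-parameter bite
submodel with seven species (2·5 classes + 7 species rates); the
envenoming submodel (global intercept, unconstrained class offsets,
species slopes) has 13. The class offsets `B` are deliberately
unconstrained: `B0` and `B` are only softly separated by their priors,
and the sampler handles that direction explicitly (below).

`ρ` is added *inside* the hazard (`h = βΣcS + ρ`, floored at 0) rather
than outside the exponential; the floor keeps the hazard a rate. A
floored cell has `ΔHe = 0`, which is the correct degenerate limit but
makes the likelihood non-smooth there; the sampler and the DIC
definition account for this.

### Observation model and priors

Counts are Poisson with mean `ΔHe` by default; a binomial(H, ΔHe/H)
family is available by configuration. Priors: Normal(0, 10²) on all
fixed effects on their linear scales, half-Normal(0, 5) on the species
contact rates `c_s ≥ 0`, Gamma(shape 1, rate 0.01) on `τ`. These are
weak; several posterior directions are consequently prior-dominated
(see *Identifiability*).

### MCMC

`fit_mcmc` is an adaptive random-walk Metropolis-within-Gibbs sampler.
Per iteration:

- single-site Gaussian random-walk updates of each of the 30 fixed
  effects, with `c_s` sampled on the log scale (removes the positivity
  boundary and speeds traversal across orders of magnitude); proposal
  scales adapt to 0.35 acceptance during warmup;
- correlated near-ridge proposals per land cover class (moving
  `β0[k]` and `β1[k]` along the direction that preserves the linear
  predictor at the class-mean log-population) and per species (moving
  `b_s` with a compensating shift of `B0` at the mean abundance);
- two exact moves along likelihood-invariant directions: slice sampling
  of the common shift between `log c` and `β0` (the hazard is invariant
  to `c → c e^d, β0 → β0 − d`), and a Gibbs draw of the Gaussian
  conditional along `B0 → B0 + d, B → B − d`;
- a Haario-style adaptive-covariance block proposal over all 30 fixed
  effects (eight proposals per iteration, one of them at triple scale to
  jump soft ridges), with running moments that exclude the initial
  transient — the diminishing adaptation keeps the chain ergodic;
- a conjugate Gibbs draw of `τ` given the ICAR quadratic form;
- three chequerboard sweeps of single-site `ρ` updates (all cells of one
  colour are conditionally independent given the other), after which the
  field is re-centred to sum to zero and the cached likelihood state is
  rebuilt, which also caps floating-point drift from incremental
  updates.

Chains are initialised at the posterior mode of the fixed effects
(L-BFGS with `ρ = 0`) plus per-chain jitter, with `ρ` started at the
clipped MAP hazard residual: a zero `ρ` start makes the first `τ` Gibbs
draw enormous and freezes the field. Warmup is the first half of each
chain and is discarded. Split-R̂ and effective sample sizes come from
ArviZ.

### Identifiability

The model is over-parameterised by design, as the structural
parameterisation requires: the scale of `c` against `β0`, `B0` against
`B`, and (through the logit) `b` against `B0` are only prior-identified,
and a "saturated-bite" mode (`p_bite → 1`, pattern explained by `Penv`
alone) exists in principle. Identification of the hazard channel comes
from the nonlinearity of `1 − e^{−h}` and from population variation
within classes; the synthetic population generator therefore spans a
realistically wide density range (lognormal spread over roughly two
orders of magnitude). Posterior intervals for individual weakly
identified coefficients are wide — interval coverage in the recovery
experiment is the meaningful check, not point accuracy.

### DIC and posterior predictive check

DIC is `D̄ + p_D` with `p_D = D̄ − D̂`. The plug-in deviance `D̂` is
evaluated at the posterior mean of the *expected incidence surface*
(mean-parameterisation focus) rather than at the posterior mean of the
raw parameters: the hazard floor can make the latter degenerate (a
plug-in mean of exactly 0 against a positive count).

The posterior predictive check computes Pearson's r between observed
counts and the posterior-median surface, with a Monte Carlo p value
against a null of random torus shifts of the observed field — shifts
preserve the field's spatial autocorrelation while breaking its
alignment with the prediction, which is the spatial correction needed
on a lattice.

## The synthetic study system

`make_default_truth` builds a 20×20 lattice of 1 km² cells (so 5×
block upscaling gives a 4×4 coarse model grid) with climate from 2008
so a 3-year rolling window exists for every projection year:

- **Climate**: monthly tmin/tmax/rain as a lowland seasonal cycle minus
  a 6.5 °C/km lapse over a fixed central-highland elevation surface,
  plus smoothed Gaussian random fields (moving-average kernel, width 5
  cells), a national interannual anomaly (sd 0.25 °C) and multiplicative
  lognormal rainfall noise; trends accrue linearly (°C/decade) or
  geometrically (rain multiplier/decade).
- **Land cover**: five-class mosaic from per-class smoothed score
  fields; classes claim their quota of best cells in turn so realized
  shares match requested fractions to rounding.
- **Population**: lognormal smooth base field around 300 persons/km²
  with spread wide enough to span rural hamlets and dense towns (factor
  ~20 between low and high cells); decadal growth multiplied exactly at
  the national level and concentrated near urban cells when requested.
- **Species**: seven log-linear intensity surfaces in standardized
  annual tmax and rainfall, proportion agriculture, distance to forest
  and distance to a species-specific climatic niche centroid. Centroids
  separate dry-zone taxa (warm/dry side) from wet-zone taxa (cool/wet
  side) so the seven surfaces are not collinear. Occurrences are a
  multinomial draw (150 points per species) proportional to intensity.
- **Generating parameters** (`default_params`): contact is highest in
  agriculture and tea and lowest in urban cells; Russell's viper and the
  hump-nosed vipers carry the largest species contact rates. The
  resulting national incidence is on the order of 1–2% per year — high
  relative to actual envenoming rates, but it keeps per-cell counts
  informative at desk scale. `τ = 1000` makes the ICAR field a modest
  correction (roughly a third of the hazard scale): the spatial effect
  is a residual term, not the dominant signal.
- **Observation**: Poisson counts around `ΔHe`, capped at the cell
  population. The real survey's noise model is not asserted; the family
  is a configuration choice.

All randomness flows from one master seed through named
`SeedSequence` streams, so every fixture is exactly regenerable, and
`write_fixture`/`read_fixture` persist a system as TIFF/CSV/JSON with
sha256 checksums.

What the generator does **not** emulate: coastlines and real geography,
observation biases of occurrence databases, imperfect detection in
incidence surveys, within-class heterogeneity of contact rates, and
socioeconomic covariates. Passing tests demonstrate internal
consistency of the method at realistic magnitudes, not transferability
to any real surveillance dataset.

## Pipeline stages

- **Delta-method bias correction**: per calendar month and cell,
  additive factors for temperatures (observed − modelled reference
  climatology) and multiplicative for rainfall (observed/modelled,
  denominator floored at 0.01 to guard dry cells). Applying a
  correction to its own reference period reproduces the observed
  climatology (exactly for differences, up to the floor for ratios).
  Backcast validation reports pooled Pearson r, OLS slope/intercept of
  observed on backcast, and RMSE.
- **Climate windows**: projections use bioclim summaries (mean monthly
  tmin/tmax, total rainfall) averaged over each year and the two
  preceding (window 3). The window re-analysis fits one Poisson
  regression of counts on the three windowed summaries with a
  log-population offset per candidate window 1–10 and picks the AIC
  minimiser, ties to the smaller window; the criterion itself is a
  package choice since window selection requires *some* information
  criterion, and AIC of the same GLM family is the natural one.
- **Land cover change**: CLUE-style competitive allocation. Score =
  logit suitability (per-class logistic regressions on driver layers)
  + conversion-resistance bonus for the incumbent class + per-class
  offset; cells take the legal argmax and offsets adjust iteratively
  until counts match demand. When the iteration converges at zero
  tolerance the result is exactly the total-score-maximising assignment
  subject to demand (offsets are dual prices; argmax with demand met is
  complementary slackness) — verified against exhaustive search on
  9-cell maps. If the dual iteration stalls a few cells short (marginal
  cells cycling), a greedy legal repair moves cheapest cells from
  surplus to deficit classes; infeasible demands still raise a
  non-convergence error. Tie-breaks go to the lowest class code;
  default tolerance 1 cell, 1000 iterations. The projection pipeline
  uses a conversion-resistance of 4 logits so land cover persists
  year-to-year unless demand forces change, which keeps a null scenario
  (constant demand) free of allocation churn. Pairwise annual
  change-rate caps are not imposed by default. Tree cover is reclassed
  from five 20% bands (midpoints 0.10…0.90) to proportions by one
  rescaling factor matching a reference mean, clamped to [0, 0.99].
- **Population**: decadal layers are bias-corrected by the cellwise
  mean observed/predicted quotient (cells with predicted density below
  0.5 persons/km² take the study-area mean factor — the quotient is
  meaningless in empty cells) and interpolated annually with
  shape-preserving PCHIP (harmonic-mean slopes), which passes through
  knots exactly, adds no new extrema, and preserves non-negativity;
  Catmull-Rom-style Hermite splines can overshoot below zero, which is
  why the shape-preserving flavour is used.
- **Abundance projection**: per-species Poisson intensity GLMs are fit
  to gridded occurrence counts with a cell-area offset (an
  inhomogeneous log-linear intensity; interaction terms of full point
  process models are out of scope because the pipeline consumes only an
  intensity surface). Covariates are standardized with *baseline*
  means/sds so projected trends are not re-absorbed by
  restandardization. Niche distance is Euclidean in per-variable
  standardized climate space. Expert relative-abundance adjustment is a
  raw multiplicative weight per species (default 1).
- **Scenarios**: SSP1 pairs with no further emissions and a
  deterministic continuation of the observed reference climatology (a
  smooth trend projection, no resimulated interannual weather); SSP2
  with RCP4.5 and SSP5 with RCP8.5, each nested over three synthetic
  RCM variants that carry a systematic bias (+1.5 °C, ×0.85 rain by
  default) which the delta correction must remove. Demand trajectories
  are linear between 2010 counts and scenario end-shares.
- **Upscaling and evaluation**: species intensity and population are
  block-summed 5× to the coarse model grid; land cover by majority vote
  (ties to the lowest class code). The model consumes per-km²
  intensities (block sums divided by block area) so the 1 km-scale
  parameters keep their meaning, while the case multiplier uses the
  total coarse population; fitted parameters are held constant across
  years and `ρ` is not projected (it is a fitting-scale residual).
- **Change statistics**: per-cell OLS slope of incidence on year;
  percentage change 100·(end − start)/start with zero-baseline cells
  masked; national accumulated change from the regression of the
  national incidence rate (total cases / total population) on year,
  with the SE propagated from the slope's standard error (the
  regression-based definition matches the use of a slope SE for the
  uncertainty band); RCM consensus as the per-cell count of strictly
  negative slopes (zero counts as not decreasing); dominant species by
  argmax of `c_s · S_s · exp(b_s)` (a pure `c_s · S_s` weighting is
  available, since the exact figure weighting is a judgment call);
  per-transition distributions of percentage change (median, IQR,
  2.5th/97.5th percentiles).

## Numerical choices

- Probabilities are clamped to the open interval at machine precision
  (`1 − e^{−h}` and `expit` saturate to exact 0/1 in floats for extreme
  arguments, which would break the strict invariants).
- The ICAR log density is `(n−1)/2 · log τ − τ/2 Σ_{i~j}(ρ_i − ρ_j)²`
  (rank-deficient normaliser on a connected lattice); it is checked
  against a dense pseudo-inverse Gaussian on 3×3 lattices.
- `validate_downscale` refuses constant backcasts (undefined
  correlation); degenerate logistic fits raise a separation error
  naming the class; all-zero occurrence counts raise a degenerate-data
  error; constant abundance covariates are dropped with a warning.
- Fixture round-trips are bit-exact for integer rasters and within
  representation error for floats; manifests carry sha256 checksums and
  the master seed.

## Problem sizes

The default experiments run on the 20×20 system: the recovery
experiment uses one simulated survey and 3 chains × 20,000 iterations;
scenario runs cover 2010–2050 annually; the window re-analysis uses ten
replicate 14-year climate histories; allocator checks run 41 years and
exhaustive comparisons on 3×3 maps. These sizes keep the complete suite
at desk scale while leaving every estimate comfortably informative.

## Known limitations

- The bare `c_s`, `β0`, `B0`/`B` coefficients are reported as sampled,
  but only combinations of them are well identified; compare intervals,
  not medians, against generating values.
- The allocator is a documented re-implementation of the CLUE-S
  competitive mechanism, not a bit-level reproduction of any released
  land-change tool.
- `ρ` is estimated at the fitting scale and held at zero in
  projections; spatially varying residual risk is therefore not
  propagated into scenarios.
- The synthetic RCM ensemble shares one weather generator; cross-RCM
  spread understates real structural climate-model uncertainty.
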