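# Methods

This note documents the models, numerical choices and limitations behind
`riskscape`, in the order data flow through the pipeline.

## Predation-risk kernel

The influence of one predator nest at distance `d` is

```
h(d) = 1                                   d <= f        (plateau)
       exp(-(d - f)^2 / (2 s^2))           f < d <= c    (Gaussian flank)
       0                                   d > c         (cut-off)
```

with plateau radius `f` (m), flank SD `s` (m) and cut-off `c = 10 000` m.
The kernel is unit-height, not a normalised density: the covariate is
standardised before model fitting, so any overall scale cancels (this is
tested — multiplying all heights by a constant changes nothing but the
intercept).  The function is continuous except at the cut-off, where the
jump is `exp(-(c - f)^2 / (2 s^2))` (about 0.043 at the widest default
kernel, `s` = 4 km, `f` = 2.5 km).

Across multiple nests of one species and year the box-level covariate is
the **sum** of kernel heights by default, reflecting cumulative exposure to
several territories; a pointwise **max** is available as a configuration
option for a worst-case-exposure reading.  The candidate grids are SDs of
{1, 2, 3, 4} km crossed with plateaus of {500, 1000, 1500, 2000, 2500} m.
The SD candidates are interpreted in kilometers: meter-scale SDs would be
degenerate next to 500-2500 m plateaus and a 10 km cut-off.

Hyperparameters and the temporal lag (0 = current year's nests, 1 =
previous year's) are selected jointly: the full occupancy model is refit
once per candidate and the minimum-AIC candidate wins, with ties broken
toward smaller plateau, then smaller SD, then smaller lag.  Non-converged
candidate fits are recorded and excluded from the argmin.  A missing
predator-survey year is filled from the nearest available year, preferring
the later one, and every fill is flagged in the output.

## Habitat composition

Land-use rasters are planar-metric categorical grids (ESRI ASCII or
single-band GeoTIFF).  Raw codes are merged to the analysis classes (young
and mature forest types by dominant species, clear cuts, built areas, bogs,
and agricultural field as its own code, 25, since field layers typically
come from a separate land-use source).  Buffer composition uses the
**cell-center rule**: a cell contributes its full area iff its center lies
within the buffer radius.  This is standard zonal practice; the
discretisation error is confined to perimeter cells (on a uniform grid the
300 m buffer at 25 m cells is within 2% of the analytic circle area) and
the implementation is tested for exact agreement with a brute-force
enumeration oracle.  Buffers are truncated at grid edges; the synthetic
generator therefore keeps a margin of at least the largest radius between
boxes and the grid boundary.  Areas are reported in hectares; all
coordinates and distances are meters.

## Occupancy models

Cleaning keeps the *first* visit per box-year (equal search effort) and
drops box-years first visited after June.  The red-squirrel series carries
a two-level `time_period` factor split at 2006, when nest-material
recording began.

The model is a logit-link Bernoulli GLMM with independent Gaussian random
intercepts, `site` only (red squirrel, one box per site) or `box` nested in
`site` (flying squirrel, two boxes per site).  All continuous covariates,
including year, are standardised by `(x - mean)/sd` with the sample SD;
quadratic and interaction columns are products of *standardised* parents
and are not re-standardised.  Factors enter as 0/1 indicators.

**Estimation.**  For fixed effects `beta` and log-SDs of the random
intercepts, the random-effect vector is profiled out at its penalised-mode
value (Newton iterations; under nesting the mode solve and the
log-determinant are closed-form diagonal operations after two Schur steps,
so each iteration is O(n)).  The Laplace-approximate marginal
log-likelihood

```
l = l(y | beta, u_hat) - u_hat' D^-1 u_hat / 2 - log|D|/2 - log|Z'WZ + D^-1|/2
```

is maximised over `(beta, log sigma)` with L-BFGS-B.  `beta` belongs in the
outer problem because the log-determinant depends on it through the working
weights `W`; profiling `beta` inside the penalised solve (the faster
PIRLS-only shortcut) attenuates estimates noticeably at realistic cluster
sizes.  On shared test data the fitter agrees with `glmmTMB` and
`lme4::glmer` (Laplace) to ~1e-4 in coefficients and log-likelihood.

Numerical choices: inner mode tolerance 1e-11 relative change with step
halving; outer bounds `log sigma` in [-8, 3] (the lower bound is the
numerically-zero-variance boundary, at which the model reduces to the GLM);
fixed deterministic start at the plain-logistic estimates with variance
0.1; working weights floored at 1e-10; a |coefficient| > 15 triggers a
separation warning.  With no random structure the fit is exact damped
IRLS and matches an independent logistic oracle to 1e-6.

Standard errors come from the central-difference observed information of
the Laplace objective over all outer parameters (matching glmmTMB); a
cheaper profile (Schur-complement) covariance is used inside grid searches
where only AIC matters.  AIC is `-2 logLik + 2(p + q)` with `q` the number
of variance parameters; only AIC differences are ever interpreted.

**Screening and selection.**  VIFs are computed on main-effect habitat
covariates only (quadratics would inflate them trivially; mandatory terms
are never dropped) and the largest-VIF variable is removed iteratively
until all are below 5.  In compositional habitat data one class is always
close to a linear combination of the others, so a drop is expected; the
dropped class (young pine in the emulated design) is analysed in separate
models instead.  Best-subset search enumerates all subsets of the optional
main-effect terms (capped at 20 terms), pairs each quadratic with its
parent, ranks by AIC, and breaks exact ties toward fewer terms, then
lexicographic order.  Predator x habitat interactions are fitted at the
home-range scale, with interaction parents forced back into the model if
the VIF screen removed them; interactions with p >= 0.05 are dropped and
the model refit.  Cone-crop models join the previous autumn's cone index,
use a site-only intercept, and fit cone + forest + cone:forest for spruce
and pine separately.  Wald inference is two-sided at alpha = 0.05
throughout, with no multiplicity correction.

## Residual diagnostics

Pearson residuals (by default) use fitted probabilities that include the
random-effect modes.  Moran's I uses binary distance-band weights
(`w_ij = 1` iff `0 < d_ij <= r`), not row-standardised, with
normal-approximation expectation `-1/(n-1)` and variance; a seeded
permutation test is available for small n.  Boxes sharing a coordinate are
averaged, and by default each box contributes its mean residual across
years.  Constant residuals and empty weight matrices raise errors rather
than returning 0 — at a 50 m radius the emulated flying-squirrel design has
no neighbour pairs at all (boxes are 80-100 m apart).

A caveat worth knowing: conditional residuals of two boxes in the same site
are negatively correlated by construction (the site mode fits their
average), so at radii where only within-site pairs are neighbours the
statistic is pushed negative even for a correctly specified model.  This is
a property of mode-based residuals, not evidence of missing spatial
structure; comparing radii, and the per-year option, help separate the two.

## Synthetic-data generator

The generator emulates the study design, not any particular landscape:

- **Landscape:** one smoothed Gaussian random field per class (wrap-mode
  smoothing at the clustering range, default 300 m); each cell takes the
  argmax of field + offset, with offsets calibrated iteratively from the
  log target shares so empirical proportions match the configured mix
  (within a few tenths of a point; the acceptance band is 3 points).  The
  default 13-class mix is a forest-dominated mosaic with 15% field, 9% bog
  and 3% built area.  Cells are written as raw land-use codes so the
  merging step is exercised.  Default cell size 25 m (typical of
  Landsat-derived classifications).
- **Sites and boxes:** hard-core inhibition (>= 800 m between sites) on
  forest cells, with the second box of a flying-squirrel pair at a uniform
  bearing 80-100 m away.  Geometry constraints are asserted on every draw.
- **Predators:** year-one nest counts are Poisson at 2 (owl) and 1
  (goshawk) pairs per 10 km^2, placed on forest cells; each later year a
  nest keeps its location with probability 0.8 (territory persistence) and
  otherwise relocates.  Persistence below 1 is what makes lag-0 and lag-1
  kernels distinguishable; 0.8 encodes strong long-term site fidelity with
  some turnover.
- **Cone index:** i.i.d. log-normal (log-SD 0.5) with mast years (prob
  0.25, x4), generated from the year before the first analysis year so the
  lag-1 join is always defined.
- **Outcomes:** `eta = beta0 + sum beta_t z_t + b_site + b_box` on
  standardised covariates, Bernoulli draws, with the realised covariates,
  linear predictor and random effects returned as recoverable truth.  The
  default flying-squirrel truth uses risk -2.4, field 0.71, field^2 -0.23,
  year 0.26, sigma_site 1.0, sigma_box 0.5 and a kernel of SD 3000 m /
  plateau 2500 m at lag 1; the red-squirrel preset uses goshawk -0.22 at
  lag 0, time-period 1.33, cone 0.17 and cone x spruce 0.08.
- **Visits:** each box-year gets a first visit in April-June carrying the
  true state; 30% get a later (uninformative) second visit and 2% are first
  visited only in July, which the cleaning stage must drop.

Per-component random streams are spawned from the master seed, so outputs
are byte-identical under a fixed seed and changing one component's
parameters does not perturb the others' draws.

What the generator does **not** emulate: imperfect detection, observer
effort variation, box relocation after clear-cutting, vole/weather
covariates, or the real spatial covariance of Finnish land use.  Passing
recovery tests therefore demonstrate that the pipeline is a consistent
estimator of its own generating model at study-like size and geometry —
not that the field system satisfies these assumptions.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the full design at 200 sites x 10
years (flying) and 120-250 sites x 17 years (red), with 10 replicates for
parameter/kernel recovery, 500 independent reduced-size replicates (50
sites x 5 years) for Wald-test calibration, and 100 replicates for
null-interaction dropping.  Wald tests in this model family are mildly
liberal at 50 sites (empirical size around 0.05-0.07 at nominal 0.05, with
p-values agreeing with `glmer` to four decimals), which is worth
remembering when interpreting borderline effects at small n.

## Known limitations

- Random intercepts only; no random slopes, crossed factors, or spatially
  correlated effects.
- No detection-probability (imperfect-detection) occupancy layer; the
  first-visit rule addresses effort, not detectability.
- Exhaustive best-subset search is exponential and capped at 20 optional
  terms; the pipeline exposes a configurable term universe instead of a
  heuristic search.
- Kernel selection refits the full model 40 times per predator; with the
  fast profile-covariance path each fit is sub-second at 4000 box-years,
  but very large designs would want a coarser first pass.
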