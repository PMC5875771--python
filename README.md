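# riskscape

Predation-risk kernel surfaces and mixed-model nest-box occupancy analysis
for landscape ecology.

## The problem

Arboreal squirrels in managed boreal forest choose nest sites under two
simultaneous pressures: the composition of the surrounding habitat and the
proximity of their avian predators (Ural owls for the nocturnal flying
squirrel, goshawks for the diurnal red squirrel).  Long-term nest-box
monitoring programs record yearly presence/absence per box, predator-nest
surveys give the predators' nest coordinates, and land-use rasters describe
the habitat mosaic.  `riskscape` implements the full inference chain that
links these data sources:

1. **Predation-risk covariate.**  The risk surface around a predator nest is
   a *flat-top bivariate Gaussian kernel*: height 1 on a plateau of radius
   *f* around the nest, decaying beyond it as

   `h(d) = exp(-(d - f)^2 / (2 sigma^2))` for `f < d <= 10 km`,  and 0 past
   the 10 km cut-off.

   The surface height at a nest-box location, summed over all predator
   nests of one species and year, is the risk covariate.  The kernel's SD
   (1-4 km), plateau radius (500-2500 m) and temporal lag (current vs
   previous year's nests) are selected by refitting the full occupancy model
   for each of the 20 x 2 candidates and taking the minimum AIC.

2. **Habitat composition.**  Areas (ha) of merged land-use classes whose
   cell centers fall within circular buffers around each box, at a
   home-range scale (200 m flying / 300 m red) and a dispersal scale
   (1000 m / 2500 m).

3. **Occupancy models.**  Logit-link Bernoulli mixed models
   `logit P(occupied) = X beta + b_site (+ b_box)` with Gaussian random
   intercepts for site and, in the two-boxes-per-site flying-squirrel
   design, box nested in site.  All continuous covariates (including year)
   are standardised as `(x - mean)/sd`; agricultural field enters with a
   quadratic term.  Estimation is maximum likelihood under the Laplace
   approximation (verified against `lme4::glmer` / `glmmTMB`).  Habitat
   covariates are screened for multicollinearity with VIFs (threshold 5);
   predator x habitat interactions and (for red squirrels) previous-autumn
   cone-crop x forest-type interactions are tested and non-significant
   interactions dropped; the full model is compared against the 10 best
   AIC-ranked term subsets.

4. **Diagnostics.**  Moran's I of model residuals under binary
   distance-band weights at configurable radii, with normal-approximation
   or permutation inference.

Because the original field data are not public, the package ships a
first-class synthetic-data generator (`riskscape.simulate`) that emulates
the study design — clustered categorical landscape, hard-core site
placement with 80-100 m box pairs, persistent predator territories, mast-y
cone series, and occupancy drawn from the logistic truth model — so every
stage is testable end to end with known ground truth.

## Worked example

```python
from riskscape import (flying_config, simulate_dataset, ModelSpec,
                       build_design, fit_glmm, wald_table)

cfg = flying_config(seed=7, n_sites=100, years=tuple(range(2002, 2010)))
data = simulate_dataset(cfg)          # landscape, boxes, predators, outcomes
table = (data.occupancy
         .merge(data.covariates, on=["box_id", "year"])
         .merge(data.boxes[["box_id", "site_id"]], on="box_id"))
spec = ModelSpec(mandatory=["year"], habitat=["Mo spruce", "Field"],
                 risk=["ural_owl"], quadratic=["Field"], random="site_box")
fit = fit_glmm(build_design(table, spec))
print(wald_table(fit).round(3).to_string(index=False))
```

prints

```
     term  estimate    se       z     p  significant
Intercept    -0.156 0.135  -1.155 0.248        False
     year     0.167 0.067   2.502 0.012         True
Mo spruce    -0.065 0.117  -0.555 0.579        False
    Field     0.296 0.233   1.273 0.203        False
 ural_owl    -2.052 0.141 -14.598 0.000         True
  Field^2    -0.056 0.075  -0.749 0.454        False
```

The simulated Ural-owl kernel effect (truth -2.4 on the log-odds scale per
SD of risk) is recovered as -2.05 +/- 0.14 and is overwhelmingly
significant, while habitat terms whose simulated effect is zero stay
non-significant.  `fit.sigma_site` / `fit.sigma_box` return the fitted
random-intercept SDs (0.80 and 0.37 here; truths 1.0 and 0.5).

## Command line

The `riskscape` console script wraps the same library: `simulate`, `clean`,
`habitat`, `risk`, `select-kernel`, `fit`, `interactions`, `cones`,
`diagnose`, `report`, and `run-all`, driven by a YAML config (see
`riskscape.pipeline.PipelineConfig`).  `run-all` executes the whole
workflow — cleaning, buffer compositions at both scales, VIF screening,
kernel/lag selection per predator, full mixed models, separate young-pine
models, interaction and cone analyses, best-subset ranking, and Moran's I —
persisting each stage's outputs as plain CSV.

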