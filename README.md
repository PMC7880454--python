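# nomadsel

Resource- and step-selection analysis for nomadic movers on **dynamic**
raster landscapes — the setting where the covariate an animal selects
(vegetation greenness in the growing season, snow-cover fraction in
winter) is itself a time-indexed sequence of satellite composites rather
than a static map.

The package is aimed at movement ecologists who have (a) relocation
tables (individual id, timestamp, planar x/y), (b) dated covariate
scenes (16-day greenness composites in roughly [−0.2, 1]; 8-day
categorical snow products), and (c) optionally a study boundary, and who
want both a population-level and an individual-level answer to "what
covariate values does this animal select?".  A synthetic landscape and
mover generator with known ground-truth selection coefficients makes
every stage testable without any satellite download.

## Models

**Resource selection function (RSF, population level).**  Used daily
locations (response 1, weight 1) are contrasted against pseudo-absence
points (response 0, weight 1000) drawn scene-by-scene inside each
individual-season-year's 100% minimum convex polygon, in a weighted
logistic mixed model

&nbsp;&nbsp;&nbsp;&nbsp;logit P(used) = β₀ + β₁ z (+ β₂ z²) + random effects,

with candidate random intercept/slope by individual and random
intercepts by year and by scene, fitted by Laplace-approximated maximum
likelihood.  Singular variance components are removed one at a time
(smallest first) until the fit is clean.  The linear shape encodes
selection for the maximum/minimum available covariate, the quadratic
shape selection for intermediate (β₂ < 0) or extreme (β₂ > 0) values;
the shapes are compared by AIC and Akaike weights.

**Step-selection function (SSF, individual level).**  Each observed step
at a lag of 1, 5 or 10 days is matched with K pseudo-steps (lengths and
turns resampled independently from the pooled empirical kernels at that
lag) and fitted by conditional logistic regression on the matched
likelihood ∏ₛ exp(η_obs)/Σⱼ exp(ηⱼ) with η = β₁z (+ β₂z²).  Entities
with at least 20 steps are fitted; a likelihood-ratio test against the
null conditional likelihood gates significance (α = 0.05), AIC picks the
shape, and each entity is classified as selecting the maximum, minimum,
intermediate or extreme covariate values — or none.  Individuals with
several classified years yield a strategy-switching summary.

**Relative selection strength (RSS).**  Results are reported as
log RSS(x, x_ref) = β₁(x − x_ref) + β₂(x² − x_ref²) over the trimmed
availability range (5th–95th percentile of pooled used + available
values), referenced to the trimmed mean; the covariate value at peak
selection (−β₁/(2β₂) for a downward parabola) is reference-invariant and
is the headline per-model number.

## Worked example

Simulate a mover that selects covariate values near 13/28 ≈ 0.46
(quadratic truth β₁ = 13, β₂ = −14) on a heterogeneous dynamic
landscape, then recover the selection from its track alone:

```python
import numpy as np
from nomadsel import (LandscapeConfig, MoverConfig, generate_scene_series,
                      simulate_mover, build_kernel, generate_pseudo_steps,
                      fit_clogit, classify_selection)
from nomadsel.tracks import steps_for_track

scenes = generate_scene_series(LandscapeConfig(
    grid_nx=128, grid_ny=128, correlation_length=1000.0, n_scenes=33,
    value_mean=0.5, value_sd=0.25, value_min=0.0, value_max=1.0, rng_seed=11))
track = simulate_mover(MoverConfig(beta1=13.0, beta2=-14.0, n_days=520,
                                   rng_seed=101), scenes)
steps = steps_for_track(track, lag_days=1)
strata = generate_pseudo_steps(steps, build_kernel(steps, 1), K=100,
                               scenes=scenes, rng=np.random.default_rng(0))
fit_quad = fit_clogit(strata, "quadratic")
cls = classify_selection(fit_clogit(strata, "linear"), fit_quad)
print(f"strata: {strata.n_strata}")
print(f"quadratic fit: b1 = {fit_quad.beta['z']:.2f} (SE {fit_quad.se['z']:.2f}), "
      f"b2 = {fit_quad.beta['z2']:.2f} (SE {fit_quad.se['z2']:.2f})")
print(f"category: {cls.category}, peak covariate: {cls.peak_covariate:.3f}")
```

prints:

```
strata: 513
quadratic fit: b1 = 11.67 (SE 1.43), b2 = -13.03 (SE 1.51)
category: intermediate, peak covariate: 0.447
```

i.e. the fitted selection surface is a downward parabola whose peak
(0.447) sits near the ground truth 13/28 ≈ 0.464, and the entity is
classified as selecting intermediate covariate values.

The full two-season pipeline (simulate → prepare → rsf → ssf → report)
runs from the command line:

```sh
nomadsel all --outdir demo_out --seed 3
```

and writes the use–availability tables, model-comparison and
coefficient tables, RSS curves, per-category percentages and the
switching summary as CSV, with a manifest per stage.

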