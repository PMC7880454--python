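# Methods

This note documents the statistical machinery, the synthetic data it is
validated on, the numerical choices, and the design decisions taken
where the problem was genuinely open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The estimation problem

Both analyses target the exponential (log-linear) selection model: the
relative weight an animal puts on a location with covariate value z is
w(z) = exp(β₁z + β₂z²).  A downward parabola (β₂ < 0) peaks at
−β₁/(2β₂) and encodes selection for intermediate values — the shape
predicted by the forage-maturation hypothesis for a grazing ruminant on
a greenness covariate, and by the water-versus-mobility trade-off for
snow cover.  The linear sub-model (β₂ = 0) encodes monotone selection
for the maximum or minimum available value.

Selection is only ever *relative*: both designs compare used locations
to an availability sample, and all reporting goes through relative
selection strength, log RSS(x, x_ref) = β₁(x − x_ref) + β₂(x² − x_ref²).
Changing the reference shifts curves by a constant and never moves the
peak, so the peak covariate value is the comparison-safe summary.

## RSF: weighted logistic mixed models

Availability for each individual-season-year is its 100% minimum convex
polygon (convex hull of the daily fixes), clipped to a study boundary
when one is supplied.  Pseudo-absences are allocated per covariate
scene — `multiplier` × the number of used points whose dates fall in
that scene's window — and placed by grid-stratified sampling: the
polygon's bounding box is divided into a 10 × 10 grid (configurable),
cells receive counts proportional to their in-polygon area (largest
remainders), and points are rejection-sampled into each cell.  Used
points weigh 1, available points 1000; the large availability weight is
the standard device that makes the logistic slope estimates approximate
the underlying log-linear intensity model, removing the dependence of
the slopes on the arbitrary availability sample size.  Weights multiply
only the Bernoulli log-likelihood terms.

The mixed model is fitted by in-house Laplace-approximated maximum
likelihood with independent Gaussian random terms (intercept and slope
by individual, intercepts by year and scene; no intercept–slope
correlation).  For candidate SDs σ the penalized joint likelihood is
maximized over fixed effects and spherical random effects by Newton
iteration (relative log-likelihood tolerance 10⁻¹⁰, weight-scaled
gradient tolerance), and the profile

l(σ) = l_joint − ½ log det(I + (ZΛ)ᵀW(ZΛ)),  Λ = diag(σ)

is maximized over σ by bounded Nelder–Mead.  Because a derivative-free
optimizer can stall just off the boundary, any component below 0.1 is
checked against its exact-zero value and snapped to zero when removal
costs nothing (10⁻³ on the log-likelihood); a component whose SD is
below 10⁻⁴ is flagged singular.  The simplification ladder removes the
smallest singular component and refits until the model is clean, with
the fixed-effects-only model as the floor; every removal is recorded in
the audit trail.  With no random terms the same Newton solver is an
exact weighted logistic regression (it matches an independent GLM
implementation to 10⁻⁶ in the tests, and the one-random-intercept fit
matches an independent Laplace GLMM implementation to ~10⁻² on β and
10⁻² on σ).

AIC is −2·l_Laplace + 2(#fixed + #variance parameters); shapes are
compared by ΔAIC and Akaike weights on identical row sets only.
Coefficient p-values are Wald z-tests.  Marginal/conditional R² follow
the variance-partition convention: fixed (resp. fixed + random) latent
variance over total latent variance with the logistic residual π²/3;
random-slope contributions are scaled by the mean squared covariate.
Covariates stay on their natural scale so peak formulas apply to the
reported coefficients directly.  Multiplier stability refits the chosen
model across the 1/2/5/10/20× availability ratios and reports the
largest relative change in the selection coefficients between the two
largest multipliers; the intercept is excluded because it absorbs the
sampling ratio by construction.

## SSF: matched conditional logistic regression

Daily fixes are first regularized (sub-daily fixes collapse to the
day's centroid).  Steps at lag L ∈ {1, 5, 10} days come from maximal
runs of fixes spaced exactly L calendar days apart; every phase offset
contributes runs, and a run needs ≥ 3 points (the minimum for a turn
angle).  Turn angles are counter-clockwise-positive differences of
successive headings wrapped to (−π, π]; zero-length steps keep zero
displacement, have no heading, and leave the following turn undefined.

Step-length and turn samples are pooled across individuals per lag into
an empirical kernel (zero-length steps excluded); pseudo-steps resample
length and turn independently and are placed at the previous observed
heading plus the drawn turn, from the step's start point, reading the
covariate from the scene containing the step's end date.  Strata that
cannot fill K valid endpoints within 10 redraw rounds, or whose
observed covariate is missing, are dropped whole — never padded
asymmetrically.

The conditional likelihood is maximized by Newton iteration on the
exact gradient and observed information (stratum-centered design for
conditioning; gradient norm < 10⁻⁸), with step-halving.  The same
solver matches a brute-force maximization of the explicit product
likelihood to 10⁻⁶ and an independent conditional-logit implementation
to 10⁻⁵ in the tests.  Significance is a likelihood-ratio test against
the null conditional likelihood (−Σ log(K+1)): 1 df for the linear
model, a joint 2-df test for the quadratic — a joint test being the
only coherent α ≤ 0.05 criterion for a two-term model.  Among
significant models AIC picks the shape; the category follows from the
slope sign (max/min) or the curvature sign (intermediate/extreme), with
an exactly-zero curvature treated as linear-shaped and logged.
Entities need ≥ 20 strata; growing-season fits run per individual at
all lags plus per individual-year at the 1-day lag, winter fits per
individual-year at all lags, reflecting how data volume differs between
the seasons.  K defaults to 400 for reported results, with
25/50/100/200/400 available for stability checks.  A strategy switch is
any change of category (including to or from "none") across an
individual's classified years.

## Scenes and seasons

Scenes are half-open date windows [start, start + period); 16-day for
greenness, 8-day for snow.  The categorical snow product is
reclassified to binary snow / no-snow with every other class (cloud,
night, lake, ...) as nodata — unknown codes are an error — and then
block-aggregated (default 4 × 4, i.e. 500 m → 2 km) to a mean
snow-cover fraction, ignoring nodata cells.  The growing season is the
longest run of calendar dates whose covering scenes are snow-free
(fraction > 0 anywhere counts as snow; threshold configurable) in every
observed year; all remaining dates are winter, and a winter spanning
New Year is labelled by its starting calendar year.  The default
calendar boundary dates (May 9 – Aug 29) are configurable.

Raster I/O uses single-band TIFFs with a JSON sidecar index carrying
origin, cell size, dates, period and covariate kind; all geometry is
planar metric coordinates (projected data are assumed; the methods are
coordinate-system-agnostic).

## Synthetic data: what it emulates and what it does not

Landscapes are Gaussian random fields (white noise smoothed with a
Gaussian kernel of bandwidth = correlation length) evolving between
scenes as AR(1) with coefficient `temporal_persistence`, rescaled and
clamped — emulating broad, slowly shifting greenness/snow patterns on a
16/8-day cadence.  Movers draw `n_candidates` endpoints per day from an
explicit kernel (gamma lengths, mean `step_scale`, shape 2; von-Mises
turns) and select one with probability ∝ exp(β₁z + β₂z²) — exactly the
discrete-choice estimand an SSF targets, which is what makes parameter
recovery checkable.  Out-of-grid candidates are redrawn up to 20 times
then reflected.  Collar imperfections are emulated by random fix drops
and optional hourly bursts with Gaussian jitter.

Recovery and type-I tests run on a 128 × 128-cell, 250 m landscape with
1 km correlation length, values clamped to [0, 1], persistence 0.8, and
movers with 2 km mean daily steps (~520 days for recovery, ~130 for the
null replicates) — sizes at which a full replicate set fits in seconds
while strata counts (~500 and ~125) match the regimes of interest.

The generator does not model herding or fission–fusion dynamics,
memory, perception radius, barriers, or multi-covariate landscapes.
Passing recovery tests therefore show the estimators are correct for
movement that truly follows the step-kernel + exponential-selection
process; they do not show robustness to social or cognitive movement
drivers absent from the generator.  One known, accepted approximation:
pseudo-steps resample the *observed* (selection-tilted) step lengths
rather than the unobservable availability law, which induces a small
attenuation visible in the recovery tests — the standard empirical-SSF
construction, retained deliberately.

## Numerical choices and degenerate inputs

- Conditional-logit and penalized-Newton solvers use step-halving line
  searches; log-sum-exp stabilization throughout.
- Percentile trims use linear-interpolation empirical quantiles; trims
  need ≥ 20 values.
- A covariate constant within all strata is non-identifiable: the fit
  is returned flagged (non-converged) at the null likelihood.
- Separable conditional-logit problems (observed endpoint always
  extreme) have no interior optimum; estimates run large and the SEs
  blow up accordingly — callers see this through the Wald SEs.
- MCPs need ≥ 3 non-collinear points; degenerate polygons are errors.
- Pseudo-absence cells that starve under rejection sampling fall back
  to uniform sampling over the polygon (logged).
- On the used side, points on nodata are dropped; on the available
  side they are resampled up to 10 times to preserve the per-scene
  ratio, then dropped (the ratio contract is checked before drops).
- Per-entity RNGs derive from the master seed through stable SHA-256
  key hashing, so artifacts are reproducible independent of execution
  order.

## Known limitations

- Random effects are independent (no intercept–slope correlation); the
  ladder removes whole terms rather than correlations.
- Mixed-effects SSFs, integrated SSFs (movement-parameter
  re-estimation) and behavioural-state segmentation are out of scope.
- Season definition assumes the snow series covers the dates of
  interest in every year; uncovered dates count as not snow-free.
- The weighted-likelihood R² decomposition is heuristic under extreme
  class weights and is reported for comparability, not inference.
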