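# Methods

`uavfield` analyzes field experiments surveyed by drone. The workflow has
three stages: (1) build a predictive model linking a ground-sampled trait to
per-pixel imagery indices, (2) map the model over a fine grid of the whole
field, and (3) test experimental treatments on the dense grid of predicted
values with spatially structured mixed models. This note documents the
models, the defaults and why they are what they are, what the synthetic
generator does and does not emulate, and the numerical choices.

## 1. Candidate indices

Three per-pixel covariates are computed per survey date:

* **Canopy cover** `C_<date>`: binary vegetation mask from the RGB
  orthomosaic by excess-green thresholding, ExG = 2G − R − B, vegetation iff
  ExG > t. Default t = 0; an automatic bimodal split (Otsu) is available.
  ExG at t = 0 is the simplest defensible RGB segmentation; the strategy is
  pluggable. The quadrat/cell mean of the mask is the cover *fraction*.
* **Plant height** `H_<date>`: DSM minus an explicit ground-elevation
  layer, clamped at 0 (negative canopy height is physically meaningless;
  the masked-vs-zero distinction is preserved). No terrain model is fitted:
  callers supply ground elevation (a pre-season DSM, or a soil-percentile
  surface). Early-season height layers with canopies below the DSM noise
  floor should be excluded from the candidate set (`build_index_stack`
  exclusions).
* **NDVI** `N_<date>`: (NIR − Red)/(NIR + Red) from panel-calibrated
  reflectance, masked where NIR + Red = 0. Red/NIR bands are assumed (not
  red-edge). Panel calibration uses the gain known/mean(pre, post) from the
  two panel captures bracketing the flight; output clipped to [0, 1].

All rasters live in one local projected Cartesian frame in meters,
north-up, square pixels; there is no re-projection machinery by design.

## 2. Yield model and all-subsets AIC selection

The predictive model is Gaussian and linear (identity link) in the
quadrat-mean indices:

    y_p = b0 + Σ_i b_i x̄_{i,p} + ε,   ε ~ N(0, σ²).

Every subset of the m candidates is fitted (2^m models; guard at m > 20)
and ranked by AIC = −2 logLik + 2k with the **full** Gaussian
log-likelihood −(n/2)[ln 2π + ln(RSS/n) + 1] and k = |subset| + 2, counting
the intercept, the slopes and the residual variance. This convention is
what makes a 4-predictor model report 6 parameters. Akaike weights
exp(−ΔAIC/2)/Σexp(−ΔAIC/2) are normalized over all enumerated models; the
relative identity w_i/w_1 = exp(−ΔAIC_i/2) is denominator-free and is the
quantity verified in tests. Ties are broken by smaller k, then
lexicographic subset.

An exact fit (RSS = 0) has unbounded Gaussian likelihood; `aic()` refuses
it and the ranking places exact fits first, ordered by smaller k then
lexicographic spec, with the Akaike weight split uniformly among them
(relative likelihoods between exact fits are undefined). The minimal exact
subset therefore wins, which is what makes zero-noise recovery well-posed.

## 3. Gridding, prediction, plot comparison

The field bounding box is tiled by square cells (default 0.25 m, the scale
of an individual wheat plant) anchored at the minimum corner, half-open on
both axes. Cells are classified against the plot layout with the strictest
reading that guarantees one treatment per retained cell: touching ≥ 2 plots
⇒ eliminated; touching one plot but not fully inside it ⇒ eliminated
(plot/corridor mix); fully inside one plot ⇒ retained; otherwise outside.
Since 2.4/0.25 and 4.2/0.25 are non-integer, edge cells are eliminated by
containment rather than by snapping plots to the grid; a 2.4 m × 4.2 m plot
retains between 100 and 144 cells depending on alignment.

Pixel predictions are conditional means (the residual ε is *not* added; an
option to simulate it exists for uncertainty propagation and defaults off).
Cell values are plain averages of the unmasked pixel centers falling in the
cell — no kriging or smoothing — so cell means weighted by pixel counts
conserve the pixel total exactly; this conservation is asserted in tests at
1e-9. Membership is pixel-center-in-cell with coordinates snapped to 1e-9 m
before the floor, so boundary pixels resolve identically in the arithmetic
and polygon paths.

Per plot, the quartiles (linear-interpolation definition — the common
statistical default; nothing in the workflow pins down another choice) of
the cell predictions are compared with the manually harvested quadrat
value; a plot is flagged when the manual value falls strictly outside
[q25, q75], and the flagged percentage is reported to 0.1 %.

## 4. Mixed-model inference

Cell predictions within a plot are repeated observations of one
experimental unit, and fields carry systematic spatial variation, so all
treatment tests use the linear mixed model

    ŷ_cell = Xβ + u_row + u_plot(row) + e,
    u_row ~ N(0, σ²_row), u_plot ~ N(0, σ²_plot), e ~ N(0, σ²_e),

with random intercepts for the sowing row and the plot nested in the row
(fitted via statsmodels MixedLM; the plot term is a variance component of
within-row plot indicators). Smooth fertility trends are largely absorbed
by these two components — fitted σ²_plot routinely exceeds the generative
plot variance when a trend is present, which is the intended behavior, not
a defect. Omitting the plot intercept treats ~125 correlated cells as
independent replicates; the package exposes `include_plot=False` purely to
demonstrate the resulting type-I inflation (measured ≈ 0.39 at α = 0.05 in
the calibration design below, versus ≈ 0.05–0.07 with the intercept).

Conventions: LRTs compare ML fits and use a χ² reference with df equal to
the difference in fixed-design columns; coefficient tables come from REML
(standard practice). Cultivar analysis fits `y ~ sowing_date + cultivar`
(sowing date as a 2-level factor), finds the cultivar with the lowest
estimated marginal mean (averaging over sowing levels with equal weight),
re-codes it as the reference and reports Wald z contrasts with raw
asterisks (* < 0.05, ** < 0.01) — uncorrected by default, matching common
reporting; a Holm option exists. Trait analysis fits the four
preceding-crop traits (stem, seed, above-ground, 100-seed dry weight) and
all six pairwise interactions (11 fixed coefficients), centering traits
before forming products (this changes no LRT — they are invariant to
affine covariate maps — but decorrelates mains from interactions), and
tests each term by single-term deletion under ML. Marginal-effect surfaces
evaluate the fixed part on a focal × moderator grid with other covariates
at their means and random effects at zero.

Numerical notes: optimizers are tried in the order lbfgs → cg → powell →
nm; a result is accepted only if it converged *and* has a finite
log-likelihood — MixedLM can report convergence at a degenerate optimum
with llf = +∞ (scale → 0), which would silently zero an LRT statistic.
Variance components may legitimately sit on the 0 boundary and are
reported as such.

## 5. Synthetic experiments

No public dataset of this kind exists, so the generator produces complete
experiments with known truth. The latent yield surface (g per 1 m² quadrat
equivalent) is

    L = μ + trend + u_row + u_plot + e_pixel,

with μ = 500 g; `trend` a sum of deterministic basis fields (linear
gradients, fixed-wavelength sinusoids) scaled by an amplitude (default
40 g) — smooth, reproducible, parameter-light systematic error; row
effects (SD 25 g) over each row's band; plot effects (cultivar + sowing +
trait contribution + N(0, 15²)) inside plots; white pixel noise (SD 20 g).
Quadrat samples are midpoint-rule means of L over the 1 m × 1 m quadrat's
pixel centers plus harvest noise (SD 20 g). Magnitudes are choices of
realistic scale (10–50 g against a 500 g mean), not published values; all
are configurable.

**Index construction.** Each *true* index is an affine image of a distinct
additive component of L (the components — mean, trend bases, row field,
plot field, pixel-noise field — are partitioned round-robin among the true
indices), plus index noise in yield units (SD 10 g):
x_i = a_i + (component_i + ε_i)/β_i. Had each index been an affine image of
L itself, any two true indices would be exactly collinear at zero noise
and the minimal exact subset would be a single index; the component split
keeps y an exact linear function of the full true subset and of no proper
subset, so the zero-noise preset must recover exactly the generating
subset with zero residual. Non-true candidates are smooth random surfaces
plus noise, independent of L. Indices are *statistical surrogates*: there
is no radiative-transfer or canopy-growth model, no index saturation, no
sensor physics — passing tests demonstrate pipeline correctness, not that
real NDVI behaves linearly.

Layouts: the default is a quarter-scale field (20 m × 25 m, 20 plots of
2.4 m × 4.2 m in 4 rows, 4 cultivars) so a full pipeline run takes ~2 s;
`full_scale_config()` is the full 40 m × 50 m, 70-plot layout (56
cultivar-testing plots across 14 cultivars, 4 weedy, 4 sheet, 6
destructive-sampling plots; one quadrat per plot plus 84 adjacent-area
quadrats = 154 sampling points). Seeding: one integer seed feeds a root
`SeedSequence`; each sub-stage (layout, traits, row, plot, pixel, index
noise, nuisance, samples) draws from its own spawned child stream, so
adding a stage never perturbs earlier draws, and identical configs are
bit-identical.

A discretization caveat: quadrat means are midpoint-rule sums, so refining
the pixel size moves a noiseless quadrat mean by O(amp·(2πΔ/L)²) — about
6e-3 g at 0.1 m pixels with the sinusoidal bases — which bounds the
"resolution invariance" that can be asserted.

## 6. Calibration studies and their designs

Monte Carlo studies draw cell tables directly from the mixed-model family
(`simulate_cell_observations`), bypassing rasters — that is the correct
generative family for calibrating the inference stage and two orders of
magnitude cheaper.

* **Design**: 8 rows × 8 plots × 8 cells/plot, 4 cultivars, SDs 25/15/30.
  The plot count (64) matches a full-scale analysis and is what governs
  the χ² approximation of the cultivar LRT; at ~24 plots the ML-based LRT
  is visibly anticonservative (≈ 0.11 at α = 0.05), a small-sample fact
  about the test, not an implementation property.
* **Type-I error** (500 replicates): ≈ 0.07 with the plot intercept
  (batches of 500 have landed between 0.05 and 0.09 — the ML-based LRT
  retains mild anticonservatism even at 64 plots, and the Monte Carlo SE
  at 500 replicates is ≈ 0.011); ≈ 0.39 without the plot intercept (the
  pseudo-replication demonstration).
* **Recovery** (200 replicates): REML estimates of the grand mean and the
  three variance components fall within 3 Monte Carlo SEs of truth.
* **End-to-end detection**: the detection preset is the full-scale layout
  with one cultivar (v5) elevated by 60 g — twice the 30 g residual SD
  used throughout calibration — and trend amplitude and plot SD of 10 g,
  chosen by a prior power calculation (4 replicate plots per cultivar give
  a contrast SE near 8 g, hence z ≈ 7.5) so that a non-detection indicts
  the pipeline rather than the design. Single-realization p-values still
  range over orders of magnitude (1e-11 to 3e-3 across seeds), which is
  why the acceptance script reports a median over three realizations. The
  all-null end-to-end runs use a 64-plot calibration-scale layout where
  the null LRT is near nominal.

## 7. Known limitations

* Upstream photogrammetry (orthomosaic stitching, structure-from-motion,
  GCP bundle adjustment) is out of scope; inputs are finished rasters.
* No spatially correlated residual models (autoregressive errors); spatial
  structure is handled only through the row/plot random intercepts.
* No cross-validation or regularized/machine-learning alternatives to the
  exhaustive AIC search.
* Wald z contrasts and χ² LRTs rely on asymptotics; denominator-df
  corrections (Kenward–Roger etc.) are not implemented, and with few rows
  the row-variance estimate is noisy.
* The synthetic generator does not emulate sensor physics, index
  saturation, occlusion, georeferencing error, or missing data beyond
  masks.
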