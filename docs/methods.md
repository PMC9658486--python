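# Methods

This note documents the models implemented in `shrubvol`, the synthetic
campaign generator they are exercised on, and the numerical choices made
where the design was genuinely open. It states no empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Field and canopy-height-model geometry

A multi-stemmed shrub is measured by total height `H` (m), basal trunk
diameter `D` (cm, at soil height) and two perpendicular canopy diameters
`C1 ≥ C2` (m). Canopy area is the circle whose radius is the mean of the
two canopy radii, `A = π((C1+C2)/4)²`, and crown volume is the cone
`V = A·H/3`. The circle (not the ellipse `πC1C2/4`) is deliberate: the
area uses the *mean radius*, which differs from the ellipse whenever
`C1 ≠ C2`.

For UAV-derived data a plot is a regular canopy-height raster (or xyz point
cloud). The bare-soil reference `z0` is the mean elevation of
vegetation-free cells (the sites are flat; a least-squares plane is
available for sloping ground). Derived quantities:

* surface volume `Σ max(z−z0, 0)·cell²` — negative heights are sensor
  noise over bare ground and are clamped; the published raster tool's
  behaviour on negatives is unspecified, clamping is asserted here;
* cover area: cells **strictly** above the 0.30 m threshold ("above 30 cm"
  excludes the boundary);
* mean height: the arithmetic mean of `z−z0` over *all* valid cells,
  vegetated or not, unclamped — matching the published per-plot pixel
  counts, which include bare ground.

## The allometric model zoo

Three families over predictor subsets of {V, A, H, D} (trees, subsets up
to size 3) or {V, A, H_mean, D_mean, NrS} (stand plots, up to size 4):

    linear      Y = a + Σ bᵢ·Xᵢ             (OLS)
    ln_linear   Y = a + Σ bᵢ·ln(Xᵢ)         (OLS)
    power_sum   Y = a + Σ bᵢ·Xᵢ^cᵢ          (Levenberg–Marquardt)

yielding 42 candidate equations per tree response and 90 per stand
response. The response is never transformed, so residual sums of squares —
and therefore BIC values — are directly comparable across families and no
log-back-transform bias correction exists anywhere.

Ranking uses the Gaussian-likelihood BIC, `n·ln(RSS/n) + k·ln(n)`, with
`k` = mean-function parameters + 1 for the error variance, identically in
every family. A numerically perfect fit (RSS snapped to 0 below
`1e-12·Σy²`) receives −∞ and ranks first. The **best** model is the global
BIC minimum. The **most parsimonious** model is the BIC minimum among
models with the smallest predictor count `v*`, where `v*` is the smallest
count whose best BIC lies within ΔBIC ≤ 10 (the strong-evidence threshold;
configurable) of the global minimum. Ties break by fewer parameters, then
by family order linear < ln_linear < power_sum (simpler first).

`power_sum` fits start from a per-predictor log–log OLS of
`Y − min(Y) + ε` on each predictor plus a restart grid of shared exponents
{0.5, 1, 1.5, 2, 3} with conditionally-exact OLS for the linear
coefficients; each start is polished by Levenberg–Marquardt with an
analytic Jacobian, tolerance 1e-10, and a 200·p evaluation cap.
Non-convergent candidates are flagged and excluded from selection, never
silently kept. Standard errors come from the Jacobian at the optimum; note
that for the shifted power form the three parameters trade off strongly
over a two-decade predictor range, so exponent estimates scatter widely
between replicate datasets even when each fit is internally precise.

Mean-response confidence intervals are provided for the OLS families only
(normal theory, via statsmodels); the published whole-plot interval does
not state whether it is a mean-response or single-prediction interval, and
the mean-response reading is implemented.

## Segmented (hinge) regression and Davies' test

`y = β₀ + β₁x + β₂(x−ψ)₊` is linear given ψ, so ψ is profiled: 200 grid
points between the 5% and 95% x-quantiles, then golden-section refinement
between the neighbours of the grid minimum (tolerance 1e-9 of the search
span). A fit is flagged *degenerate* when the refined breakpoint sits at
the search boundary or when the hinge fails to improve on the plain
regression line by more than a numerical epsilon — a pure line has no
breakpoint to report.

Because ψ vanishes under the null β₂ = 0, significance uses Davies' bound:
Wald statistics for β₂ at m = 10 equally spaced candidate breakpoints
(interior 10–90% quantiles), with

    p ≤ 2·P(t_dof > M) + V·(1 + M²/dof)^(−(dof−1)/2) / √(8π),

where M is the largest |t| and V the total variation of the statistic
sequence — the t-process analogue of the Gaussian-process bound, which
keeps the test conservative at moderate sample sizes. A Wald p-value for
β₂ at the *fitted* ψ is reported as a secondary quantity; it is
anti-conservative because ψ was estimated. One breakpoint only; grouped
data are fitted per group.

## Monte-Carlo height subsampling

For sample sizes n = 1…400 per plot: draw n heights per plot without
replacement, regress harvested biomass on the per-plot mean heights,
record Pearson's r, repeat (default 10,000 repetitions; scaled-down values
in the tests) and average. Implementation: one uniform random key per
cloud point per repetition; the n_max smallest keys, *sorted by key*, form
a sample whose every prefix is itself a uniform without-replacement
sample, so prefix cumulative means deliver the entire curve from one draw
per repetition — identical in distribution at each n, with unbiased mean r.

Sample sizes are reported per 100 m² (`n·100/plot_area`). The minimum
number of observations is the hinge breakpoint of mean r against n, fitted
on a geometrically thinned copy of the curve (≈60 points, equal weight per
scale decade) and with the breakpoint free down to the smallest n: on the
raw uniform grid the plateau outnumbers the elbow ~20:1 and pushes or
boundary-degenerates the hinge. On one fixed campaign the breakpoint is
stable to a few observations across Monte-Carlo seeds at 500 repetitions;
across *replicate campaigns* of 11 plots it genuinely varies by roughly
±30%, which is a property of the study design (11 plots, one realisation),
not of the estimator — single-campaign breakpoint values should be quoted
with that caveat.

## Nutrient pools and partitioning

Elemental totals are mass-weighted sums, `E = Σ mass·concentration`
(% → /100, ‰ → /1000). Every compartment must have C and N chemistry —
there is no silent default. P was measured only for trunk and foliage
tissue; by default a compartment without P raises an error, and the
pipeline opts into summing P over the measured compartments only (so tree
P totals cover trunk + foliage, and stand tables carry no P response at
all). FBMF = FB/(FB+trunk), TMF its complement. The partitioning relation
`FB ~ a + b·BM^c` reuses the power machinery; allometric theory predicts
c ≈ 0.75, and the published "water content of 60.31%" used in the
whole-plot validation is numerically a *dry-matter fraction*
(52,847 × 0.6031 ≈ 31,872 kg), so the operation is named
`dry_mass(fresh, dry_fraction)`.

## The synthetic campaign generator

The generator emulates the harvest campaign's statistical structure; its
defaults are the study conditions (37 trees, 11 plots of 5×5 m at 2 cm
raster, scaling exponent 0.75, FBMF plateau 0.3, 15% multiplicative noise,
litter~SOM r² = 0.72).

**Trees.** H and the mean crown diameter are correlated lognormals
(log-scale ρ = 0.5); A and V are then *computed* through the geometry
module. Marginals take σ = (ln max − ln min)/5.5 so the published min–max
envelope spans ±2.75 sd, with medians set from the published means. Basal
diameter is lognormal, correlated (ρ = 0.85) with log-volume. Total mass is
`BM = 3.0·V^0.75·ε` with unit-mean lognormal ε (cv 0.15), the coefficient
calibrated to the published mean biomass. The FBMF declines linearly from
≈0.65 to the 0.3 plateau at 25 kg, then follows a shallow power decline
(exponent −0.175): the F+B *mass* nearly saturates while the trunk keeps
growing, which reproduces both the hinge at 0.3 and an emergent partitioning
exponent near 0.75. Foliage:branch splits by a Beta draw around the
published 4.1:3.3 ratio of means. Conservation (`trunk+branch+foliage =
total`) is exact by construction. The published tree volume maximum
(169.1 m³) exceeds the largest volume its own A and H maxima allow under
`V = A·H/3` (86.9 m³); the generator keeps every variable inside its
envelope rather than chase that inconsistent corner.

**Stands.** Plot canopy volumes are drawn lognormally (median e³·⁶⁵ ≈ 38 m³,
σ = 0.55) — *stratified* over the distribution's quantiles with jitter,
because field campaigns place quadrats deliberately across the
stand-development gradient; unstratified draws make the realised 11-plot
gradient, and everything downstream of it, swing wildly between seeds.
Stems (lognormal count, median 12) carry cone crowns pre-sized toward the
volume target with radii capped by the plot; all crown heights are then
rescaled so the noiseless surface volume equals the drawn volume exactly
(max-composition commutes with positive scaling — a single stem remains an
exact cone, which the tests exploit). The grid adds Gaussian sensor noise
(sd 0.05 m, centimetre-level as expected for a 2 cm photogrammetric DTM).
Reported V, A and H_mean are *measured from the noisy grid* by the geometry
module. Masses use `BM = 2.25·V^0.8·ε`; the stand mass–volume power is
shallower than the tree one because the published stand mass envelope is
much narrower, in log range, than the volume envelope. The stand FBMF
declines linearly in biomass (0.55 − 0.0017·BM, clipped to [0.20, 0.62]).
SOM and litter are a bivariate Gaussian pair with correlation √0.72,
truncated to positive values. D_mean is lognormal within its envelope,
correlated with plot volume.

**Chemistry.** One row per (unit, tissue): Normal(mean, SE) around the
published tissue table, with concentration draws resampled until positive.
Unmeasured analytes stay missing.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial autocorrelation of canopy height beyond
single crowns, measurement error in the manual tape variables,
non-conical crown shapes, within-campaign weather or season effects, and
any correlation between tissue chemistry and plant size. Oracle and
recovery tests establish that the *procedures* are correct and that the
published effect structure is recoverable at the published noise levels;
they cannot certify field accuracy of the original coefficients.

## Numerical and scale choices

* Determinism: every dataset is a pure function of (config, seed); the
  generator uses separate deterministic substreams for trees, stands and
  chemistry. Pipeline reruns are bit-identical.
* Degenerate inputs raise typed errors (`DomainError`,
  `ConfigurationError`, …) rather than returning NaNs; pipeline stages
  re-raise with a stage tag.
* Test problem sizes: 300-tree campaigns for recovery tests (200
  replicates for the acceptance checks), 500-repetition subsampling runs,
  1,000 null simulations for the Davies calibration, 2 cm rasters for the
  cone-convergence checks — each chosen as the smallest size at which the
  checked property is unambiguous.
* The CLI defaults to the published 10,000 subsampling repetitions;
  library calls take `reps` explicitly.

## Known limitations

* The parsimonious-model ladder (ΔBIC ≤ 10) is one defensible reading of
  "best with the smallest number of variables"; the original selection
  rule is not fully specified. The threshold is a config knob.
* The candidate zoo (42/90 equations) is a superset reconstruction; the
  original 27/60 candidate lists are not recoverable.
* The shifted-power exponent is weakly identified on two-decade data;
  compare exponents only with their Wald intervals in view.
* Stand crowns are cones; real canopies are rougher, so the generator's
  within-plot height variance is, if anything, conservative for the
  subsampling experiment.
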