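# Methods

This note records the model, the numerical choices and the design decisions
behind `proglacial`, and what the synthetic-data tests do and do not show.

## Soil-temperature model

Monthly mean soil temperature is a linear mixed model on seven covariates and
five interactions with a glacier random intercept (see README for the
formula). Assumptions: within the snow-free season the response is linear in
the standardized covariates; glacier-level departures are exchangeable,
normal, and independent of the covariates; residuals are homoscedastic at the
monthly scale. Months with snow-free-day frequency `sfd` ≤ 20% are excluded
(strictly) because snowpack decouples soil from atmosphere — the
`sfd_cutoff_diagnostics` helper shows the residual structure
(heteroscedasticity of residuals against fitted values) fading as the cutoff
rises, which is how the 20% default is justified on the synthetic world.

Estimation is REML (statsmodels `MixedLM`), with optimizer fallbacks
(default → L-BFGS → Powell). A fit that stops at a variance boundary (group
variance → 0) with finite estimates is accepted with a warning; genuine
non-convergence raises. R²m = var(Xβ̂)/(var(Xβ̂)+σ²_gl+σ²_res) and R²c adds
σ²_gl to the numerator (Nakagawa–Schielzeth).

* **Standardization** (mean/sd per continuous predictor, √dg included) is
  computed once on the filtered training table and frozen: validation and
  projection inputs are transformed with the stored parameters. Anything else
  would make averaged leave-one-out coefficients incoherent.
* **Depth** is treated as a continuous standardized covariate taking values
  {5, 10, 15} cm (minimal reading consistent with its interaction with sfd);
  a categorical treatment would add two columns without changing the rest of
  the pipeline.
* **Semi-partial R²** refits the model without each term and reports the drop
  in the variance of the linear predictor relative to the full model's total
  variance. Refitting (rather than zeroing the coefficient) is what makes
  variance shared with the remaining terms count for nothing — a duplicated
  column has a semi-partial R² of ~0. Bootstrap intervals resample glaciers
  (the grouping unit) with replacement and re-evaluate the fitted full and
  reduced predictors on the resampled rows; the reduced models are not
  refitted inside the bootstrap, which keeps 1000 replicates affordable.
* **Permutation importance** permutes a raw predictor column, rebuilds the
  design (interactions included, standardization frozen) and reports the mean
  of 1 − r between original and permuted population-level predictions, so a
  predictor's additive and interactive contributions are broken jointly.
* **Leave-one-glacier-out**: one refit per held-out glacier; the arithmetic,
  unweighted mean of the per-fold fixed coefficients (standardized scale) is
  the transferable vector, applied with no random effect. Non-converged folds
  are dropped from the mean with a warning.

## Radiation

Hourly absorbed shortwave radiation is evaluated at the 24 whole hours of
local solar time (longitude/15° offset from UTC) of the 15th day of a month
and summed to MJ m⁻² d⁻¹. The solar ephemeris is the Spencer/NOAA
low-precision algorithm (declination Fourier series, equation of time, hour
angle); tests pin it within 0.5° angular separation of an independent
Michalsky-style oracle.

The direct/diffuse split of the albedo-free ("net") radiation uses the hourly
clearness index Kt = downward/extraterrestrial (clipped to [0, 1], 0 at
night) and the Erbs et al. (1982) piecewise polynomial diffuse fraction:
Kd = 1 − 0.09 Kt below 0.22, a quartic in (0.22, 0.80], and 0.165 above. The
quartic rises by < 0.001 just below its upper boundary; the monotonicity test
carries a 0.01 tolerance for that reason. Kd and (1 − Kd) multiply net
radiation to give the diffuse and direct components (conserving their sum to
machine precision).

Terrain factors: per-cell horizon angles are ray-marched in 24 azimuth
sectors (step = one cell, default search radius 5 km; the synthetic worlds
use 25 cells) using the true distance to each rounded sample cell; the sky
view factor is cos²(slope/2) × mean over sectors of cos²(horizon). A cell is
shaded when solar altitude falls below the horizon angle of the sun's sector.
The absorbed flux is: direct × max(0, cos i)/max(ε, sin h) (zeroed when
shaded or the sun is down; ε = 10⁻³ caps low-sun amplification), plus diffuse
split into a circumsolar part (Hay anisotropy index = direct beam /
extraterrestrial, routed like the beam and zero at night) and an isotropic
part weighted by the sky view factor, plus terrain-reflected radiation
albedo_adjacent × (1 − svf) × net. Only the adjacent-surface albedo enters:
the "net" input is already albedo-free and is not reduced again for the
target surface.

## Terrain and snow

Slope/aspect use Horn's 3×3 kernel with odd-reflection padding, which makes
border cells behave as one-sided differences and planar ramps exact
everywhere; aspect is degrees clockwise from north, flat cells carry the
sentinel 180° (equivalent at slope 0). Lapse-rate downscaling refers each
coarse temperature to the mean fine-DEM elevation of its coarse cell, which
makes the shift mean-preserving (the reference elevation of coarse products
is otherwise undefined). Distance to the glacier is the 8-connected
chamfer/geodesic lattice distance (cardinal = cell, diagonal = √2 cell) from
cells inside the rasterized outline, matching grid-distance tooling semantics
rather than Euclidean distance.

Snow detection: a day is snow-covered for the sensor when its diurnal range
(valid only with ≥ 4 records/day) is strictly below the threshold, and for
the satellite when fractional cover ≥ 40% (snow-free strictly below). The sfd
denominator is the number of *observed* days (valid ranges, or cloud-free
images) rather than calendar days; a `calendar_denominator` switch provides
the other reading. Calibration scans thresholds {0.5…3} °C × minimum images
{1, 5, 10, 15, 20} and selects the combination maximizing wR², ties broken by
the smaller wRMSE (the selection rule itself is a package choice; the scan
grid is fixed). Season duration counts snow-free days per calendar year with
nearest-observation filling of cloud gaps, averaged over a period's years.

## Weighting

Weights are 1/(G·M·n) per observation, with G the glaciers (or 1000 m
single-linkage station clusters, when no glacier level exists) in the
observation's region, M the *non-empty* sfd decile categories of its glacier,
and n the observations in its (glacier, category) cell: regions then sum to
1, glaciers to 1/G, cells to 1/(G·M) exactly. The third level of the scheme
is implemented as an equal share per non-empty category within each glacier —
the only normalization consistent with regions summing to 1; empty categories
receive no reallocated mass. wR² is the coefficient of determination of a
weighted regression of observed on predicted (so a constant bias does not
reduce it); wMAE and wRMSE are weighted moments of the raw errors, and a
constant observed or predicted vector makes wR² undefined (NaN).

## Projection and buffering

Projection applies a coefficient vector (normally the LOO mean) to monthly
covariate rasters with the frozen standardization, at 5 cm depth, masking
cells with sfd ≤ 20% or missing covariates; no random effect is added.
Sampling follows a stratified equal-area design: grid cells (default 50 km;
an equal-area Mollweide forward projection is provided for geographic
coordinates), five disjoint distance-from-glacier bands (defaults
0–100 … 2900–3100 m), two random raster cells per band without replacement,
and whole cells only — a grid cell that cannot fill every band is dropped.

ΔT is the late-period minus early-period mean over the season's months,
excluding months masked in either period pairwise from both means (seasons:
DJF/MAM/JJA/SON calendar months; month means are unweighted by day count).
T_var is q90 − q10 (type-7 linear-interpolation quantiles, used consistently
for all quantiles in the package, including the 5%/95% monthly extremes) of
cell values whose centers fall within 250 m; a buffer reduced to the single
host cell has zero spread by convention, 2–4 cells are reported missing.
T_bp = T_var/ΔT keeps ΔT's sign; |ΔT| < 10⁻⁶ °C yields a +∞ sentinel classed
">10" (any spatial variability trivially exceeds no change). Classes are
(−∞,−10], (−10,−1], (−1,1], (1,10], (10,∞). The extrapolation audit reports
the percentage of projected covariate values (snow-free cells only, since
only those are projected) strictly outside the training range, with dg
compared on the √ scale.

## The synthetic world

The generator is the package's test bed and defines its study conditions:
26 glacier forelands × 7 stations × 24 months by default (mirroring the
field study's 26 forelands and ~6.7 stations each), one mountain patch per
glacier on a shared 30 m grid (`dem_size` = 32 cells per patch), glaciers as
circular outlines around each summit with a slightly retreated second epoch,
and stations scattered over the foreland. Glaciers rotate through three
latitude bands (Northern 47°, Inter-tropical −8°, Southern −44°) that double
as regions, giving the weighting scheme its levels and the buffering analysis
its bands.

Macroclimate is a band-specific seasonal cycle (sea-level mean 16–18 °C,
amplitude 10 °C extratropical / 1.5 °C tropical, opposite-phase hemispheres)
plus a linear trend (default 0.5 °C/decade), lapse-rate-downscaled to the
DEM. Snow follows the rule "snow when the downscaled monthly mean < 0 °C",
with 10% per-day jitter — this couples sfd to elevation and season exactly
the way the model exploits. Radiation forcing is clearness index 0.55 ± 0.15
by season with net = 0.8 × downward, run through the full terrain radiation
path. Monthly soil temperature is generated from natural-scale coefficients
(all nonzero, so each is individually recoverable; macroclimate coupling
0.55 + 0.005·sfd reaches 1.0 at sfd = 90%, making the projected ΔT equal the
imposed trend at snow-free cells) plus a glacier intercept (sd 1 °C) and a
monthly residual (sd 1 °C); the equivalent standardized coefficient vector is
derived exactly and stored. Snow-decoupled months (sfd ≤ 20%) instead hover
near 0 °C, giving the cutoff diagnostics something real to detect.

Hourly traces add a diurnal sinusoid (amplitude 5 °C snow-free, 0.2 °C under
snow — the insulation signal) and AR(1) noise (lag-1 r = 0.6) whose marginal
sd is 5% of the day's amplitude: an insulated sensor is quiet at every time
scale, so the diurnal-range snow test stays exact while traces remain
textured. Monthly sfd truths are stored as 100·k/n in exactly the arithmetic
the detectors use, so noise-free recounts match bitwise. Satellite cover
draws uniformly in [40, 100) on snow days and [0, 40) otherwise, with
independent cloud gaps. Glacier retreat *within* the projection window is not
modelled (both periods use the most recent outline for distance), so the
closed-loop ΔT isolates the macroclimate trend.

What the synthetic world does **not** emulate: real glacier dynamics or
geography, soil moisture and thermal inertia, longwave radiation, vegetation
height, spatially correlated cloud cover, sensor drift, or irregular logging
schedules. Passing tests therefore demonstrate the pipeline's internal
correctness and statistical calibration under its own assumptions — not that
the model is adequate for any particular real foreland.

## Problem sizes and determinism

Default test and acceptance scales are chosen to keep the full suite and the
acceptance script at a few minutes on one CPU: recovery uses 20 replicate
study-sized worlds (≈ 2900 retained rows each); other stages use 6-glacier,
one-year worlds with 24-cell patches and scaled-down sampling bands
(0–430 m, one grid cell per patch). Every random draw flows from a single
seed through named substreams (terrain, stations, intercepts, snow, residual,
trace, satellite, tree cover), so each artifact is reproducible in isolation;
identical configs produce bitwise-identical worlds, traces and tabular
outputs. Interval coverage in the recovery check is pooled over coefficients
and replicates (260 intervals), the stable way to test calibration at this
replicate count.

## Known limitations

* The diffuse-fraction correlation predicts from Kt alone; separation models
  with additional predictors (solar elevation, persistence) would shift Kd by
  a few percent in broken-cloud regimes.
* `MixedLM` Wald intervals are z-based; with 26 glaciers the intercept's
  interval is slightly anti-conservative compared to a t-based one.
* The horizon ray-march samples nearest cells along each azimuth; very narrow
  terrain features between rays can be missed at large search radii.
* Semi-partial bootstrap intervals condition on the point-estimate
  coefficient vectors (see above); fully refitted bootstrap intervals would
  be wider for strongly collinear terms.
* The equal-area sampling grid is exact on projected (meter) rasters; for
  geographic rasters the provided Mollweide forward transform must be applied
  to coordinates first.
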