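# Methods

This note documents the models implemented in `ecosens`, the defaults
that matter, what the synthetic scenes do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Scope and data model

The package analyses monthly raster cubes (`MonthlyStack`: time × row ×
col, calendar index, nodata mask, north-up geotransform). NDVI is
dimensionless in [−1, 1], air temperature in °C, precipitation in
mm/month, LST in Kelvin, TVDI dimensionless in [0, 1]. Stacks are stored
as multiband TIFF with NaN nodata, a JSON description tag (geotransform,
variable, time index) and a `*_time_index.csv` sidecar; the sidecar wins
on read and shuffled rows are restored to chronological order. The
package does not reproject between coordinate systems and does not read
native satellite archive formats; inputs are assumed co-registered.

## Preprocessing

**Savitzky–Golay smoothing** of NDVI time series uses window 7
composites, polynomial order 2 by default — a common choice for 16-day
vegetation-index series. Edge handling defaults to polynomial fitting on
the terminal window (`interp`), which keeps the filter exact on
polynomials of degree ≤ order over the entire series; `reflect` and
`nearest` padding are selectable. The filter targets *sub-monthly*
composites. The pipeline therefore leaves it off for monthly inputs
(`sg_enabled=False`): a 7-month window applied to monthly series
measurably inflates the lag-1 memory coefficient (α 0.5 → ≈0.8 on
synthetic scenes) by smearing information across adjacent months.

**Maximum-value compositing** takes the per-pixel maximum over
non-missing values per month or per year; an all-missing group becomes
nodata. Annual maximum NDVI feeds the trend maps.

**DCT-PLS gap filling** of LST scenes solves the penalized least-squares
smoother in the discrete-cosine basis: filter factors 1/(1 + s·λ²) with
λ the Laplacian eigenvalues of the grid graph. Missing cells carry zero
weight and are iterated to a fixed point; the roughness parameter s
minimizes the GCV score over 61 log-spaced candidates in [1e−6, 1e6].
Numerical choices: the convergence tolerance is 1e−6 *relative to the
observed data range* (scenes are in Kelvin; an absolute tolerance would
be scale-dependent), the search runs from the smoothest candidate
downward with gaps warm-started from the previous solution, candidates
far from the GCV minimum are capped at 50 iterations, and the selected s
is re-solved to full convergence (cap 500 iterations, error past it).
Near-identity filters (tiny s) converge slowly but also diverge in GCV,
so they never win the search. Gap filling is applied per 2-D monthly
scene; the transform machinery is dimension-generic.

**Resampling** between the ~1 km LST grid and the ~250 m NDVI grid is
nearest-neighbour block replication (factor 4 for the emulated
products), with the geotransform cell size scaled accordingly.

**Low-cover exclusion**: for each pixel and calendar month, the month is
excluded when its across-years mean NDVI is below 0.1 (strict
less-than). The rule is applied per pixel per calendar month — the
monthly climatology reading of "mean NDVI".

## TVDI

Per monthly scene, the NDVI axis is binned (default width 0.02); bins
with at least `min_count` joint-valid pixels (default 10, smaller for
small test scenes) contribute their maximum LST to the dry edge and
minimum to the wet edge. Both edges are ordinary least-squares lines in
bin centers; a wet fit with slope above +5 K/NDVI falls back to the
constant scene minimum. Edges are fitted per scene rather than pooled
because the dry edge drifts with season. TVDI is the normalized position
(LST − wet)/(dry − wet), clipped to [0, 1] with clip counts logged;
pixels where the fitted edges touch or invert become nodata. Fitting
lines through bin extrema against bin *centers* biases the fitted dry
edge upward by about slope × half-bin-width (≈0.4 K at the defaults);
pixels on the *fitted* edges evaluate to exactly 0 and 1.

## Trend mapping

Mann–Kendall: S is the signed pair count; Var(S) uses the tie
correction Σ t(t−1)(2t+5) over tie-group extents; Zc applies the
standard continuity correction (S−1 for S>0, S+1 for S<0). The
five-way classification (significant/non-significant
increase/decrease, no trend) uses |Zc| against 1.96 and the sign of Zc.
The Theil–Sen slope is the median of all pairwise slopes. Annual series
come from yearly maximum compositing; missing years are dropped
pixel-wise with n adjusted, and pixels with fewer than 4 years become
nodata. No serial-correlation correction (pre-whitening) is applied to
the pixel tests. Area fractions are reported per trend class, per β band
({β≤0, 0<β<0.001, 0.001≤β≤0.002, β>0.002} per year) and per mean-NDVI
level (breaks 0.1/0.2/0.4/0.6/0.8); each partition sums to 1 over valid
pixels.

## Sensitivity and VSI

**Standardization.** Each pixel's monthly series is de-trended by its
full-series OLS line, then z-scored per calendar month across years.
Used months therefore have exactly mean 0 and (sample) SD 1. A calendar
month that is constant after de-trending gets z = 0 but is flagged
unused — it carries no information and would break the unit-variance
contract. Fewer than 3 usable years also disqualifies a month.

**AR1 regression.** NDVI_t on (NDVI_{t−1}, Tem_t, Pre_t, TVDI_t),
least squares without intercept (all variables are zero-mean by
construction). Only lag pairs with both months usable enter — pairs are
never bridged across an excluded month. Pixels need at least 36 usable
pairs (a stable 4-parameter fit); rank-deficient designs become nodata
and are counted. Standard errors come from the usual OLS covariance.

Note on scales: the regression is fitted on per-month re-standardized
series. Coefficients of a generative recursion are recovered on their
native scale only when the generated anomalies themselves have unit
variance; otherwise the climate coefficients absorb the anomaly SD. The
synthetic module therefore exposes its raw anomaly/driver surface
(`truth_standardized`) for exact-scale recovery tests, while the
pipeline's α (scale-invariant under this re-normalization) is directly
comparable to the generative value.

**PCR weights.** Principal components of the four standardized
predictors (the lag term included by default; a 3-variable climate-only
mode is selectable); NDVI_t is regressed on the component scores, and
components with coefficient p < 0.1 (t-tests of the score regression)
are kept. Each variable's importance is |Σ loading × coefficient| over
kept components. If no component is significant the pixel's weights are
zero and flagged. With mutually uncorrelated unit-variance predictors
and all components kept, importances reduce to |OLS coefficients|.

**Weight rescaling** is global: one min and max over all three climate
importances and all pixels maps to [0, 1] (so the single largest
importance on the map becomes exactly 1), followed by per-pixel
normalization to sum 1 so the VSI is a convex combination. The
unnormalized mode is selectable; a degenerate global range yields equal
thirds.

**Variability scores.** Per pixel, the mean and variance of the
de-trended monthly series — de-trending here removes the slope component
but keeps the series mean, otherwise the mean–variance relationship
would be vacuous. Across pixels, variance is regressed on mean by OLS;
the residual, min-max standardized to [0, 100] (clipped against
floating-point overshoot), is the score. A degenerate residual range
maps all pixels to 50. All four variables are scored on the months the
NDVI analysis uses, so numerator and denominator of each ratio cover the
same season.

**Sensitivity scores** are log10((V_NDVI + 1)/(V_climate + 1)); the +1
offset on both scores avoids log 0 and division by zero and is a
documented knob.

**VSI** is the weighted sum of the three sensitivity scores, then
min-max rescaled to [0, 100] over valid pixels; the raw weighted sums
are also emitted. The final rescale is forced so the index always spans
its stated relative scale.

**Memory classes** use half-open intervals: α < 0.4, [0.4, 0.6),
α ≥ 0.6; boundary values go to the upper bin. **Gradient regressions**
of α on growing-season (default May–September) mean covariates use
α ~ 1 + ln x for NDVI and TVDI (non-positive covariates dropped and
counted) and α ~ 1 + x + x² for precipitation and temperature,
reporting coefficients, R² and the overall-F p-value.

## Synthetic scenes

The generator emulates a mid-latitude arid-basin study: an elevation
gradient organises all spatial base fields (greener/wetter/cooler
"mountain" rows, LST negatively tied to the vegetation base so a dry
edge exists); each climate variable is base + cosine seasonal cycle
(July peak) + linear trend + white noise; precipitation is clipped at
zero. NDVI anomalies follow the same lag-1 recursion the pipeline fits,
driven by the per-month standardized climate anomalies, with the
moisture driver either TVDI computed scene-by-scene from the generated
LST and the NDVI climatology (default — closing the loop the regression
assumes) or the LST anomaly directly (useful on tiny grids where edge
fitting lacks pixels). Anomalies are spun up from the stationary
distribution and re-embedded as climatology + anomaly × climatological
SD, clipped to [−1, 1]; winter climatology at sparse pixels drops below
the 0.1 threshold so the exclusion rule is exercised. LST gaps are
injected by exact-count uniform sampling (so tests can assert counts),
with the withheld truth returned for gap-fill scoring. Everything is a
deterministic function of the seed.

Default study conditions: 19 years (228 months) from 2000, coefficients
(α, β, γ, δ) = (0.5, 0.2, 0.3, −0.2), innovation SD 0.3, 10% LST gaps.
The default analysis grid is 30 × 30 (900 pixels; the acceptance run
completes in well under a minute) and the recovery checks use ~200
pixels — large enough for stable across-pixel regressions, small enough
to keep the suite fast.

Not emulated: cloud/QA contamination and its seasonal structure,
orography beyond a linear gradient, spatially correlated observation
noise, land-cover heterogeneity, human disturbance. Passing tests
demonstrate the estimators recover known structure under the stated
stochastic model — not that real MODIS/station archives satisfy that
model.

## Known limitations

- The per-month re-standardization scale effect above means climate
  response coefficients are comparable across pixels but not directly
  to a generative model whose anomalies are not unit-variance.
- PCR p-values are nominal t-tests on component scores; no multiplicity
  correction is applied across components or pixels (matching the
  procedure the pipeline reproduces).
- Min-max rescalings (weights, variability, VSI) are map-relative:
  scores are not comparable across runs on different domains.
- The wet edge of TVDI is a fitted line with a constant-minimum
  fallback; physically-based wet-edge estimates are out of scope.
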