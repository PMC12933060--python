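# Methods

`wetlandflux` implements a data-driven upscaling chain for wetland greenhouse
gas exchange: multiscale eddy-covariance (EC) observations — fixed towers and
midday airborne transects — are paired with daily 7-band surface reflectance
to train bootstrap random-forest ensembles that predict daily CO2 and CH4
flux per 500-m pixel with uncertainty, feeding CO2-equivalent accounting,
nonparametric trend mapping, and driver attribution. Everything runs against
a synthetic landscape generator with known ground truth, so each stage is
testable without any external data.

## The synthetic landscape

The generator emulates a tidal-to-freshwater wetland gradient (mangrove,
saltmarsh, freshwater marsh, swamp, upland, open water) of the kind found in
large managed coastal wetland complexes.

**Habitat mosaic.** A Gaussian-smoothed random field plus a west-to-east
gradient is cut at the cumulative class-fraction quantiles, giving contiguous
patches whose realized fractions match the request up to ties, ordered
coastal (water, mangrove) to inland (upland). Default fractions: mangrove
0.20, saltmarsh 0.10, freshwater marsh 0.30, swamp 0.15, upland 0.10, water
0.15.

**Reflectance.** Each habitat has a baseline 7-band spectrum (blue, green,
red, NIR1, NIR2, SWIR1, SWIR2, all in [0, 1]); water has NIR1 = 0.03, darker
than every land class, which is what makes histogram water masking work. An
annual cosine (period 365.25 d, greenness peaking in the wet season) and
i.i.d. Gaussian noise (sd 0.01) are added, and disturbance events depress
the NIR bands inside a circular footprint with linear recovery over
`recovery_days`. A QA mask randomly removes `qa_dropout_frac` of pixel-days
(default 0.36, the reduction rate typical of daily BRDF-adjusted reflectance
after quality and cloud filtering).

**True fluxes.** Daily CO2 flux (µmol m⁻² s⁻¹, negative = uptake) is affine
in NIR1 per habitat; daily CH4 flux (nmol m⁻² s⁻¹) is affine in the
NIR1−SWIR1 wetness proxy. Coefficients are set so habitat means at baseline
reflectance are mangrove −4.0 < swamp −3.0 < saltmarsh −2.5 < freshwater
marsh −2.0 < upland −1.5 for CO2, and freshwater marsh 150 ≫ swamp 60 >
saltmarsh 40 > mangrove 25 > upland 5 for CH4 — the canonical pattern of
strong CO2 uptake in mangroves and methane hotspots in freshwater marsh.
Gaussian process noise (sd 0.6 µmol / 18 nmol) is added daily.

**Towers.** Eight towers (2 mangrove, 2 freshwater marsh, 1 saltmarsh,
2 swamp, 1 upland) emit 48 half-hourly records per day per gas. The CO2 diel
cycle is a half-sinusoid daylight drawdown scaled so that, by construction,
daily mean = a·(midday mean) + b exactly at zero noise, with defaults
a = 0.27, b = 0.58 µmol m⁻² s⁻¹ — an affine midday-to-daily relation that
ordinary regression recovers to machine precision. CH4 is flat through the
day. Half-hourly noise (sd 1.5 µmol / 30 nmol) and random gaps
(`gap_rate` = 0.1) are added.

**Flights.** Midday transects (timestamps restricted to [10:00, 14:00)) fly
straight grid rows at 100 m s⁻¹ with 1-Hz sampling, ~5 samples per 500-m
pixel, carrying the pixel's true midday flux plus noise (sd 2 µmol /
40 nmol). The plan re-flies a fixed set of grid-spanning flight lines
(2 × transects_per_day lines, alternating halves) roughly ten days per year
across wet and dry seasons, mirroring campaigns whose seasonal deployments
repeat the same flight tracks; revisiting matters because temporal
aggregation of the validation depends on pixels being sampled on several
days.

## Ingest

Tower days survive only when strictly more than 80% of the 48 half-hours are
present; the daily SD is the descriptive n−1 spread of the half-hours (not a
standard error). The midday→daily CO2 conversion y = a·x + b is refit per
run by OLS on tower (midday mean, daily mean) pairs; uncertainty propagates
first-order with a, b, x independent: se_y² = x²·se_a² + se_b² + a²·var_x,
where var_x is the squared midday sample SD. CH4 needs no conversion (daily
mean = midday mean). Airborne samples inside the midday window are pooled —
across flights — per (pixel, date, gas) before the mean/SD/n are computed.
Tower and airborne records for the same pixel-date are both kept as separate
training rows; sources are pooled, never averaged.

## Reflectance covariates

QA masking combines by AND (idempotent). Water detection uses Otsu's
criterion on the NIR1 band: candidate thresholds are the interior edges of
256 equal-width bins over the observed range; the between-class variance
w0·w1·(µ0−µ1)² is computed exactly from the values, with ties broken toward
the lower threshold. The mask can be built per day or per monthly composite
(per-pixel monthly mean NIR1, one mask applied to all days of the month —
the default, since composites are robust to QA gaps). A separability
diagnostic (fraction of variance explained by the split) below 0.75 triggers
a unimodal-histogram warning, i.e. "no distinct water class". Covariate
sampling attaches the 7 bands to each observation and drops rows whose
pixel-day is masked, logging the retention fraction.

## Upscaling ensemble

Per gas: a deterministic 80/20 split stratified by source; grid search over
hyperparameters (documented default grid: trees {100, 300} × mtry {2, 3, 5} ×
min-leaf {1, 5, 20}) minimizing mean 10-fold CV RMSE on the 80%; then a
bootstrap ensemble (default 100 members) in which each member is a random
forest fit on a with-replacement resample of the training rows, the same
size as the training set. Tuning happens once, before ensembling.
Predictions report the ensemble mean and the across-member n−1 SD (zero iff
the members agree); masked pixel-days carry no prediction. Validation pairs
held-out observations with predictions and reports r² (squared Pearson
correlation, 1:1 style), a 1−SSE/SST variant, RMSE and MAE at daily,
monthly, seasonal (wet = May–October; dry = November–April, with
November–December assigned to the following year's dry season so seasons are
contiguous blocks) and annual scales, averaging obs and pred within
(pixel × period) before scoring.

A composition caveat: pooled-source r² is not guaranteed monotone across
aggregation scales even when each source's curve is. Towers contribute few
pixels with many observations (their groups shrink from ~280 monthly to ~56
seasonal), airborne transects many pixels with few revisits (singleton-heavy
groups at every scale), so the pooled mix shifts toward the noisier source
as periods widen. On the default scenario the per-source curves rise
monotonically with aggregation and every aggregated scale explains at least
as much variance as daily; the pooled curve can dip slightly between monthly
and seasonal for exactly this reason.

## Accounting

Annual pixel mass = annual-mean flux × molar mass (44.01 / 16.04 g mol⁻¹) ×
pixel area (2.5×10⁵ m²) × 3.1536×10⁷ s, with CO2 in µmol (10⁻⁶ mol) and CH4
in nmol (10⁻⁹ mol); signs are preserved (negative = removal). MMT and Tg are
the same unit (10¹² g). CO2-equivalents use the 100-year global warming
potential for nonfossil methane, GWP = 27.0: CO2eq = CO2 + 27·CH4, exactly
linear and therefore partition-additive over any unit map. The offset ratio
is 100·GWP·CH4/|CO2| where the CO2 term is net uptake, undefined (NaN)
otherwise. Unit aggregation sums each ensemble member over the unit before
taking the across-member mean ± n−1 SD, preserving within-member spatial
covariance; interannual SDs are reported separately where relevant.

Trends use the Mann-Kendall test (S = Σ sign differences; tie-corrected
variance; tau-a without ties, tau-b with ties; two-sided normal
approximation with continuity correction) and Sen's slope (median pairwise
slope), per pixel and per unit, requiring at least four annual layers.
Scenarios shorter than four complete years skip the trend stage.

## Attribution

Unit summaries hold habitat percent areas, centroid distance to the western
shore (km), disturbance indicators (percent ghost forest = mangrove inside
the hurricane footprint; percent burned = fire footprint — synthetic
stand-ins for mapped damage products, as flagged in their construction), and
mean fluxes/trends from the accounting stage. PCA eigendecomposes the
correlation matrix; components are ordered by eigenvalue with the
largest-|loading| element of each made positive. Iterative pruning removes
the variable with the smallest maximum |loading| across the leading
components that explain 70% of variance (so a noise variable cannot shelter
in its own trailing component), refitting each round, while that maximum is
below the threshold (default 0.3); the flux responses are protected.

The path model is a recursive system over observed variables, estimated
equation-by-equation by OLS on standardized variables (which coincides with
maximum likelihood for recursive systems); it reports standardized
coefficients, SEs, two-sided p-values (starred at 0.05 / 0.005 / 0.0001),
per-equation R², and indirect effects as sums over directed paths of
products of path coefficients. Cycles and collinear predictor sets
(condition number > 10⁸) are rejected.

## Problem sizes and numerical choices

The default demonstration scenario is 40×40 pixels × 3 years with a
20-member ensemble, weekly prediction sampling (`date_stride = 7`), and a
compact tuning grid ({100} trees × mtry {2, 3} × min-leaf {5, 20}), chosen so
the complete pipeline — simulation through attribution — runs in a few
minutes on a single core; the full default grid and 100 members remain the
library defaults. The analysis scripts use a 4-year variant (2020–2023) so
the trend stage is exercised. Sample SDs use n−1 everywhere (daily spread,
airborne pooling, ensemble uncertainty, unit aggregation) for consistency.
Random state flows from a single seed through named SeedSequence streams per
stage; no stage consumes OS entropy, and a rerun with the same configuration
reproduces identical manifests and checksums.

## What passing tests do and do not show

The generator is deliberately idealized: fluxes are exact (noisy) functions
of same-day reflectance, the diel cycle is a fixed shape with an affine
midday-daily link, QA dropout is spatially independent, and disturbances are
circular with linear recovery. Passing recovery tests therefore demonstrates
that the pipeline's machinery is correct and unbiased under its own
assumptions — not that reflectance alone carries this much flux information
in real wetlands, where lags, footprint mismatch, meteorological drivers and
spatially correlated cloud masks all degrade skill. Regional mass budgets
from the synthetic domain are orders of magnitude smaller than any real
landscape's and are meaningful only relative to the generator's truth.

## Known limitations

- No map projection or georeferencing beyond a pixel-center affine grid.
- The water mask is purely spectral (NIR1 threshold); no static land/water
  product is consulted.
- Trend p-values assume serial independence of annual values.
- Path-model standard errors ignore spatial autocorrelation among units.
- Latent-variable structural models and model-fit indices are out of scope.
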