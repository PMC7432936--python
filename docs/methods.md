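# Methods

This note documents the models, the synthetic world, the numerical choices
and the limits of what a green test establishes.

## The LUR procedure

The package implements the harmonized land-use-regression protocol of the
large European multi-city exposure studies.

**Predictor grid.** 53 candidate variables, each with an a-priori expected
direction of effect ("sign prior") fixed before any fitting:

| group | radii (m) | count | prior |
|---|---|---|---|
| major/minor road length in buffer | 50, 100, 300, 500, 1000 | 10 | + |
| distance to nearest major/minor road | — | 2 | unconstrained |
| LDMV/HDMV daily counts in buffer | 50, 100, 300, 500, 1000 | 10 | + |
| industrial / urban / harbor area in buffer | 100, 300, 500, 1000, 2000 | 15 | + |
| open-space area in buffer | 100, 300, 500, 1000, 2000 | 5 | − |
| population in buffer | 100, 300, 500, 1000, 2000 | 5 | + |
| elevation | — | 1 | − |
| distance to coastline | — | 1 | unconstrained |
| wind-direction fraction toward 3 industries | — | 3 | + |
| regional annual wind speed | — | 1 | unconstrained |

Distance-to-road variables are plain nearest-feature distances (a "buffer on
a distance" is ill-defined), and their priors are deliberately unconstrained:
a distance variable can legitimately enter with either sign depending on
whether the dominant source is local or regional. Traffic counts sum the
daily count of each road *feature* once if it intersects the buffer with
positive length (a tangent contact does not count); a length-weighted variant
is not the default because intersection counts, not vehicle-meters, are what
count stations report.

**Selection.** (1) start from the intercept-only model; (2) tentatively add
each remaining candidate and keep the one maximizing adjusted R² among
additions where the new coefficient obeys its prior and no entered
coefficient flips against its own; accept only if adjusted R² improves by
more than `gain` (default 0.01, the conventional threshold); (3) repeat
until no acceptable addition; (4) prune: iteratively drop the
highest-p coefficient with p ≥ 0.1; (5) collinearity screen: while any
VIF ≥ 5, drop the worst predictor and refit, then re-prune; (6) a final
guard drops any predictor whose sign was flipped by the removals. Ties in
step choice break by higher adjusted R², then lower RMSE, then predictor
name — deterministic under column permutation. Every emitted model asserts
its own contract at construction (signs, p < 0.1, VIF < 5); an
intercept-only result is valid output, flagged in the selection log, which
records every accept/reject decision and replays to the final model.

**Inference.** OLS with conventional t-based standard errors (two-sided p on
residual df); R², adjusted R², RMSE = √(SSE/n). VIF_j = 1/(1 − R²_j) of
column j on the rest.

**Validation.** LOOCV re-estimates the *coefficients* of the developed model
on each n−1 subset and predicts the held-out site; LOOCV R² = 1 − SSE/SST
(not a squared correlation — it can be negative, and penalizes
anti-correlated predictions). Selection is not re-run per fold, matching how
a finished model is usually validated; this is optimistic, and an
`honest_loocv` mode that repeats the whole search per fold is available (off
by default).

**Screening threshold (documented tuning).** At n ≈ 40 sites with 53
candidates, the conventional gain of 0.01 demonstrably overfits: on pure
noise the search retains >1 predictor in ~94/100 seeded runs, and with three
true predictors at R² ≈ 0.8 it recovers exactly the true set in only ~7/100
runs (it keeps the truth plus noise variables whose apparent adjusted-R²
gain exceeds 1%). The acceptance suite therefore verifies the screening
properties — ≥80% exact recovery, ≤20% multi-predictor false selection on
noise — at a tuned gain of 0.10; the pipeline default remains the
conventional 0.01. A sweep (gain → exact recovery / null multi-predictor per
100 seeds): 0.01 → 7/94, 0.03 → 65/91, 0.05 → 87/79, 0.075 → 92/38,
0.10 → 88/18.

## QA and temporal adjustment

LOD = mean + 3·SD of the field blanks (standard convention; sample SD,
ddof 1). Duplicate agreement is the squared Pearson correlation of paired
primary/duplicate values (undefined and flagged under zero variance).
Stolen/outlier records are excluded and itemized; below-LOD records are kept
but flagged (exclusion configurable).

Adjustment: `adjusted = mean_i [ site_i − (ref_i − ref_scope_mean) ]`, where
`ref_i` is the reference period with maximal calendar overlap (ties → the
earlier period) and the scope mean is the reference annual mean, or the
reference season mean for seasonal scopes (the seasonal analog is this
package's consistent extension of the annual rule). The correction is exact
whenever the site series is parallel to the reference series; under
*multiplicative* seasonality (the default truth), spatially varying
amplitudes break parallelism and the adjustment is only approximately
unbiased — this is a property of the method itself, not of the
implementation, and the exactness/unbiasedness tests therefore run the
simulator in its additive-seasonality mode, which is the method's stated
premise.

## The synthetic world

A 20 × 30 km planar city in meter coordinates (no geodesy anywhere): the
coastline is the east edge; the southern region holds the harbor polygon,
six industrial zones and three point sources (two refineries, a paper mill);
the north is residential; an open-space band separates them. A coastal
highway, east–west arterials and a heavy-duty harbor corridor carry
20,000–60,000 vehicles/day (HDMV share up to 30% on the harbor road); minor
roads carry 300–6,000. Elevation rises from the coast at 7.5 m/km plus
gentle hills; population density is ~2,500 /km² in urban polygons against a
background of ~80. Hourly winds are a two-component von Mises mixture along
the coast axis (NE/SW), in meteorological FROM-degrees. Rasters extend 2 km
past the bounds so 2-km buffers at coastal receptors stay covered.

**Ground truth.** Per pollutant: concentration = seasonal multiplier ×
(baseline + Σ coefficient × generating field) + spatially correlated noise,
where the generating fields are named variables of the predictor grid with
prior-consistent signs (e.g. NO₂: major-road length, harbor and industrial
area, population positive; elevation negative). Baselines sit at the annual
level (NO₂ 13, SO₂ 2.4, PM₁₀ 30, PM₂.₅ 9 µg/m³ before covariates) and the
seasonal multipliers reproduce the emulated campaign's contrast —
winter/summer ratios ≈ 2.5 (NO₂), 1.5 (SO₂), 2.5 (PM₁₀), 2.0 (PM₂.₅), with
spring near the annual level and autumn closing the four-season mean to ~1.
Measurements add a shared city-wide per-period deviation (temporal noise), a
per-record measurement error, and a 2.5% dropout rate flagged stolen or
outlier; the reference site contributes 26 contiguous fortnights plus one
blank and one duplicate per pollutant per period.

**Spatial noise.** A Gaussian random field with exponential covariance
(marginal SD 0.45–4 µg/m³, range 3.5–4.5 km by pollutant), simulated exactly
by Cholesky factorization on a 25 × 35 node grid and bilinearly interpolated.
The marginal SD is exact at grid nodes; between nodes interpolation shrinks
it by up to ~8% at the default resolution (a standard artifact of
grid-based field simulation; refine `nx`/`ny` where it matters). Cholesky
factors are cached on grid geometry and range, so repeated realizations are
cheap. Negative simulated measurements are censored at zero (rare with the
default parameters).

**What a green test does not establish.** The generator produces rectangular
zoning, straight roads, stationary winds and Gaussian errors; real campaigns
face correlated instrument drift, seasonally varying source strength,
non-Gaussian outliers and GIS-layer error. Green recovery tests establish
the *procedure's* correctness and its behavior under a known world, not
field accuracy in any real city.

## Numerical choices

* Road-length and traffic clipping is analytic (segment–circle quadratic):
  exact, monotone in radius, tangent contact contributes zero.
* Area and population buffers use polygonal circles with `quad_segs`
  segments per quarter; 1024 by default (relative area error ≈ 4 × 10⁻⁷).
  The pipeline uses 256 (≈ 6 × 10⁻⁶) as a runtime/accuracy tradeoff; both
  are far below any statistical effect. Land-use polygons are unioned per
  class before intersection, so overlapping zones never double count.
* Population integrates cell counts weighted by the intersected area
  fraction of boundary cells — exact for uniform fields up to the polygonal
  circle error.
* Inverse distance clamps at d_min = 1 m; wind sectors default to ±22.5°
  (a 45° sector); elevation sampling is bilinear, clamped at the outer cell
  centers, and errors outside coverage.
* Seeds: all randomness flows through `numpy` `SeedSequence` spawning;
  identical (config, seed) reproduce scenes, sites, records and report
  tables byte-for-byte.

## Known limitations

No network (route) distances, dispersion physics or atmospheric chemistry;
no shapefile reader (GeoJSON only) and no geodesic coordinates; regional
meteorology is season-stationary so seasonal met scalars are not
distinguished from annual ones; the truth model shares one temporal
deviation city-wide, which is what makes reference adjustment well-posed —
cities with region-specific temporal dynamics would violate it.
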