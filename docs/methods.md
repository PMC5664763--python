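# Methods

This note documents the models, procedures and numerical choices behind
`noiselur`, and what the synthetic experiments do and do not demonstrate.

## Acoustic period metrics

**Model.** A site's exposure is summarised from a continuous outdoor
recording of 1-second A-weighted equivalent levels. All aggregation is
*energetic*: a set of levels L₁…Lₙ is combined as
10·log₁₀(mean 10^(Lᵢ/10)), the constant level carrying the same acoustic
energy. The energetic mean is never below the arithmetic dB mean (Jensen's
inequality), with equality only for constant input.

**Analysis window.** A fixed five-day window from Wednesday 06:00 to the
following Monday 06:00 (432,000 seconds), so every site is summarised over
the same weekday mix. The window constructor rejects anything else.
Timestamps are local civil time; no DST transition is modelled (a five-day
deployment sits inside one offset regime). Sub-second or duplicate
timestamps are rejected at parse time rather than merged.

**Cleaning.** Two screens, in a fixed order:

1. *Completeness* — a site missing strictly more than 10% of the window's
   seconds is excluded; exactly 10% is retained. Missingness is assessed
   against the 432,000 expected seconds before any outlier handling, so
   outlier removal never counts against the completeness budget
   (missingness models equipment failure, outliers model transient
   contamination).
2. *Outliers* — samples deviating more than 3 standard deviations from the
   five-day mean are removed. Mean and SD are computed arithmetically on
   the dB values, and the screen is a single pass: flagged samples are
   removed together and survivors are never reclassified. For Gaussian dB
   input this removes ≈ 0.27% of samples (the two-sided 3-SD tail mass);
   for a series contaminated with large isolated spikes it removes
   essentially all of them, because a spike far outside ±3 SD barely
   inflates the pooled SD at n = 432,000.

**Period levels.** L_day, L_evening and L_night pool *all* seconds of the
window whose clock hour falls in 06–18, 18–22 and 22–06 (night wraps
midnight); L_Aeq24h pools the whole window. Pooling (rather than averaging
per-day metrics) is robust to gaps; for complete data the two conventions
coincide here because the fixed window contains the same number of days of
each period class. L_den applies +5 dB to the evening energy and +10 dB to
the night energy with 12/4/8-hour duration weights:

    L_den = 10·log10((12·10^(L_day/10) + 4·10^((L_evening+5)/10)
                      + 8·10^((L_night+10)/10)) / 24)

Consequences used as test invariants: L_Aeq24h ≤ L_den ≤ L_Aeq24h + 10, and
a profile of (60, 55, 50) dB gives L_den = 60.00 exactly (the penalties
cancel the evening/night deficits energy-for-energy).

## GIS buffer predictors

All geometry lives in a projected metric CRS. Inputs whose coordinates all
fit inside a lon/lat degree box are refused — measuring buffer lengths in
degrees is a silent catastrophe, so the module fails loudly instead of
re-projecting.

The candidate grid has 105 variables: 10 road-class combinations × 5 radii
(25–500 m), 7 inverse distances (nearest road, airport, railway in
activity, any railway, church, police station, hospital), household density
at 7 radii (25–1000 m), 5 land-use classes × 7 radii, and mean NDVI at 6
radii (30–750 m). Expected signs: positive for all road lengths, inverse
distances, household density and commercial/industrial/built land-use;
negative for NDVI, nature and residential land-use.

Numerical choices:

* **Road length in a buffer** is computed by clipping each straight segment
  against the true circle (a per-segment quadratic), which is exact: a
  diametral chord measures exactly 2r and an offset chord 2·√(r²−d²).
  Composite classes ("large and medium", "all roads", …) are sums of the
  class-specific lengths — identical to re-clipping a union for
  non-overlapping polylines and much cheaper, and it makes class-partition
  additivity exact by construction.
* **Disc–polygon areas** (land use) use a Green's-theorem decomposition:
  edge portions inside the circle contribute chord terms, portions outside
  contribute signed circular arcs of r²θ/2. Summed over rings (shells CCW,
  holes CW) this gives the exact intersection area for arbitrary simple
  polygons with holes; a disc wholly inside a polygon measures exactly πr²
  and a polygon not touching the disc contributes exactly zero. Whole
  polygons are kept together during bounding-box prefiltering so the
  winding of enclosing rings stays intact. Overlapping polygons within a
  class are unioned once before edge extraction so area is never counted
  twice.
* **Inverse distances** are 1/max(d, 1 m); the floor bounds the variable
  when a site touches a feature, which otherwise would dominate the
  univariate screen.
* **Buffers are closed discs** (boundary included); raster cells belong to
  a buffer by the cell-centre rule, and missing cells are ignored.
* **Household density** is a point count divided by πr²; a density of
  1.273×10⁻³ per m² corresponds to 12.73 homes per hectare.

Variables whose source layer is empty are dropped with a logged warning, so
the feature matrix is always dense.

## The selection procedure

The response is per-site L_den; predictors are the candidate grid. The
stages, with thresholds `corr_threshold = 0.7`, `p_remove = 0.2`,
`p_keep = 0.2`:

1. **Univariate screen** — OLS of the response on each candidate alone.
2. **Best buffer per type** — within each variable type, keep the buffer
   with the highest univariate R² *among those with the expected
   coefficient sign*; ties go to the smaller buffer; a type with no
   correctly-signed buffer is dropped. This is the standard sign-constrained
   reading of buffer selection in LUR practice.
3. **Forward selection** — candidates enter in decreasing univariate-R²
   order (ties by name); a candidate is added iff |Pearson r| < 0.7 against
   every included variable *and* the adjusted R² strictly increases on
   refit. Candidates rejected once are not reconsidered in this pass (the
   challenge step provides re-entry).
4. **Backward pruning** — while any coefficient has p > 0.2, remove the
   largest-p variable and refit ("one by one", largest first — the common
   convention where the order is ambiguous).
5. **Challenge** — one full pass over the model in current order; each
   variable is challenged by every candidate of the full grid not already
   in the model. The best replacement by adjusted R² is accepted iff it
   strictly improves the model, keeps all pairwise |r| < 0.7, and its
   coefficient carries the expected sign in the new fit. A single pass
   keeps the procedure deterministic and trivially terminating.
6. **Final augmentation** — at most one additional variable: the best
   adjusted-R²-improving, gate-passing candidate, kept only if its p ≤ 0.2.

Sign constraints bind at screening and challenge only; the multivariable
forward/prune stages do not re-check signs. The correlation gate applies to
|r| on raw (untransformed) columns; response and predictors are never
transformed. All ties anywhere break by (higher adjusted R², smaller
buffer, lexicographic name), so the whole pipeline is deterministic and two
runs on identical input produce identical traces.

Every decision is logged as a trace event (variable, action, adjusted R²
before/after); replaying the add/remove/swap events against the same
feature matrix reproduces the final fit exactly, which is asserted in the
tests.

**Degenerate inputs.** Constant candidate columns screen as
zero-information (dropped); trial fits that are exactly rank-deficient
(composite road variables can be exact sums of others) or would exhaust the
residual degrees of freedom are rejected within the stage rather than
aborting the pipeline. `fit_ols` itself raises on rank deficiency and on
n ≤ p + 1. Inner-loop trials use a direct least-squares implementation of
the identical model for speed; accepted models are always refit through
statsmodels, and the two agree to machine precision.

**Known limitation — proxy selection.** The candidate grid is deliberately
redundant: composite road lengths overlap their component classes, and
neighbouring buffer radii of the same type are strongly correlated. The
correlation gate then sometimes locks in a *proxy* (e.g. a composite road
length, or the 25 m buffer of an effect generated at 50 m) and blocks the
generating variable itself, because swapping it in no longer improves the
adjusted R² or violates the gate against another retained variable. In the
recovery experiment below this caps the exact-support recovery rate around
80–90%; the selected proxies are correlated 0.7–0.97 with the true
variables, so the *signal* is captured even when the label is not.

## The synthetic-data generator

The generator emulates a small-area measurement campaign on a 3 km square
extent (≥ 2× the largest buffer) with, by default, 134 sites in four
quadrant areas: random straight road segments in four classes (3 large, 8
medium, 18 small, 30 very small), 3,000 households of which 70% cluster
around the sites (Gaussian, SD 150 m) and 30% are background, a 100 m
land-use mosaic (residential 50%, commercial 10%, industrial 10%, buildings
15%, nature 15%), a handful of community point features (active railways a
subset of all railways), and a smooth NDVI field (30 m cells, Gaussian
filter, mean 0.25, SD 0.15, clipped to [−1, 1]). The mosaic cell size is
100 m so that adjacent buffer radii (25 vs 50 m) sample measurably
different areas — with coarser cells those columns become near-duplicates
and a ground truth placed at one specific buffer is unidentifiable in
principle.

Random streams are per component (sites, roads, households, land use,
points, vegetation; and layout/response/series at the study level), so
changing one configuration never perturbs the others, and everything is
byte-reproducible from the seed.

**Ground-truth response.** L_den = β₀ + Σβₖxₖ + ε with ε ~ N(0, σ²). The
default truth mirrors the structure of a traffic-and-density noise model —
intercept 61.3 dB; positive effects of household density (50 m), medium
roads (25 m), large roads (200 m), commercial and industrial land use
(50 m) — with magnitudes (12000, 0.15, 0.015, 0.0009, 0.0010 in dB per
unit) chosen once so each predictor contributes roughly 2–4 dB of SD across
sites on the default layout, i.e. effects that are strong relative to the
default σ = 1 dB. These magnitudes are a detectability choice for the
recovery experiments, not an empirical claim about any real study area.

**Raw series.** Within each clock period, 1-s levels are i.i.d. Gaussian on
the dB scale with SD s (default 3 dB) around a mean of target − s²·ln10/20;
the lognormal correction makes the *energetic* mean equal the target, so
the cleaned series reproduces prescribed period levels to well within
0.1 dB over a five-day window. Spikes are isolated single-second excursions
(default +25 dB) at a configurable hourly rate — matching the 1-s outlier
definition — and gaps are up to three contiguous blocks totalling the
configured missing fraction. Levels are clipped to the physical [0, 140]
dB(A) range.

**What the synthetic experiments do not show.** Generated predictors are
spatially simpler than municipal GIS extracts (straight roads, box mosaic,
no geocoding error); the response is exactly linear with homoscedastic
Gaussian noise; and the series have no diurnal autocorrelation or weather.
Passing tests therefore validate the *mechanics* (formulas, cleaning rules,
geometry, selection logic, determinism) — they do not certify predictive
performance on real measurement campaigns, where the linear LUR itself
explains far less variance.

## Evaluation

Predicted-vs-measured agreement is the squared Pearson correlation, overall
and within each area using the same single model (areas are never refit);
an area with fewer than 3 sites, or a degenerate (constant) prediction,
reports an undefined R². Residual normality is summarised descriptively
with the Shapiro–Wilk statistic on standardized residuals. Level
distributions are binned in 2.5 dB classes over 45–80 dB(A) by default,
with out-of-range values counted in the edge classes so proportions sum to
one. On training data, var(predicted)/var(measured) = R² exactly (an OLS
identity, asserted to 10⁻⁶), which is why the predicted distribution is
always the narrower one.

## Experiment sizes

The shipped experiments use a 432,000-second series for the cleaning
checks, 20 seeded instances for the greedy-vs-best-subset comparison, and
50 seeded studies of 200 sites for the recovery experiment — sizes at which
the binomial uncertainty on a 90% rate is a few percent and the full suite
runs in a couple of minutes.
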