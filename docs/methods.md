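# Methods

`burnsel` implements a used/available habitat-selection analysis for
animals in burned landscapes: raster covariate derivation, a synthetic
fire-mosaic landscape generator, GPS-telemetry simulation with known
selection coefficients, and a random-forest model-development procedure
with Model-Improvement-Ratio (MIR) variable selection and permutation
significance. This note records the model choices, the defaults and
their rationale, and what the synthetic experiments do and do not show.

## Raster primitives

All rasters are north-up grids in projected meters, 30 m cells by
default, with cell centers as the coordinate reference and Euclidean
distances throughout. GeoTIFF I/O writes the standard ModelPixelScale /
ModelTiepoint / GDAL_NODATA tags; legends travel as JSON sidecars.

**Slope and aspect** use central differences in the grid interior and
one-sided differences on edges; aspect is the downhill azimuth,
clockwise from north, with a sentinel (−1) on flat cells. **Heat load**
is the folded-aspect equation of McCune & Keon (2002): aspect is folded
about 225° (A′ = |180° − |aspect − 225°||) so southwest slopes receive
the maximum load, and the ln-scale regression surface

ln HL = −1.467 + 1.582 cos L cos S − 1.500 cos A′ sin S cos L
− 0.262 sin L sin S + 0.607 sin A′ sin S

is exponentiated to a direct index (L latitude, S slope). At S = 0 every
aspect term vanishes, so flat cells are aspect-invariant by
construction. Latitude is validated to (0°, 60°), the range the equation
was fit for.

**Flow accumulation** is single-direction (D8): each cell drains to its
steepest-descent neighbor, ties resolving to the first neighbor in
clockwise-from-north order. Flats drain iteratively toward the nearest
cell that already has an outflow (same tie order); enclosed flats become
pits. Accumulation is propagated in topological order and reported as
contributing area in m², own cell included. The **wetness index**
(compound topographic index) is ln(a / tan β) with a the specific
catchment area (contributing area / cell width) and β floored at 0.001
rad so flat cells stay finite; the index is strictly increasing in a and
decreasing in β above the floor. **Draws** (convergent drainage) are
cells at or above a configurable flow-accumulation quantile (default
0.95).

**Distance transforms** are exact Euclidean (center-to-center). Burn-edge
distance is defined on every within-burn cell; the edge is any cell
outside the burn or the map boundary (a phantom ring of unburned ground
one cell off-map), and interior fire skips count as edge by default —
they are unburned ground, so a skip cell sits at distance 0. **Focal
statistics** (means and class fractions) use the two analysis windows,
3×3 and 27×27 cells (90 m and 810 m at 30 m cells); edge cells average
over the in-bounds part of the window rather than padding with invented
habitat, and nodata cells are excluded from both numerator and
denominator. **Nibble** reassigns masked land-cover cells to the class
of the exactly nearest valid cell; distance ties break to the lower
class code, then row-major source order, so results are deterministic.
**Burn classification** maps canopy-cover loss and burn year to four
classes: loss in (0, 50] is low severity, loss above 50 high severity
(the published class bounds, 1–50% and >51%, leave (50, 51] open; it is
assigned to high so the partition is exhaustive), with fire-year bands
(defaults: 1998–2007 new, 1985–1997 old) separating new from old burns.

## Synthetic landscapes

Random surfaces are Gaussian fields: white noise smoothed with a
wrap-around Gaussian kernel whose sigma is the field's correlation
length, then standardized. Category maps (burn classes, land cover) are
cut from these fields by empirical quantiles, which pins achieved area
fractions to their targets up to cell-count discreteness — the
fraction-fidelity checks pass by construction, not by luck.

The burn perimeter is the largest connected super-threshold region of a
long-range field, morphologically closed and hole-filled, giving one
simply connected fire footprint covering ~40% of the map. Within the
perimeter, classes are allocated by quantile bands of a second field:
new-high, new-low, old burn (split evenly into old-high/old-low), and
unburned skips; unallocated fraction mass joins the skips. Two presets
carry the studied compositions: `tripod` (63% new high severity, 8% new
low, 8% old burn, 21% skips; elevations 855–2,390 m) and `whiteface`
(82% / 10% / 0% / 8%; 1,280–2,222 m).

Land cover has eight classes allocated within three equal-area elevation
bands, with spruce–fir concentrated in the top band and dry forest in
the bottom band. Canopy cover is a correlated base surface (~60% cover)
knocked down by burn class — new high-severity cells are redrawn from a
low-canopy distribution (residual snags, a few percent cover), new-low
loses ~35%, old burns have partly regenerated — so the canopy contrast
between severities holds by construction. Growing-season precipitation
increases linearly with elevation (0.15 mm/m) plus correlated noise.

Default correlation lengths (dem 3,000 m, perimeter 2,500 m, burn mosaic
900 m, land cover 500 m, canopy 300 m, precipitation 1,200 m) were set
to look like a single large fire with sub-kilometer severity patchiness;
no field data constrain them, and patch-scale realism is explicitly
configurable rather than calibrated. One master seed derives per-layer
sub-seeds by fixed offsets, so layers are individually reproducible.

What the generator does **not** emulate: fire-spread physics, vegetation
succession, real DEM hydrography, or the empirical patch-size
distribution of fire skips. Canopy is close to a deterministic function
of burn class, which is stronger coupling than real landscapes show —
consequential for the recovery experiments (below).

## Telemetry simulation and sampling design

Movement is a discrete-choice step-selection process on 4-hour ticks. At
each tick, K = 20 candidate endpoints are proposed with gamma step
lengths (mean 766 m, shape 2 — positive and right-skewed, the standard
movement-length family) and uniform headings; one candidate is chosen
with probability ∝ exp(Σ β·z), where z are map-standardized covariate
surfaces and β the known selection coefficients. The chosen location is
recorded with probability 0.72 (the collar fix rate); failed fixes leave
gaps. Off-map proposals keep their gamma length and redraw the heading,
so map edges do not truncate the step-length distribution — realized
mean step length stays within sampling error of 766 m on bounded maps.
Timestamps are abstract 4-hour ticks; no diel or seasonal structure is
modeled. A separate point-level sampler draws used points directly from
an inhomogeneous point process with log-intensity Σ β·z, for experiments
that need selection without movement autocorrelation.

The study area is the union of 766 m buffers around the straight lines
connecting sequential fixes; the raster mask is computed from exact
point-to-segment distances (cells whose center lies within the buffer),
and the vector polygon from a shapely buffer of the track polyline.
Available points are drawn uniformly over the availability mask, exactly
as many as there are used points, with replacement across cells
(availability is a design distribution, not a complement of use). Table
rows with any nodata covariate are dropped and the larger class is then
down-sampled at a fixed seed, preserving the equal-count design. Raw
elevation and the circular aspect angle are excluded from the default
covariate roster; terrain enters through slope, heat load, and wetness.

Burn-use summaries report the exact percentage plus half-up roundings to
one decimal and to whole percent. For the published counts 789 of
13,972 the arithmetic gives 5.647%, which prints as 5.6% at one decimal;
765 of 6,772 gives 11.297%, printing as 11%.

## Model development

The classifier is a random forest of 4,000 bootstrap trees by default
(tests and simulations reduce the count through configuration). Two
engines sit behind one estimator:

- `cart` (default): an in-repo bagging loop over sklearn CART trees with
  per-tree bootstrap weights. Holding the bootstrap membership in-repo
  gives the classical out-of-bag (OOB) error, per-class OOB errors, and
  Breiman-style OOB permutation importances (mean per-tree decrease in
  OOB accuracy when one predictor is permuted) — the importance the R
  `randomForest` tradition reports as MeanDecreaseAccuracy.
- `hist`: LightGBM in random-forest mode (bagging 0.632 per iteration,
  √p feature sampling). Histogram split-finding is roughly an order of
  magnitude faster per fit, which is what makes ten-thousand-fit
  permutation simulations tractable; per-tree bags are not exposed, so
  its accuracy estimate is a stratified 30% internal validation split
  and its importances are split gains.

Both engines are deterministic under a fixed seed, and a test
cross-checks the cart engine's OOB error against sklearn's
RandomForestClassifier on the same data.

**Screens.** Multivariate redundancy is detected by rank-revealing QR on
the standardized column matrix (pivots whose R-diagonal falls below 1e−6
of the leading diagonal are removed). Collinearity uses Spearman rank
correlation with the |r| > 0.8 threshold; within a flagged pair, the
member with the lower importance in a small pre-screen forest is
dropped (pairs processed in descending |r|, each variable dropped at
most once). Constant columns are reported separately. Screens run on
the full table before the train/holdout split, matching the procedure's
narrative order.

**Spatially weighted 80/20 split.** Each point's training-inclusion
probability is proportional to the inverse of the local point intensity
(Gaussian KDE with rule-of-thumb bandwidth, boundary-corrected by
reflecting the points across their bounding box so map edges do not
inflate weights), capped at 1 and scaled to a fixed training size of
round(0.8 n); sampling is exact-size systematic PPS. Constant-intensity
patterns therefore get inclusion probability exactly 0.8 per point, and
clustered points are preferentially thinned into the holdout share.

**MIR selection.** Variable importance is rescaled by the maximum
(negatives floored at zero) to the Model Improvement Ratio. Thresholds
0.0–1.0 in 0.1 steps retain the nested sets MIR ≥ t; each retained set
is refitted and its OOB and per-class errors recorded (11 rows, always).
The final set minimizes the combined error — OOB error plus within-class
error — with exact ties resolving to fewer variables and then to the
larger threshold. The published description lists the three quantities
("out-of-bag error, within-class error, number of variables") without
an order; a strict lexicographic reading degenerates to "minimize OOB
alone" (continuous errors almost never tie) and systematically prefers
single-variable models under correlated predictors, so the composite is
used. "Within-class error" aggregates per-class errors by max by
default (`mean` is available in configuration).

**Permutation significance.** The used/available labels are permuted B
times (default 1,000; at least 19 enforced, or the p-resolution is
meaningless); each permutation refits the forest and records its
accuracy estimate; p = (1 + #{null ≥ observed}) / (B + 1), so p is never
smaller than 1/(B+1). The observed statistic always comes from the same
engine as the null refits.

**Partial dependence** is the substitution average: for each grid value
v, the focal column of every row is set to v and the predicted
probability of "used" is averaged. The implementation is checked
exactly against that brute-force definition. Curve direction is
summarized as the sign of the Spearman correlation between the grid and
the curve.

The full pipeline (`run_burn_model`) derives per-stage sub-seeds from
one master seed by fixed offsets, so each stage is independently
reproducible and two runs with the same inputs are identical.

## Validation experiments and their scope

**Null honesty.** Under β = 0 the chosen step endpoints are exchangeable
with the candidate pool, and the tests verify this (mean difference and
two-sample KS against candidates). Note what is *not* claimed: a single
under-mixed random walk does not occupy its range uniformly, so
comparing its points against *uniform-area* availability detects genuine
movement structure — a known property of used/available designs, not a
pipeline artifact. The pipeline-level null calibration therefore draws
availability from the candidate pool; real multi-animal, year-long
datasets mix far better than one simulated walk.

**Permutation calibration** uses 100 replicate null tables (n = 400, six
independent covariates), B = 99 permutations, 200 trees, and checks the
type-I error at α = 0.05 against the exact binomial 99% interval. It
runs on the `hist` engine: the calibration property of a permutation
p-value holds for any accuracy statistic computed identically on
observed and permuted data, and the cart engine would need roughly an
hour of CPU for the same 10,100 fits.

**Parameter recovery** draws 1,000 used points by point-level selection
(β = −1.5 on the large-scale new-high-severity fraction, +1.5 on the
large-scale skip fraction, standardized) within the burn perimeter of a
250×250 tripod-composition landscape, against 1,000 uniform within-burn
available points, and runs the full pipeline at 200 trees. Success
requires the chosen set to represent both burn classes with the leading
covariate of each class showing the generating sign in its
partial-dependence curve. Two design points matter:

- *Mosaic grain.* Recovery landscapes use a 450 m burn-patch correlation
  length — patches finer than the 810 m analysis window. At coarser
  grain the within-window new-high and skip fractions become
  near-complementary (|Spearman r| ≈ 0.8–0.9): the collinearity screen
  itself removes one of the generating covariates, and on a sizable
  share of realizations the single skip-fraction model genuinely
  minimizes every error criterion (verified at 1,500 trees), so no
  error-minimizing selection could retain both. The experiment is a test
  of the method, which requires a design where the truth is
  identifiable.
- *Roster.* Canopy cover and burn-edge distance are excluded from the
  recovery roster because the generator derives them from the burn
  classes themselves; including near-deterministic surrogates of the
  treatment would make "which covariate drove selection" ill-posed.

**Fidelity checks** confirm the tripod composition within ±2 percentage
points at 400², and the realized fix rate (0.72 ± 0.03) and mean step
length (766 m ± 2 SE) over 2,000 attempts.

Passing these experiments shows the procedure is internally correct and
can recover known selection under identifiable synthetic conditions; it
does not show that any particular real landscape satisfies those
identifiability conditions, nor does it reproduce the real study's
variable rankings, which depend on agency-archived data.

## Problem sizes

Defaults target desk-scale runs: landscapes 150²–400² cells, single-
animal tracks of 1,200–5,000 steps, tables of ~2,000 rows, 200-tree
forests in simulations (4,000 in the headline configuration), B = 99–199
permutations in simulations (1,000 by default). The test suite runs in
roughly seven minutes on one CPU; the reproduction script in about five.

## Known limitations

- D8 routing cannot split flow between neighbors; dispersal areas on
  divergent terrain are underestimated relative to multiple-direction
  algorithms.
- The `hist` engine's validation-split accuracy is noisier than OOB for
  the same tree count, and its gain importances are not comparable in
  scale to permutation importances (MIR rescaling absorbs this).
- KDE-based intensity weighting retains some boundary bias for highly
  irregular point clouds despite reflection.
- The generator's canopy–severity coupling is tighter than nature's;
  treat canopy covariates in synthetic experiments as part of the burn
  treatment, not an independent habitat axis.
- No reprojection or resampling: all inputs must be co-registered on a
  single projected grid.
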