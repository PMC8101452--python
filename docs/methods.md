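# Methods

## Model overview

`climniche` estimates, for each species, the probability that any location's
climate lies within the species' *fundamental niche* — the full set of
climatic conditions permitting persistence — and tracks how the
probability-weighted extent of suitable climate (the *potential niche*,
the intersection of the fundamental niche with the climate actually present
in the study area) changes between current and future climate grids. Changes
are then pooled across the species that provide each ecosystem service.

The niche model is deliberately minimal, chosen for presence-only data of
heterogeneous provenance: no absences, no background region, no density
estimate. Occurrence scores in a k-dimensional PCA climate space are
summarized by their mean μ̂ and sample covariance Σ̂ (denominator n−1), and
the squared Mahalanobis distance of a climate point from μ̂ is referred to a
chi-square distribution with k degrees of freedom. The upper-tail
probability P(χ²ₖ ≥ D²) is the within-niche probability: exactly 1 at the
centroid, strictly decreasing along any ray leaving it, and calibrated in
the sense that under multivariate normality a fraction 1−q of the species'
own climate mass has probability ≥ q. The p-level ellipsoid surfaces are
nested (p ≥ 0.9 innermost). The method's key assumption is approximate
multivariate normality of the species' climate envelope in PC space;
ellipsoidal symmetry is imposed by construction, which buys robustness to
outliers at the cost of flexibility for truncated or multimodal envelopes.

## Environmental space

The PCA transform is fitted once, on the valid study-area cells of the
*current* climate stack, and then applied unchanged to every future stack:

- Rainfall-derived variables (default BIO12–BIO19) are log-transformed.
  `log1p` is used rather than `log` so that zero precipitation is
  representable; the choice of the log set is configurable.
- All 19 variables are z-scored (mean/sd over valid cells, sd with n−1).
- The correlation-scale covariance of the z-scores is eigen-decomposed;
  eigenvalues are reported as variance fractions for all 19 components
  (they sum to 1 by trace conservation), and the first k = 3 loading
  columns are retained. Three components typically carry the bulk of
  bioclimatic variance (temperature level, moisture, seasonality); the
  retained cumulative fraction is logged on every fit.
- Sign convention: each loading column is flipped so its largest-magnitude
  entry is positive, making outputs reproducible across eigen-solvers.
- Future values outside the training range are extrapolated linearly
  (z-scores beyond the training span are legitimate and expected under
  warming).
- A skewness diagnostic (`distribution_diagnostics`) reports raw and
  post-log skewness per variable; it is advisory and never gates a fit,
  since transform screening is a judgement call best left visible to the
  analyst.

Constant variables (zero scale) are refused by name. A layer shifted by a
constant leaves all scores unchanged (centering absorbs it); score layers
are pairwise uncorrelated on the training cells.

## Occurrence cleaning

Records flow through four ordered rules, each contributing to a per-species
audit report: (1) a coordinate bounds filter (records outside the grid
extent count here too); (2) removal of records on nodata cells; (3) an
optional elevation cross-check against a DEM — records whose label
elevation differs by more than 500 m (default) are flagged, and dropped
only if `drop_on_elevation_flag` is set, because such flags usually warrant
manual review rather than automatic deletion; records without a label
elevation are never touched by this rule; (4) deduplication to one record
per species per climate cell, keeping the first record in input order (a
stable, reproducible tie-break; order dependence affects only *which*
duplicate survives, never how many). Species with fewer than `min_n = 20`
retained cells are excluded and listed; 20 points is a conventional floor
for a 3-D covariance estimate and the threshold is configurable.

Cell membership uses half-open cells [x₀, x₀+res) × (y₀−res, y₀]; points
exactly on the grid's outer edge are assigned to the adjacent interior
cell, so the study-area boundary never silently discards records.

## Bootstrap and projection

- B = 1,000 classical bootstrap resamples (with replacement, resample size
  n) per species; each resample is refit to its own (μ̂ᵦ, Σ̂ᵦ). Degenerate
  resamples are redrawn up to 100 times, then ridge-regularized by adding
  δ·tr(Σ̂)/k (δ = 1e−8) to the diagonal with a logged warning.
- D² is computed through a Cholesky factorization and triangular solve —
  never an explicit inverse, which exists only as a test oracle.
- Potential-niche area = Σ over valid cells of the within-niche
  probability × cell area (km²), i.e. a threshold-free, probability-
  weighted area, also reported as a percentage of the study area.
- For every (period, RCP) scenario, one GCM is drawn uniformly at random
  per species × bootstrap (independent draws, logged to CSV so the
  shared-draw variant can be audited or added). Each bootstrap model is
  paired with its own current-climate area, so per-bootstrap changes are
  differences within one model, and a future grid bit-identical to the
  current one yields *exactly* zero change — the projection stage derives
  the current-climate PC stack through the same code path as the future
  stacks to keep this invariance exact to the last bit.

## Service aggregation

Changes are expressed in percentage points of the study area (not relative
to a species' own current area), so species of very different range sizes
pool on a common scale. Per service and scenario the pooled vector
concatenates the per-bootstrap changes of all member species; a species
contributes once per level-2 service it provides, so a level-1 category's
n counts species-service memberships, and the level-1 pooled multiset is
exactly the concatenation of its level-2 children. Pooling refuses ragged
inputs (a scenario missing for one member species) rather than silently
biasing the distribution. An equal-weight-per-species variant is a
documented possible extension, not implemented.

Beanplots draw one panel per service and one bean per scenario (2050
before 2070, RCP 2.6 → 8.5): a mirrored Gaussian-KDE silhouette, the raw
pooled values as a faint strip, the median bar, and a zero-change
reference line. Constant distributions collapse to a spike. The exact
plotted values are exported as CSV beside the figure.

## Synthetic data

The generator exists so that every stage can be tested against known
ground truth without downloads; its defaults describe a tropical-mountain
study region at desk scale.

- **Current climate**: a latent elevation field (smooth ridge + low-order
  cosine noise, relief 1.5 km) drives temperature via a 6 °C/km lapse from
  a 24 °C base; a latent moisture gradient drives precipitation
  (~200–2,000 mm annual). Diurnal and seasonal amplitudes grow with
  elevation. Per-cell coherence BIO5 ≥ BIO1 ≥ BIO6 holds by construction,
  precipitation is non-negative, and a configurable nodata fraction voids
  the same cells in every layer (refusing if fewer than two valid cells
  remain). Explicit `elevation`/`moisture` fields may be supplied, which
  makes the lapse relation exact and testable.
- **Futures**: one stack per period × RCP × GCM. Temperature-level layers
  (BIO1, 5, 6, 8–11) shift by a scenario mean offset plus a smooth
  GCM-specific anomaly field (low-order cosine basis, sd 0.4 °C by
  default) so GCMs disagree spatially, not just by a constant; the
  seasonality layers BIO4 and BIO15 are inflated multiplicatively. Default
  offsets are CMIP5-era magnitudes — 1.0/1.8/2.2/3.7 °C by 2070 for RCP
  2.6/4.5/6.0/8.5, with 60% of the warming realized by 2050 — and default
  inflations 1.02–1.12 by 2070. Range-type layers (BIO2, BIO7) and
  precipitation totals carry over unchanged, preserving coherence. The
  true spatial covariance of GCM disagreement is not modelled; the cosine
  field is a structural stand-in.
- **Virtual species**: occurrence cells are drawn *without replacement*
  with selection weight equal to the species' chi-square niche probability
  at each cell — pre-matching the one-record-per-cell rule so the
  generator does not manufacture duplicates the cleaner would delete.
  Because sampling weights are niche probabilities (not the normal
  density), the moments of the induced occurrence distribution are those
  of the weighted cell distribution; recovery tests therefore compare
  fitted parameters against moments computed by exact enumeration over
  cells (on a symmetric dense lattice these coincide with the generating
  mean). A species whose niche has no support on the grid is refused.
- **Catalogue**: each species receives 1–3 distinct level-2 services
  (uniform; median 2 over many species) from a pool of 19 services in 4
  categories.
- All randomness flows from one root seed through named substreams
  (`climate`, `gcm/...`, `species/...`, `bootstrap/...`, `gcm-draws/...`),
  so each stage is independently reproducible and insensitive to the
  order in which other stages consume randomness.

What passing synthetic tests do **not** show: performance under real-world
sampling bias, spatial autocorrelation of occurrence records, non-elliptic
niches, latitude-dependent cell areas (grids are planar equal-area by
design), or realistic GCM disagreement structure.

## Numerical choices

- Covariances use the n−1 denominator throughout.
- Degeneracy: a covariance is treated as singular when its smallest
  eigenvalue ≤ 1e−10 × the largest; constant climate variables are
  detected via a scale below 100 machine epsilons of the variable's mean
  magnitude.
- Rasters are written as float32 TIFF with NaN nodata plus a JSON sidecar
  carrying grid geometry; every pipeline stage consumes the on-disk
  artifacts of its predecessors, so single-stage and full runs follow the
  identical numeric path (including the float32 round-trip) and produce
  bit-identical tables.
- The pipeline's problem sizes at desk scale — 60×60 cells, 12 species,
  120 occurrences each, B = 200, 5 GCMs — were chosen as the smallest
  configuration that exercises every factorial combination (2 periods × 4
  RCPs) with stable service-level distributions; the statistical method is
  size-agnostic and B = 1,000 remains the library default.

## Known limitations

- The potential niche ignores dispersal limits, biotic interactions and
  land use, so it upper-bounds any realized distribution.
- The chi-square reading of Mahalanobis distances treats Σ̂ as known;
  with small n the probability surface understates parameter uncertainty
  (the bootstrap ensemble is the mitigation).
- Membership-weighted pooling lets multi-service species dominate their
  categories; this mirrors how service counts are usually reported but is
  a modelling choice, not a law.
- GeoTIFF geo-referencing tags (CRS, affine transform) are not written;
  grids are planar with an explicit JSON sidecar instead.
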