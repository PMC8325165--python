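# Methods

This note documents the models and procedures implemented in `no2parity`,
the choices made where the construction was genuinely open, and what the
synthetic validation does and does not demonstrate.

## Oversampling level-2 retrievals

Level-2 NO2 column retrievals arrive as quadrilateral footprints of roughly
3.5 × 5 km (3.5 × 7 km for early-mission data), each with a tropospheric
column amount (molecules cm⁻²) and a quality-assurance value in [0, 1].
Pixels with QA strictly greater than 0.75 are retained; the inequality is
strict, so a pixel at exactly 0.75 is dropped.

Oversampling composites all retained footprints of an averaging period onto
a regular 0.01° × 0.01° grid. Cell (i, j) receives

    value(i, j) = Σₚ wₚ · columnₚ / Σₚ wₚ ,   wₚ = area(footprintₚ ∩ cell),

with overlap areas computed by Sutherland–Hodgman clipping of each
quadrilateral against the axis-aligned cell. Areas are evaluated on a local
equirectangular plane about the grid center; the cos(lat) scale factor is
common to every overlap in the grid, so the weighted means are unaffected
by the projection. Design points:

- **Area weighting** is the conventional oversampling construction; the
  choice of weight scheme (area vs. retrieval-uncertainty weighting) is a
  package convention, exposed by keeping `method="centers"` (center-point
  binning with unit weights) as a cheap alternative.
- **Temporal pooling**: all pixels of the three-month window enter one
  weighted mean rather than averaging daily means; this maximizes noise
  suppression and makes batch processing exact — merging per-day weighted
  sums is algebraically identical to a single pass (tested).
- Cells are half-open, `[lon, lon+0.01) × [lat, lat+0.01)`, anchored at the
  grid origin, so cell assignment is bit-reproducible.
- Negative retained columns (possible under retrieval noise) are kept;
  clipping them would bias period means upward.
- The mid-record footprint-size change needs no special casing: larger
  footprints simply spread their weight over more cells.
- Cells never touched by a footprint are missing (NaN), never silent zeros.
- The clipping kernel is JIT-compiled (numba), with an equivalent pure-numpy
  implementation kept as a fallback; the two agree to 1e-14 and both are
  checked against brute-force polygon clipping with an independent geometry
  library (shapely) in the tests.

The difference field is lockdown minus baseline (ΔNO2 < 0 is a drop),
missing wherever either period is missing. The city-local anomaly field
subtracts the mean ΔNO2 over a city mask from each cell in the mask.

## Tract harmonization

A tract's exposure is the **unweighted arithmetic mean of the cells whose
centers lie inside the tract polygon**. Center containment (rather than
area-weighted overlap) keeps the fallback condition — "no colocated cell" —
well defined, and with half-open cells no center can be claimed by two
tracts. Centers exactly on a shared boundary belong to no tract.

Tracts without a colocated cell center fall back to inverse distance
weighting at the tract centroid: the eight cells of the 3×3 neighborhood
around the cell containing the centroid (center cell excluded), weights
d⁻ᵖ with p = 2 over non-missing neighbors, distances in a local planar
frame about the centroid (error < 0.1% at these scales). Whether "eight
neighboring cells" means the 3×3 ring or the eight nearest non-missing
cells is ambiguous; the 3×3 ring is the default and `neighborhood="nearest8"`
is provided as the alternative. The centroid is the polygon area centroid.
Tracts for which both paths fail (all eight neighbors missing) are excluded
and counted in the manifest. `delta_no2 = no2_lockdown − no2_baseline`
exactly, and `interpolated ⇔ n_cells = 0` by construction.

## Disparity statistics

Subgroups are the tails of each demographic variable: low tail = value ≤
P₁₀, high tail = value ≥ P₉₀ (percentiles by linear interpolation between
order statistics — documented because membership near ties depends on the
convention). Under heavy ties, subgroup size is capped at ceil(n/10) with
ties broken by tract-id order, so membership is deterministic. Thresholds
are recomputed within each conglomeration (all/urban/rural/MSA). Tracts
missing a variable are excluded from that variable's partition only.

The disparity ratio divides the marginalized subgroup's mean exposure by
the nonmarginalized subgroup's, on the raw concentration scale (the
headline quantities in this literature are ratios of plain means). Which
tail is "marginalized" is variable-specific (least White, most Hispanic,
lowest income, lowest vehicle ownership, lowest college attainment).

Two significance procedures:

- **Within a period**: two-sided two-sample Kolmogorov–Smirnov test between
  the subgroup exposure distributions, asymptotic p, α = 0.05.
- **Between periods**: a z test on the change in the log-scale disparity.
  Exposures are log-transformed (they are strongly right-skewed; nonpositive
  values cannot be logged and are dropped with a count), and

      z = [(m_L − nm_L) − (m_B − nm_B)] / SE,

  the difference-in-differences of subgroup means of log NO2, with
  SE = √(Σ s²ᵢ/nᵢ) over the four group-period samples (Welch-style,
  per-group variances, treating the four samples as independent). The
  pooled-vs-per-group variance choice is not dictated by the construction;
  Welch is the safer default. Significance at |z| > 1.96. Simulated null
  rejection rates for both tests are 0.05 ± 0.01 at n = 500 per group
  (lognormal nulls, 1000 replicates — computed in the tests and the
  acceptance script).

No multiple-testing correction is applied, deliberately, and no
intersectional (e.g., race × income) partitions are built.

## Road-density proxy

Density = number of primary-road *segments* (polyline records as delivered
by the source layer — densities inherit the source's segmentation
convention) whose minimum distance to the tract centroid is ≤ 1 km. The
1-km radius reflects the observed decay of near-road NO2 enhancements
(roughly half within 0.5–2 km). Distances use a local planar frame about
each centroid. Decile profiles are means over equal-probability bins of a
demographic variable; the ΔNO2 profile carries a seeded nonparametric
bootstrap 90% CI (1000 resamples) — the CI method is a package convention.

## Synthetic scenarios

The generator produces a complete, internally consistent world:

- **True field**: background B plus Gaussian city plumes (amplitude Aₖ,
  σ = 14 km) plus a near-road term E·exp(−d_city/τ)·exp(−d_road/L) with
  L = 2.5 km and τ = 30 km. The taper encodes traffic volume declining away
  from the metro and keeps the (sharp) road term a bounded fraction of the
  local column, which in turn keeps footprint-smoothing error in the
  oversampled field small. The lockdown state multiplies the road term by
  (1 − 0.35) and everything else by (1 − 0.15) by default — drops
  concentrated near roads. Defaults (B = 1.5e15, A = 3e15 and 2e15
  molecules cm⁻²) give columns in the realistic 1.5–6e15 range.
- **Roads**: radial highways per city (with heading wiggle) plus intercity
  connectors.
- **Tracts**: Voronoi cells of seed points, 85% uniform and 15% clustered
  tightly (σ = 0.035°) around cities. The clustering yields realistic size
  heterogeneity including sub-cell tracts; at the defaults ~8% of tracts
  lack a colocated grid cell, exercising the IDW path at the realistic rate.
- **Demographics**: a logistic link on the rank of distance-to-road (plus
  Gaussian noise): White share, income, vehicle ownership, and college
  attainment rise with distance from roads; Hispanic share falls. Race
  shares sum to one exactly. With a planted ratio of 1.0 the link slope is
  zero and demographics carry no spatial signal. The spatial covariance of
  real demographics is not characterized by any single convention; this
  link is the package's own construction.
- **Planted disparity**: with the demographic-decile memberships fixed, the
  above-background field is scaled by the closed-form factor
  s = B(R−1)/(e₁ − R·e₀), where e₁/e₀ are the unscaled excess means over
  the least/most-White deciles at tract centroids. This plants the target
  baseline ratio R exactly on the noise-free surface using the same
  partition rule the estimator applies. Scaling the whole excess (rather
  than the road term alone) keeps the solution well defined for any
  attainable R and preserves the road/local-column bound above. If the
  domain cannot support the requested R (e.g., a domain entirely inside the
  plume), configuration fails loudly rather than planting a distorted
  geography.
- **Swaths**: one full domain tiling per synthetic day; the tiling origin
  is jittered and the footprint axes slightly rotated day to day. Column =
  field at the footprint center × (1 + ε), ε ~ N(0, cv) with cv = 0.5 by
  default (single-retrieval uncertainties run 40–60% of the column). QA is
  uniform on (0.75, 1] for a configurable good fraction (default 0.9) and
  on [0, 0.75) otherwise. No missing-data stripes by default; a gap
  fraction is configurable.

Everything is deterministic given the config seed (independent named
substreams per stage), and scenarios serialize to CSV/GeoJSON/JSON and
round-trip exactly.

### What the synthetic validation shows — and does not

Passing the end-to-end checks demonstrates that the estimator chain is
self-consistent: planted decile ratios {1.0, 1.5, 2.6} are recovered within
a few percent from 60 days of 40%-noise swaths over 5000 tracts, and with
zero noise, tract exposures match true-field means over the same cells to
≤ ~2% for tracts spanning ≥ 4 cells (the residual is footprint smoothing:
a ~5 km footprint cannot fully resolve a 2.5 km near-road gradient; the
worst single tract can drift slightly above 2% for unlucky seeds). It does
**not** validate retrieval physics (no air-mass factors, stripes, clouds,
or orbital geometry are emulated), real demographic covariance structure,
or population-weighted exposure semantics — conclusions about real data
still require the real inputs.

## Problem sizes and budgets

Default study conditions: a 2° × 2° domain (200 × 200 grid), 5000 tracts,
2 cities, 60 synthetic days per period (~129k pixels per period). A full
synthetic pipeline run takes a few seconds on one core; the test suite and
the acceptance script each run in well under a minute. The acceptance
script's recovery sweep uses 3 scenario seeds per planted ratio; the test
suite uses 5.

## Known limitations

- Oversampled values are footprint-smoothed; near sharp line sources the
  grid underestimates ridge values (and tract means inherit a ≲2% error at
  the defaults). Real analyses face the same resolution limit.
- The KS test's asymptotic p-values are approximations at small subgroup
  sizes (< ~25 tracts per tail).
- The z test treats the four group-period samples as independent; in real
  data the same tracts appear in both periods, so the SE is conservative
  when period errors are positively correlated.
- Real-data mode expects pre-downloaded, documented-format inputs; there
  are no download clients, no destriping, and no dasymetric averaging.
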