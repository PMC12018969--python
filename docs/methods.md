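# Methods

This note documents the models implemented in `ecoscape`, the parameter
choices that matter, what the synthetic landscapes do and do not emulate,
and the numerical conventions used throughout.

## Data model and conventions

All analysis happens on aligned single-band rasters at one fixed
resolution (default 500 m per cell). Row 0 is the northernmost row in
memory; origins are stored as lower-left corners, and the conversion to
the GeoTIFF upper-left tie point or ESRI ASCII header happens only at the
I/O boundary. Misaligned inputs (shape, cell size, or origin beyond
1e-6 m) are an error, never silently resampled. Continuous rasters use a
-9999 nodata sentinel; categorical rasters reserve 0. The six-class legend
is fixed: 1 cropland, 2 forest, 3 grassland, 4 water, 5 construction,
6 unutilized. Reprojection and multi-band imagery are out of scope; grids
are assumed already projected to a common equal-area CRS.

## Markov demand projection

The per-step transition matrix is the row-normalized cross-tabulation of a
paired two-epoch map; rows for classes absent at the first epoch become
identity rows so the matrix is always usable. One step equals the 5-year
calibration interval, so a 2020-analogue projected to a 2035-analogue uses
three steps — the only step count consistent with a 5-year calibration
window. Demands are rounded to integers by largest remainder, which
conserves the total cell count exactly.

Scenario rule sets are shipped verbatim as data: binary conversion-cost
matrices (rows = from, columns = to, legend order A F G W C U),
neighborhood weights, restricted (RDA) classes, and multiplicative
probability modifiers (S3: forest→construction ×0.6,
construction→water ×2.2, water→construction and water→cropland ×0).
After applying modifiers and cost-matrix zeroing, each row is re-balanced
by assigning the deficit or surplus to the diagonal, then clipped and
renormalized. Routing the imbalance to self-persistence (rather than
rescaling the whole row) keeps "reduced by 40 %" literally true for the
targeted entry.

Two published inconsistencies are represented as-is rather than
reconciled: the S1 construction row permits conversions although the
accompanying narrative says construction cannot convert, and the S2 cost
matrix does not by itself encode the forest/water freeze (the freeze is
carried by the RDA set instead). "Restricted" is interpreted as freezing
all cells of the protected class — cells of other classes may still
convert *into* a protected class. Both choices are configurable through
`ScenarioConfig`.

## CA allocation

The allocator converts cells from over-supplied to under-supplied classes
until counts meet demand. A candidate conversion of cell x to class t
scores

    score(x, t) = P_occ(t | x) · (Ω_t(x) + δ) · inertia_t

- `P_occ` — per-class occurrence probability from a multinomial logistic
  model on standardized drivers (default; deterministic and fast), or a
  one-hidden-layer MLP (12 units) where a neural estimator is preferred.
  Fitting uses a balanced, seeded sample (default ≤ 2000 cells per class);
  a class present with fewer than 10 cells is an error.
- `Ω_t` — weighted same-class density in a 3×3 Moore window (centre
  excluded), the class's neighborhood weight taken from the scenario
  table. The floor δ = 0.01 lets classes with zero weight (cropland, per
  the published table) or no local presence still receive cells; without
  it a zero neighborhood term would veto them entirely.
- `inertia_t` — starts at 1; when a class's demand gap keeps its sign two
  iterations running, the coefficient is multiplied (under-supply) or
  divided (over-supply) by `1 + |gap|/demand`, bounded to [0.1, 10]. This
  is a simple self-adaptive rule with the qualitative behaviour expected
  of macro-level demand feedback.

Only transitions permitted by the cost matrix occur; RDA cells are never
touched. At most 1 % of cells convert per iteration (max 500 iterations)
to prevent oscillation. `greedy` mode takes candidates in strict score
order and is fully deterministic; `roulette` mode samples candidates with
probability proportional to score via the Gumbel top-k construction,
reproducible under a fixed seed. A run that stalls with any residual gap
above 0.5 % of the cell count raises an error carrying the per-class
residuals. Because scenario demands can ask a frozen class to shrink
(which frozen cells cannot do), the pipeline clamps restricted-class
demands to at least their current counts and removes the surplus from the
non-restricted demands proportionally before allocating.

## Annual water yield

Budyko–Fuh water balance per cell: `ω = Z·AWC/P + 1.25`,
`AET/P = 1 + PET/P − (1 + (PET/P)^ω)^{1/ω}` (clipped to [0, 1]),
`yield = (1 − AET/P)·P` in mm. The seasonality constant Z defaults to 10
(mid-range monsoon-climate value; valid range (0, 30]). Cells with
non-positive precipitation are flagged nodata with a warning count. Totals
convert as 1 mm on a 500 m cell = 250 m³. No per-class evapotranspiration
coefficients enter the formula — yield depends on climate and soil only —
and no flow routing is performed (all cell yield is assumed to reach the
outlet). The exponent form `(PET/P)^ω` is the standard dimensionless
Budyko argument.

## Habitat quality

Degradation of habitat cell x of class j sums over threats r and threat
cells y: `D_x = Σ_r Σ_y (W_r/ΣW)·max(0, 1 − d_xy/d_rmax)·β·S_jr`, with
Euclidean centre-to-centre distances, linear decay only, and no per-threat
averaging over the number of source cells. The implementation evaluates
the inner sum as a spatial correlation with the decay stencil, which is
exactly the pairwise double loop (the tests verify equality to 1e-12
against a brute-force oracle). β (legal protection/accessibility) is 1 by
default and may be supplied as a raster.

Quality is `Q = H_j·(1 − D^z/(D^z + k^z))`: z defaults to 2.5 (the
conventional value for this saturation curve); the half-saturation
constant k defaults to half the maximum observed degradation, falling
back to 0.5 with a warning when D is identically zero. **Comparisons
across maps must use one k**: the pipeline derives k from the baseline
map and reuses it for every scenario map of the same run, since per-map
auto-k would place each map on its own quality scale. The default threat
set — construction (weight 1.0, reach 3000 m) and cropland (weight 0.6,
reach 1500 m) — ships as an editable CSV; no threat table is published
for the study system, so these are explicit, reproducible assumptions.

## Carbon storage

Per-cell stock is the cell area in hm² (25 hm² at 500 m) times the summed
four-pool density (aboveground, belowground, soil, dead organic matter;
t/hm²) of the cell's class. Stock change between two maps is the per-cell
difference, and the flow breakdown attributes the total exactly to
from→to class pairs. No published density table exists for the study
system; the shipped default preserves the standard ordering
(forest > cropland ≈ grassland > water ≈ construction) with a small
seeded jitter, and all tests use synthetic tables.

## Geographical detector

`q = 1 − SSW/SST` with population variances, so SSW and SST are plain
sums of squared deviations and q coincides exactly with one-way ANOVA R².
A constant response is an error (SST = 0). Significance defaults to a
seeded permutation test (≥ 999 shuffles recommended; p = (1+#{q* ≥ q})/
(1+B)). The analytic alternative is the equivalent central-F ANOVA test
via `F = (N−L)/(L−1)·q/(1−q)`; a noncentral parameterization with the
noncentrality estimated from the observed stratum means was rejected
because it compares the statistic against its own sampling distribution
rather than testing q = 0.

OPGD searches 4 discretization methods (equal-interval, quantile,
natural-breaks via deterministic 1-D k-means, geometric/log-spaced on the
shifted range) × 3–8 classes, keeps the maximal-q stratification, skips
candidates that leave a stratum empty, and breaks ties toward fewer
classes then method order. The interaction detector overlays two
stratifications (distinct label pairs) and classifies q(a∩b) against q_a,
q_b into the five standard categories (tolerance 1e-9 on the independence
equality). Note that a pure overlay refines both stratifications, so
weakening categories cannot arise from overlay alone; they require
re-discretized inputs.

## Synthetic landscapes

The generator emulates the structural features the pipeline is sensitive
to, on a default 150×200-cell canvas at 500 m (~7500 km², the order of
magnitude of a large prefecture-level study area): spatially
autocorrelated driver surfaces (Gaussian-smoothed white noise, default
correlation length 6 cells), elevation rising toward one corner with
slope/aspect from finite differences, distance rasters to a city centre,
county centres, rasterized road/rail polylines and a buffered random-walk
river corridor, population/GDP decaying from the centre, and smooth
precipitation/PET gradients with positive AWC.

Land use is assigned by per-class affinity over the drivers (construction
core near the centre, cropland ring, forest periphery at elevation, water
along the corridor) under a quota-matching bias search; realized shares
land within ~1 pp of the target (default 27/41/2/8/22/0 %, echoing a
cropland/forest/construction-dominated 2020-style structure). The second
epoch applies a planted row-stochastic transition exactly (up to integer
rounding), placing conversions preferentially at cells most suited to the
destination class. The default planted matrix mirrors rapid-urbanization
change — construction growth fed mainly by forest (0.06 per step) and
cropland (0.035), near-inert construction — so the scenario contrasts
(S1 forest loss and carbon decline, S2 recovery) emerge from the rules
rather than being imposed.

Not emulated: real geography and hydrography, class patch-size
distributions, multi-temporal driver change, observation error in the
rasters. Passing tests therefore demonstrate correctness of the
algorithms and the stated statistical contracts on landscapes with known
structure, not predictive skill on any real region.

## Problem sizes and determinism

Tests run the full chain at 150×200 where a contract concerns full-scale
recovery (transition estimation) and at 40×80-class scales elsewhere;
the seeded scenario-ordering study uses 50 replicates at 60×80 and the
acceptance script one run at 100×130. Every stochastic component draws
from `numpy` generators seeded from the user-facing seed; greedy
allocation, logistic fitting and the permutation test are exactly
reproducible, and two pipeline runs with the same config and seed write
byte-identical summaries.

## Known limitations

- The CA is cell-based; patch-growth or road-driven growth mechanisms are
  not modelled.
- Demand comes only from the Markov chain (optionally scenario-modified);
  exogenous planning totals are not supported.
- Only linear threat decay; no habitat-rarity weighting.
- Water yield ignores land cover by construction of the formula, so
  scenario maps differ in water yield only through climate/soil inputs,
  not land-use change.
- The geodetector assumes an aligned, complete driver stack; q carries no
  correction for spatial autocorrelation, so its significance on strongly
  autocorrelated responses is optimistic — the permutation test shuffles
  cells independently.
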