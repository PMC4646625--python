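# Methods

## Data model

A census table is a three-level hierarchy (national → state → county). Every
unit carries a paired frequency distribution over seven farm-size bins —
1–24, 25–49, 50–99, 100–199, 200–499, 500–999, ≥ 1000 head — with a farm
count `n_b` (always published) and a population subtotal per bin, plus a
population total. Population values may be redacted; the file format encodes
redaction with the NASS sentinel `(D)`, and internally redaction is a tagged
singleton, never a magic number, so files round-trip bit-identically.
Identifiers are zero-padded FIPS-style strings (2-digit states, 5-digit
counties, `"00"` for the nation).

Any redacted cell is bounded: `n_b·lower_b ≤ cell ≤ n_b·upper_b`, with the
top bin's upper bound replaced by a cap — the unit's own published total
when available, otherwise its parent's. These bounds are used everywhere:
seeding, raking clamps, validation.

## Missing-data model

Imputation is raking (iterative proportional fitting) customized in three
ways for redacted hierarchical data:

1. **Midpoint seeding.** A redacted bin cell starts at `n_b·(lower+upper)/2`
   (top bin: midpoint of its bounded range, clamped); a redacted total
   starts at the sum of its cells. Seeded row totals are then reconciled so
   the children of each parent sum exactly to the parent total
   (proportional scaling within row bounds, then largest-remainder
   integerization restricted to the seeded totals). This makes the
   hierarchy identity exact by construction.
2. **Pinned published cells.** The raking equations describe plain
   alternating row/column rescaling; published values must never move, so
   after each multiplicative pass published cells are restored and the
   row's (or column's) residual is re-absorbed proportionally by its seeded
   cells, clamped to their feasibility bounds. With every cell seeded and
   no bounds this reduces exactly to classical raking (verified against a
   brute-force iterator to 1e-9).
3. **Bounded integerization.** Final cell values are integerized by
   largest-remainder within each row, restricted to seeded cells, with a
   correction walk so each row sums exactly to its total while staying in
   bounds.

Convergence: iteration stops when the largest marginal discrepancy is
≤ 0.5 animals (integer data; exact zero is unattainable in floating point)
or at 2,000 iterations. Because rows are pinned to integer totals while
columns are the parent's bin subtotals, a residual column mismatch of one
or two animals can be irreducible; the loop detects a discrepancy plateau
(no improvement over 50 iterations) and stops early rather than burning the
full iteration budget. Row sums — the quantities that propagate through the
hierarchy — are exact after integerization regardless.

The two-step order (states against the nation, then counties against the
completed states) means each county-level raking problem has a fully
published column marginal. Imputation involves no randomness.

## Distribution model

Standard information-theoretic workflow for presence/absence data:

- **Collinearity screen:** pairwise Spearman correlations; for each pair
  with |r| ≥ 0.7 one member is dropped, with a caller-supplied preference
  order breaking ties (e.g. keeping distance-to-roads over
  distance-to-development).
- **Form choice:** each covariate enters linearly or as its square,
  whichever has the lower AIC in a single-covariate logistic fit; ties go
  linear. "Quadratic" means the squared term alone — the printed national
  equation contains x² terms without paired linear terms.
- **All-subsets + averaging:** every subset of the screened global model is
  fitted (capped at 15 covariates), ranked by AIC, and coefficients are
  averaged with Akaike weights over the ΔAIC ≤ 2 window. Averaging is
  full-model (shrinkage): a coefficient contributes zero from models that
  omit its term, and the intercept is averaged with the same weights. This
  is the conservative default when the conditional/full choice is not
  dictated.
- Logistic fits use statsmodels' Newton solver with a BFGS fallback for
  (quasi-)separated designs; non-convergent subsets are skipped with a log
  entry.

The built-in national swine equation carries the ten model-averaged
coefficients and intercept −5.63×10⁻² (distances in meters, temperature in
°C, precipitation in mm, slope in degrees). At an all-zero covariate vector
it predicts p ≈ 0.486.

**Evaluation.** AUC is computed from the rank (Mann–Whitney) statistic with
tie averaging. Cross-validation refits the entire selection + averaging
pipeline on each training split (5 folds, seeded uniform shuffle; a
single-class fold triggers a logged reshuffle). Variable importance is
permutation-based — the holdout AUC drop when one covariate's values are
shuffled — reported per fold with mean and standard error; it is a standard,
reproducible choice where no importance statistic is dictated, so only rank
behaviour (not magnitudes) is comparable across implementations.

## Simulation model

**Disaggregation.** Within each bin of a completed unit, `n_b` farm sizes
are drawn i.i.d. U(a, b) — a null distribution assuming nothing beyond the
bin bounds — and raked one-dimensionally to the bin's population subtotal:
multiplicative rescaling toward the subtotal, out-of-bin values clamped to
the violated bound and nudged 10 % of the bound-to-midpoint distance inward
(preventing oscillation at the bounds), repeated until the residual is
below 0.5 or 2,000 iterations; then largest-remainder integerization with a
bounded correction walk makes the sum exact. Enforcing each bin's subtotal
(rather than only the unit total) guarantees both bin sums and the grand
total exactly, for every seed. The top bin's draw ceiling is the unknown
population available to one farm: the bin subtotal minus the 1,000-head
minimum of each of its other farms.

**Placement.** Farms are placed per county, largest size class first. Each
farm draws a target probability from the empirical pool of model-predicted
values at observed presence points — real farms do not always sit at the
highest-probability pixels, and sampling the pool reproduces that spread.
The farm then lands uniformly on an available county pixel whose
probability lies within ±δ·target of the target, δ doubling from 0.01 until
candidates exist. The window is multiplicative because occurrence
probabilities from distance-based covariates are strongly log-skewed
(typical values 1e-4 against maxima near 1e-2); an additive window wider
than the bulk of the distribution would decouple chosen pixels from their
targets, and the chosen-pixel distribution would no longer match the pool.
Placed farms claim square exclusion windows — 5×5 pixels (25) for the
≥ 1000-head bin, 3×3 (9) for the five intermediate bins, none for 1–24-head
farms — interpreted as centered squares since only the pixel counts are
dictated. Windows apply across county borders by default (a config toggle);
farms themselves never leave their county, since the aggregate data are
county-level and cross-county placement would break reaggregation. If a
county exhausts available pixels, windows are relaxed to single pixels; if
pixels are still exhausted the county errors out listing the unplaced farms.

All randomness streams from a single 64-bit run seed, split per unit by a
CRC32 of the unit id, so county outputs are independent of processing order
and runs are reproducible bit-for-bit.

Coordinates are pixel centers in decimal degrees through an affine
north-up geotransform; the synthetic landscape uses a 0.001°/pixel grid
anchored at (−100°, 45°).

## Synthetic data

The generators define the conditions everything is tested under:

- **Census:** county farm counts are Poisson with per-bin means
  (20, 2, 1.2, 0.8, 1, 1, 5) across 10 states × 8 counties; within-bin farm
  sizes are uniform on the bin, Pareto-tailed (shape 2.5, scale 1,000,
  capped at 200,000) in the unbounded bin so most animals sit on few large
  farms; states and the nation are exact sums. Redaction mirrors disclosure
  practice: the smallest counties (below a 25-farm threshold) are redacted
  until ~19 % of county totals are withheld, a complementary-suppression
  partner is added whenever a lone redacted county would be recoverable by
  subtraction, bin cells with 1–2 farms are also withheld, and one state in
  ten is redacted to exercise the two-step hierarchy. Bin-cell redaction is
  more extensive here than in the real census; the county-total rate is the
  calibrated scenario quantity.
- **Landscape:** ten named covariates as seeded low-frequency cosine
  mixtures, `f(r,c) = Σ_k a_k cos(2π(u_k r/R + v_k c/C) + φ_k)` with six
  waves and |u|,|v| ≤ 3, min-max normalized and scaled to plausible ranges
  (e.g. distance-to-roads 0–3,000 m, temperature 0–25 °C). The true
  occurrence logit is the configured model applied to these fields plus
  white unobserved-heterogeneity noise (sd 3.5 on the logit scale) and an
  intercept shift so the landscape-mean occurrence equals the target
  prevalence (0.14). The noise level was fixed once so that an ideal scorer
  attains AUC ≈ 0.80 — the "good, not excellent" discrimination regime real
  farm-location data exhibit; without it a smooth noiseless landscape is
  unrealistically predictable. The exclusion mask is a thresholded smooth
  field covering 10 % of pixels; counties tile the grid as rectangles.
- **Sample:** points are allocated to counties proportional to farm counts,
  pixels drawn uniformly within county, labels Bernoulli(true surface), and
  the sample is thinned/augmented by class to the target prevalence at the
  target size (10,000). Class-balanced thinning is case-control sampling:
  it shifts the intercept but leaves slope coefficients estimable.

What the generators do **not** emulate: real U.S. geography and county
shapes, spatial autocorrelation in the unobserved heterogeneity, NASS's
actual suppression algorithm, within-county sampling weights, and the
aerial-photo measurement process. Passing tests therefore demonstrate
algorithmic correctness and statistical behaviour under known ground truth,
not predictive accuracy on real landscapes.

## Verification

Absolute percent difference, `APD = 100·|estimate − reference|/reference`,
with 0/0 defined as 0 and positive/0 flagged undefined and excluded from
means (with a count). Reaggregation sums fine-level values into groups and
compares against reference totals; per-level summaries average county
values within state and report at the state level. The substitution
analysis re-redacts k randomly chosen published values (bin cells or
totals, never national) from a completed table, re-imputes, and measures
the APD of recovered state totals across repetitions — stability across
patterns shows the imputation does not depend on which cells happen to be
missing. Because the hierarchy reconciliation is exact, a lone redacted
value among published siblings is recovered by forced subtraction and the
typical substitution APD is zero to a fraction of a percent.

## Problem sizes and numerical choices

Test and acceptance runs use the scenario defaults above (80 counties,
120×160 to 400×400-pixel landscapes, samples of 3,000–10,000 points,
10,000 placements, 50 replicates for coefficient recovery at n = 10,000) —
sizes chosen so every stage runs in seconds to a few minutes on one core
while keeping Monte-Carlo error well inside the asserted tolerances.
Raking tolerance is 0.5 animals; oracle comparisons are at 1e-9; surface
predictions are closed-form and compared at 1e-12. Degenerate inputs are
handled explicitly: empty bins are pinned at zero, a=b uniform draws are
constant, single-farm bins are forced to the subtotal, and infeasible
subtotals or marginals raise errors naming the offending unit.

## Known limitations

- Only the single population variable is imputed; multi-variable
  cross-classified raking with microdata (production types, age classes) is
  out of scope.
- The pinning scheme for published cells during raking is this package's
  own resolution of an under-determined design point; alternatives (e.g.
  soft constraints) could distribute rounding differently.
- Column (bin-subtotal) marginals at the parent level may be off by one or
  two animals after integerization; row totals and the hierarchy are exact.
- GeoTIFF I/O is not implemented; rasters are text ASCII grids.
- The placement pixel-selection rule (pool draw + multiplicative window) is
  one reasonable realization of probability-matched placement; the window
  shape of exclusion neighborhoods (squares) is likewise an interpretation
  of the stated pixel counts.
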