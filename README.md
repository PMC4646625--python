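# flaps

**Farm Location and Agricultural Production Simulator** — a spatial
microsimulation toolkit that turns aggregate, partially-redacted livestock
census tables into synthetic individual farms with georeferenced locations
and population sizes.

National-scale data on individual livestock farms do not exist for the U.S.:
the Census of Agriculture publishes only county/state/national aggregates,
and even those are partially withheld ("(D)") wherever a value could reveal
an individual operation. Yet epidemiological models, emergency-response
planning and biosecurity analyses all need farm-level populations and
between-farm distances. `flaps` closes that gap in three stages:

1. **Missing-data model** (`flaps.impute`) — hierarchical iterative
   proportional fitting (raking). Each census unit reports paired
   frequency distributions over seven farm-size bins (1–24, 25–49, 50–99,
   100–199, 200–499, 500–999, ≥ 1000 head); farm counts `n_b` are always
   public, so any redacted population cell is bounded by
   `[n_b·lower_b, n_b·upper_b]`. Redacted cells are seeded at bin midpoints
   and raked row/column-wise (rows = child units, columns = bins) against
   the child totals `Q_i` and parent bin subtotals `Q_j`:

   ```
   p_ij(k+1) = p_ij(k) / Σ_j p_ij(k) × Q_i
   p_ij(k+2) = p_ij(k+1) / Σ_i p_ij(k+1) × Q_j
   ```

   Published cells are hard constraints re-pinned every cycle; states are
   completed against the nation first, then counties against the completed
   states. Output is integer, hierarchy-exact and deterministic.
2. **Distribution model** (`flaps.sdm`) — logistic regression of farm
   presence/absence with Spearman |r| ≥ 0.7 collinearity screening,
   per-covariate linear-vs-quadratic form choice by AIC, all-subsets
   enumeration, and Akaike-weighted full-model averaging over candidates
   with ΔAIC ≤ 2. The published national swine equation (10 terms:
   distances to open areas, cropland, roads, temperature linear; slope,
   precipitation, distances to forest/urban/wetland/barren squared) ships
   as `builtin_swine_model()` and maps directly onto covariate rasters to
   give a 100 m occurrence-probability surface.
3. **Simulation model** (`flaps.disaggregate`, `flaps.placement`) — per
   bin, farm populations are drawn U(a, b) and raked one-dimensionally to
   the bin subtotal with exact sum-preserving integerization; farms are
   then placed on the probability surface by matching each farm to a pixel
   whose probability resembles a draw from the empirical pool of predicted
   values at observed presence locations, with exclusion neighborhoods
   (5×5 pixels for ≥ 1000-head farms, 3×3 for intermediate bins) and an
   urban/water mask.

A synthetic-data module (`flaps.synthetic`) generates hierarchically
consistent census tables with NASS-style redaction (small units plus
complementary-suppression partners), smooth covariate landscapes with a
known true occurrence model, and weighted presence/absence samples — so the
whole pipeline is testable without the restricted source data.
Verification utilities (`flaps.verify`) implement the reaggregation and
substitution analyses with the absolute-percent-difference metric.

## Worked example

```python
from flaps import census as cs
from flaps.disaggregate import disaggregate_unit
from flaps.impute import impute_all
from flaps.synthetic import SynthConfig, make_census

# disaggregate the published 2012 national swine distribution
rec = cs.national_2012_swine()
drafts = disaggregate_unit(rec, seed=42)
print("farms simulated:", len(drafts))
print("total head:", sum(d.population for d in drafts))
big = [d for d in drafts if d.bin == 7]
print("farms >= 1000 head:", len(big), "holding",
      sum(d.population for d in big), "head")

# impute a redacted synthetic census and check consistency
truth, observed = make_census(SynthConfig(seed=0))
complete = impute_all(observed)
print("violations after imputation:", len(cs.validate(complete)))
```

prints

```
farms simulated: 63246
total head: 66026785
farms >= 1000 head: 10401 holding 63248402 head
violations after imputation: 0
```

i.e. the 63,246 published farms are simulated individually, their summed
populations reproduce the published bin subtotals and the 66,026,785-head
national total exactly (for any seed — only the individual farm sizes vary),
and imputing a ~20 %-redacted table returns a complete table that passes
every structural check with state totals summing exactly to the national
total.

There is also a thin CLI:

```bash
flaps synth --seed 3 --out demo          # synthetic census + sample files
flaps impute --census demo.observed.csv --out demo.complete.csv
flaps run --census demo.observed.csv --scope state --scope-id 01 \
      --seed 4 --out farms.csv           # fips,state,lat,lon,population,commodity
flaps verify --mode subst --census demo.observed.csv --iters 100 --seed 1
```

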