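# Methods

This note documents the models, conventions and numerical choices behind
`carescape`, and what its synthetic benchmarks do and do not establish.

## Data model

The panel is long-format: one record per (city, region, area, year,
indicator), with values kept exactly in yearbook units (counts; 10⁴ m²; 10⁴
beds/persons; days; percent). The ratio- and difference-based statistics are
unit-invariant, and the packaged national tables must match their printed
source, so no unit conversion is ever applied. Validation flags (rather than
drops) unparseable values, negative quantities and percentages outside
[0, 100]; duplicate keys and unknown indicators are hard errors. The three
proportional share groups are *not* forced to sum to 100 — the printed
national tables themselves do not (urban self-care shares in 2010 sum to
84.06) — but a group summing above 100.5 triggers a warning.

### Missing data

Two imputation primitives are provided, mirroring the stated practice of
"averaging and trend extrapolation": `mean` (series mean of observed years)
and `trend` (linear extrapolation from the two nearest observed years at the
boundaries, linear interpolation inside). The default policy applies trend
extrapolation to boundary years and the series mean to interior gaps, since
the source names both methods without assigning them. Imputed values are
clipped to the indicator's domain, carry an `imputed` flag, and a series
with no observed values at all is left missing (it will later fall under the
zero-assignment rule in the spatial stage).

## Weights and scores

Weights are exact `Fraction`s: 1/17 base, and (3/17)×share inside the three
redistribution groups. Rounding to 4 decimals happens only at display time;
this reproduces all printed values (0.0882 = (3/17)·0.5, 0.0618 = (3/17)·0.35,
…) and keeps Σω = 1 exact.

Standardization defaults to a **single min–max frame per indicator across
all cities, both area types and all years** (`all_years_both_areas`). The
published analysis compares composite scores across years and divides urban
by rural scores, which is only meaningful in a common frame; since the
source never states the pool, a `per_year_per_area` option is also provided.
A pool with max = min raises a degenerate-scale error naming the indicator.

The overall score is always the flat dot product Z = Σ ω_i d_i. Secondary
and primary sub-scores renormalize their subtree weights to the subtree
total so each sub-score lies in [0, 1]; this scale is a package convention —
the source computes sub-scores "by the same formula" without fixing one.
Incomplete city/years default to `propagate` (score = NaN, handed to the
spatial zero-assignment rule); `renormalize` and `strict` are available.

## Difference statistics

* Time ratios use the first year as base; if the base value is missing or
  zero the next usable year substitutes (logged), matching the stated
  fallback for cities with unrecorded initial years.
* Display rounding is half-away-from-zero to 2 decimals, which reproduces
  the printed values (1.54 from 1.5379, −52.47); a small relative nudge
  (1 + 1e−12) guards against binary-representation artifacts such as
  2.675 × 100 = 267.4999…
* Ranking bands use ceiling sizes (top = bottom = ⌈0.2 n⌉; 276 → 56/164/56)
  and break score ties by city id ascending; the source states neither rule,
  and these make the output deterministic.
* The coefficient of variation uses the sample (n−1) standard deviation.

### Fidelity of the published difference tables

The packaged national tables are stored to printed precision. Recomputing
the ratio table from them reproduces every printed cell at 2 decimals
except three cells of the urban days-of-stay row, and recomputing the
percentage-point table reproduces 64 of 77 cells exactly with the rest off
by exactly ±0.01. Both residuals are print artifacts of the source: the
published ratio/difference tables were evidently computed from unrounded
data while the input tables were printed rounded (the days row maps the
identical printed input 239/237 to two different printed outputs, 1.01 and
1.00, so no recomputation from the printed inputs can match every cell).
The tests therefore assert exact 2-dp equality wherever the printed inputs
support it and agreement within one unit in the last printed place
elsewhere.

## Spatial statistics

* **Weights.** The source does not specify W. The default is binary
  k-nearest-neighbour (k = 5) on great-circle centroid distance,
  row-standardized; distance ties break by city order. k-NN leaves no
  islands; an island would carry lag 0 and classify insignificant.
* **Global Moran's I** uses the standard univariate cross-product form (the
  printed formula's second variable is treated as the presumed typo it is).
  The analytical variance is computed under the randomization (permutation)
  assumption — it matches the exhaustive-permutation variance exactly at
  tiny n — and inference is permutation-first: pseudo-p =
  (1 + #{I_perm ≥ I_obs}) / (1 + n_perm), default 999 permutations.
* **Local Moran's I** standardizes with the population (n) denominator so
  Σ I_i = S0 · I holds to machine precision. Per-city p-values use
  conditional permutation (city i fixed, the other n−1 values resampled
  onto its neighbour positions without replacement), folded to the nearer
  tail. Classification at α = 0.05 by the quadrant of (z_i, lag_i); no
  multiple-testing correction is applied, as none is in the source method.
  Boundary cases (z = 0 or lag = 0) classify insignificant.
* **Zero assignment.** Cities with missing composite scores are set to 0
  and flagged before both global and local analysis; the flag propagates to
  the LISA output so contiguous artificial Low-Low blocks can be discounted.

## Synthetic data generator

The generator defines the study conditions for all stochastic tests:

| parameter | default | meaning |
|---|---|---|
| `n_cities` | 276 | prefecture-level cities |
| `years` | 2010–2016 | study window |
| `region_counts` | 33/86/77/80 | NE/E/C/W city counts |
| `rho` | 0.6 | SAR spatial-lag coefficient |
| `east_gradient` | 0.5 | latent-level offset per SD of longitude |
| `noise_sd` | 1.0 | SAR innovation SD |
| `missing_rate` | 0.05 | MCAR missing fraction |
| `k_neighbors` | 5 | weight-matrix k |
| `share_spread` | 0.8 | city-size dispersion (log scale) |
| `proportion_sd` | 0.3 | logit-scale noise of percentage indicators |
| `latent_effect` | 0.25 | logit effect of latent level on development-positive shares |
| `measurement_sd` | 0.15 | lognormal measurement noise of quantities |

Cities sit on a jittered grid in a China-like bounding box; region labels
are assigned deterministically (westernmost → Western; highest-latitude
remainder → Northeast; easternmost remainder → Eastern; rest → Central) to
honour the configured counts — stylized geography, not an atlas. Each
area's latent level is a SAR field plus the east gradient, standardized to
mean 0, SD 1. Quantity indicators share out the national 2010 anchors
proportionally to exp(0.8 · latent) with annual multiplicative trends
defaulting to the anchored national 2010→2016 ratios (so urban counts grow
and rural counts shrink by construction) and lognormal noise; the national
2010 totals therefore land within ±20% of the anchors. The days-of-stay
indicator, being a per-city mean, is generated around the national value
directly. Percentage indicators are logistic-normal perturbations of the
national year profiles, with the latent effect applied to the
development-positive shares (university education, under-35 staff,
self-financing residents), group-rescaled onto the simplex when a three-way
group would exceed 100, and clipped to [0, 100]. Missingness is MCAR —
adequate for exercising imputation and zero-assignment, but not a model of
the real (plausibly systematic, contiguous) gaps in yearbook coverage.

ρ = 0.6 with k = 5 yields observed global Moran's I around 0.25–0.35 on
composite scores, the order of magnitude the published city-level analysis
reports; the defaults were fixed from these anchors, not tuned per test.

**What passing tests show.** Oracle equivalence, calibration (rejection
rate ≈ α under independence), power against ρ = 0.8, monotonicity of mean I
in ρ, and latent-level recovery (corr > 0.7 between true levels and computed
scores) validate the machinery under the generator's assumptions. They do
not validate the published city-level magnitudes (band shares, score
levels, Moran/z values, city lists, CVs ≈ 0.28/0.16), which depend on the
non-public yearbook microdata and on the authors' unstated weight matrix.

## Problem sizes

The test suite runs the oracle comparison on 100 random instances (n ≤ 50),
permutation calibration on 500 replicates of the 276-city map with 199
permutations each (199 suffices for a size-0.05 test; 999 is the analysis
default), power and recovery on 100–200 replicates, and one full-scale
(276 cities, 999 permutations) end-to-end pipeline run — sizes chosen so
the whole suite completes in well under a minute while keeping Monte-Carlo
error far below the asserted margins.

## Known limitations

* The four-region map and centroid k-NN weights are stand-ins; with real
  administrative polygons, queen contiguity would be the natural W.
* Secondary-score scales in the published comparison table are not
  reproducible (the source's scale is unstated); the package emits its own
  0–100 convention.
* Imputation is per-series and linear; no cross-indicator or spatial
  borrowing.
* The generator's calibration targets national aggregates only — city-level
  size distributions are a modelling choice (lognormal), not estimated.
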