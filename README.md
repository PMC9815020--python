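# carescape

Measurement and spatial analysis of urban–rural disparities in the
development of elderly-care institutions across Chinese prefecture-level
cities.

China's institutional elderly-care system is split between an urban sector
that has expanded rapidly since 2010 and a rural sector — historically built
around state-supported care for the "three noes" elderly (no labour
capacity, no income, no family support) — that has contracted. `carescape`
implements the full measurement-and-inference chain used to quantify that
divergence from civil-affairs yearbook panels: a weighted composite
development score per city, three urban–rural difference statistics, and
global/local spatial autocorrelation with LISA cluster classification. It is
aimed at health-services and regional-inequality researchers who work with
city × year × indicator panels.

## The method

**Composite score.** Each city/area/year is described by 17 tertiary
indicators (6 quantity indicators — institutions, floor area, beds, staff,
residents, mean days of stay — and 11 percentage indicators of staff and
resident structure). Indicators are range-standardized over a declared
comparison pool,

    d_ij = (x_ij − x_min) / (x_max − x_min),

and aggregated with expert weights ω_i into the composite score

    Z = Σ_i ω_i · d_ij ∈ [0, 1].

Weights start from the equal base 1/17 ≈ 0.0588; the three proportional
groups (staff age structure, resident nature, self-care ability) then split
their pooled weight 3/17 by shares 0.5/0.3/0.2, 0.2/0.3/0.5 and
0.2/0.35/0.45, giving e.g. 0.0882 for the under-35 staff share. The weights
are carried as exact fractions and sum to exactly 1.

**Urban–rural differences.** Quantity indicators are compared as base-year
ratios T_t = S_t / S_2010; percentage indicators as differences
P = P_urban − P_rural (percentage points); composite scores as the ratio
Z_urban / Z_rural. Cities are also ranked into top 20% / middle 60% /
bottom 20% bands with regional membership shares, and score dispersion is
summarized by the coefficient of variation.

**Spatial autocorrelation.** On a k-nearest-neighbour weight matrix W built
from city centroids (k = 5, row-standardized, great-circle distance),

    I = (n / S0) · Σ_ij W_ij (x_i − x̄)(x_j − x̄) / Σ_i (x_i − x̄)²

with E[I] = −1/(n−1) under spatial randomness; inference is by permutation
(pseudo p-values). Local Moran's I, I_i = z_i Σ_j W_ij z_j, decomposes the
global statistic (Σ_i I_i = S0 · I exactly) and classifies each city as
High-High, High-Low, Low-High, Low-Low or insignificant via conditional
permutation. Cities with missing scores are assigned zero beforehand and
flagged, so artificial Low-Low blocks can be excluded from interpretation.

Because the city-level yearbook microdata are not machine-readable, the
package ships the published national urban/rural aggregate tables
(2010–2016) as fixtures and includes a synthetic-data generator that
emulates the study conditions: a 276-city map in the four macro-regions
(Northeast/Eastern/Central/Western = 33/86/77/80), spatially autocorrelated
latent development levels from a SAR process u = (I − ρW)⁻¹ε with an
east-coast gradient, urban-growth / rural-shrinkage trends anchored to the
national aggregates, and configurable missingness.

## Worked example

```python
import carescape as cs

# published national aggregates -> difference tables
tables = cs.load_fixture_tables()
print(cs.time_ratio_table(tables).loc["urban"].loc[["n_institutions", "floor_area"]])
#                 2010  2011  2012  2013  2014  2015  2016
# n_institutions   1.0  1.02  1.14  1.25  1.35  1.36  1.54
# floor_area       1.0  1.23  1.43  1.74  2.11  2.29  2.67

# synthetic 276-city study, scored and tested for spatial clustering
ds = cs.generate_panel(cs.SyntheticConfig(seed=42))
panel = cs.impute_missing(ds.panel)
scheme = cs.build_weight_scheme()
scores = cs.composite_score(cs.minmax_standardize(panel, scheme), scheme)
W = cs.build_knn_weights(ds.geometry, k=5)
z, flags = cs.impute_missing_zero(scores.series("urban", 2016).reindex(W.ids))
gm = cs.global_moran(z, W, n_perm=999, seed=1)
print(f"I={gm.I:.4f}  E(I)={gm.expected:.4f}  z={gm.z_score:.2f}  p={gm.pseudo_p:.4f}")
# I=0.2945  E(I)=-0.0036  z=8.23  p=0.0010
```

The ratio rows say urban institution counts grew 1.54-fold and floor area
2.67-fold over 2010–2016. In the synthetic study, Moran's I = 0.29 against
an expectation of −0.0036 (z = 8.2, pseudo-p = 0.001, the minimum attainable
with 999 permutations): urban composite scores cluster spatially, as the
generator's ρ = 0.6 SAR field intends. Classifying local statistics at
α = 0.05 yields 25 High-High cities, 18 of them Eastern — the synthetic
analogue of the coastal high-development clusters.

The same chain is available from the shell:

```sh
carescape generate --seed 42 --outdir data/
carescape run --synthetic-seed 42 --outdir reports/
carescape compare reports/time_ratios.csv my_reference.csv --index-cols 2
```

`carescape run` writes the full report bundle (composite scores, regional
bands, secondary-score comparison, time-ratio and percentage-point tables,
global Moran table, LISA table and category counts, plus a manifest) and is
byte-reproducible given the seed.

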