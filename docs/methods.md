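# Methods

This note documents the models and procedures implemented in `browndry`, the
choices behind them, and what the synthetic experiments do and do not show.

## Problem and data model

The package asks two questions about gridded annual series of vegetation
greenness (leaf area index, LAI) and hydro-meteorological variables:

1. **Where does vegetation browning coincide with multi-variable drying?**
   Browning is a decreasing LAI trend; drying is decreasing water
   availability (root-zone soil moisture, precipitation) or increasing
   atmospheric water demand (vapor pressure deficit, dryness index).
2. **Which drivers dominate inter-annual LAI dynamics?** Answered per grid
   cell by a regression-ensemble attribution over ten candidate predictors.

All stages exchange fields on a common `(lat, lon, year)` grid with annual
resolution over a multi-decadal period (default 1982–2020, split into the
halves 1982–2001 and 2002–2020). Real products at this resolution exist
(satellite LAI, reanalyses, merged precipitation, CMIP6 output), but the
package ships a synthetic generator instead, because only constructed data
provide verifiable ground truth for every stage.

## Derived water variables

**Vapor pressure deficit** is computed from air and dew-point temperature
with the Magnus form of the saturation vapor pressure,
`e_s(T) = 0.6108 exp(17.27 T / (T + 237.3))` (T in °C), and
`VPD = e_s(T) − e_a(T_d)`. With the 0.6108 coefficient both pressures are in
kPa; an optional flag returns pascals. Cells with `T_d > T` (a data
artifact) are clipped to `VPD = 0` and counted, never silently altered.

**Dryness index** is net radiation over energy-equivalent precipitation:
`DI = R_n / (λ P)` with λ = 2.45 MJ kg⁻¹ and precipitation converted from
mm yr⁻¹ (≡ kg m⁻² yr⁻¹) to W m⁻² using 365.25 × 86400 s per year. The
conversion constant is a package choice (only "unit-adjusted precipitation"
is prescribed); it scales the index but not its trends or their signs, which
are all the drying classification uses. `DI > 1` marks energy surplus
relative to water supply. Zero-precipitation cells become missing, with a
count.

## Trend detection

Per cell and period, the Mann–Kendall test:
`S = Σ_{i<j} sign(x_j − x_i)`, variance with the tie correction
`var(S) = [n(n−1)(2n+5) − Σ_k t_k(t_k−1)(2t_k+5)]/18`, continuity-corrected
deviate `z = (S∓1)/√var(S)`, two-sided p-value from the standard normal.
Significance uses α = 0.1 per cell (no field-wise multiple-testing
correction, matching the analysis design this mirrors). Trend magnitude is
the Theil–Sen median of pairwise slopes (via `scipy.stats.theilslopes`);
the estimator choice is the package's own, made for robustness on short
noisy annual series. Missing values are dropped listwise within a cell;
cells with fewer than 10 valid years are excluded. The test's calibration
(type-I rate 0.10 ± 0.02 at n = 20) and exact agreement with an O(n²)
enumeration oracle are asserted in the acceptance suite.

Long-term (aridity-style) changes use the difference of half-period means
instead of a within-half trend, with significance from 300 random
re-partitions of the pooled values into pseudo-halves of the original
sizes; the observed difference is significant outside the null's strict
10th–90th percentile band, giving a nominal 20% null flag rate (verified by
simulation). The re-partition is drawn **without** replacement (a
permutation null); a with-replacement variant sits behind a flag because
the procedure's sampling scheme is ambiguous in prose descriptions of this
design.

## Drying agreement, greenness, coincidence

A cell's four water flags are: soil moisture or precipitation significantly
decreasing; VPD or dryness index significantly increasing. The cell is
*drying* when ≥ 2 of 4 flags agree (threshold configurable; a
significance-free variant supports sensitivity analysis). Greenness cells
are categorized by Theil–Sen slope sign × Mann–Kendall significance; an
exactly zero slope ties to nonsignificant greening so no fifth category
appears. Cells are masked from the study area when any decadal mean LAI
falls below 0.5 (calendar decades clipped to the year axis, so 1982–2020
yields 1982–1990, 1991–2000, 2001–2010, 2011–2020).

Coincidence maps intersect browning (significant by default) with drying.
Area statistics weight each cell by the cosine of its center latitude —
exact for the relative area of equal-angle grid cells. Spatial
correspondence between categorical maps (e.g. the 4-category greenness map
vs. a variable's direction × significance trend map) uses Cramér's V from
the cell-count contingency table, computed without continuity correction so
identical binary maps give V = 1.

## Driver attribution

Per cell, annual LAI is regressed on up to ten predictors: annual means of
soil moisture, precipitation, VPD, temperature, net radiation, shortwave
radiation, tree-cover fraction and crop fraction, plus the annual minimum
of monthly soil moisture and the annual maximum of daily temperature
(drought and heat-wave proxies). Predictors are normalized to (0, 1] by
dividing by their maximum; this only maps into (0, 1] for positive data, so
columns with non-positive maxima are rejected with a unit-conversion hint
(hence temperature is carried in Kelvin), and constant columns are dropped
from the search.

All 2^p predictor subsets (including intercept-only, which can never pass
the adjusted-R² filter and only anchors ΔAIC) are fitted by OLS through a
shared Gram matrix with batched solves; rank-deficient subsets are skipped
rather than pseudo-inverted so AIC stays comparable. `AIC = n ln(RSS/n) +
2k` with k counting intercept, slopes and residual variance; AICc is
available behind a flag for small-n work but AIC is the default. The model
ensemble keeps fits with ΔAIC < 2 **and** adjusted R² > 0.36 (both strict).
Within each model, explained variance is partitioned by the
Lindeman–Merenda–Gold (LMG) metric — the average sequential R² contribution
over all predictor orderings, computed by the subset-size-weighted sum over
2^(p−1) subsets, reusing the R² values from the all-subsets pass. Shares
are non-negative and sum to the model R² (asserted to 1e-8 against full
permutation enumeration). Per-predictor importance is the Akaike-weighted
mean of LMG shares over the ensemble, with share 0 where a predictor is
absent (a renormalizing variant is available behind a flag). The dominant
predictor is the arg-max; two or more predictors within 1e-9 of the maximum
flag a tie. The water-variable rank records the best rank among
{soil moisture, precipitation, VPD}; whether the soil-moisture annual
minimum counts as a water variable is configurable (default: no).

Attribution is exactly invariant to rescaling any raw predictor by a
positive constant, and fully deterministic.

## Ensemble voting

Per-member greenness/drying/attribution maps are combined per cell: the
modal trend category (requiring data from ≥ 5 members, a tie when two
categories share the maximal count), the fraction of members-with-data
simulating drying, and the modal dominant driver (low agreement when fewer
than 3 members share the mode; tie and low-agreement are distinct
statuses, with low agreement taking precedence at sub-threshold counts).
Voting is invariant to member order.

## Synthetic generator

Each driver is `baseline + trend·(year − year₀) + AR(1) noise`, with the
AR(1) process initialized from its stationary distribution
(sd/√(1−φ²)) so there is no burn-in. Per-variable sub-seeds are derived
from the run seed and a CRC of the variable name, so adding a variable
never perturbs the others. Rectangular lat/lon boxes override trend or
baseline regionally (last listed wins). Annual extremes are generated as a
positive offset from their annual-mean partner (min = mean − |offset|),
enforcing the ordering invariants by construction; sub-annual series are
never simulated because only annual aggregates enter the analysis. LAI is
`β₀ + Σ βᵢ·x̃ᵢ + ε` with x̃ the same divide-by-max normalization the
attribution uses, negatives clipped to zero and counted.

Default study conditions: 20 × 30 cells, 1982–2020, baselines and noise
levels chosen as realistic mid-latitude magnitudes (soil moisture
0.25 ± 0.013 m³ m⁻³, precipitation 900 ± 46 mm yr⁻¹, VPD ≈ 0.9 kPa,
temperature 288 K with +0.02 K yr⁻¹, etc.), with lag-1 autocorrelation
0.1–0.5. The demo scenario imposes a coupled drying box (soil moisture
−0.0025 m³ m⁻³ yr⁻¹, precipitation −8 mm yr⁻¹ yr⁻¹, VPD +0.012 kPa yr⁻¹)
whose magnitudes were set by a power calculation: a trend of ≈ 0.2 noise
standard deviations per year gives ~95% per-cell Mann–Kendall detection at
n = 19 and α = 0.1, so the box is recoverable without being trivial.
Inside the box LAI is strongly coupled to the water drivers; outside it
responds only to (trend-free) shortwave radiation. The regional coupling is
deliberate: if LAI were coupled to water variables globally, chance 19-year
driver trends would produce genuinely coincident browning-and-drying cells
anywhere, and the imposed region would no longer be a well-defined ground
truth for the recovery checks. A second box carries a low LAI intercept to
exercise the study mask.

**What the synthetic data do not emulate:** spatial correlation between
cells (fields are cell-wise independent), satellite artifacts (orbital
drift, cloud contamination), cross-variable physical consistency beyond
the imposed coupling (e.g. no energy balance linking radiation and
temperature), land-cover transition dynamics, or sub-annual variability.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under known conditions — not that real-world trends
would be detected at the same rates.

## Numerical choices

- RSS is floored at 1e-30 before the log in AIC so exact fits keep a
  finite, strongly negative AIC instead of −∞.
- Modal votes with equal counts report the smallest category code as the
  representative (deterministic) and set the tie flag.
- Bootstrap null percentiles use linear interpolation
  (`numpy.percentile` default); comparisons are strict.
- NetCDF output uses xarray's scipy backend (classic NetCDF3): 64-bit
  integers are stored as 32-bit and booleans as flagged bytes.
- All pipeline outputs are pure functions of (config, inputs, seed); reruns
  are bit-identical, which the test suite asserts by hashing artifacts.

## Problem sizes used in tests

Oracle-agreement checks run on thousands of short random series;
calibration checks use 10,000 replicates; recovery experiments use 4 × 8 to
20 × 30 grids with 39-year series and 7-member ensembles. These sizes were
chosen so the full verification remains a desk-scale computation while
keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The per-cell α = 0.1 with no field significance means ~10% of null cells
  show "significant" trends; area statistics inherit that base rate.
- AIC (not AICc) at n ≈ 19–39 under-penalizes complexity; the option
  exists because rankings can differ at these sample sizes.
- The LMG enumeration is exact but exponential; it is limited to 12
  predictors (the canonical set uses 10).
- Divide-by-max normalization ties the regression scale to the sample
  maximum, so importance comparisons assume a stable upper range.
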