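# Methods

## Tracer model

The pipeline treats each EA-IRMS capsule as a two-member isotope mixing
problem: cytoplasmic element mass is a blend of unlabelled tissue at the
background atom% and food-derived element at the food's atom%. From the
measured atom% `A`, background `A_bg` and food `A_food`:

```
E      = A − A_bg                      (atom% excess)
I_iso  = (E/100) · total element mass  (µg heavy isotope)
I_phyto = I_iso / ((A_food − A_bg)/100) (µg food-derived element; pC or pN)
```

`ratio_to_atom_percent` uses the exact form `100·R/(1+R)`; δ values are
mapped to ratios with `R_std·(δ/1000+1)` against VPDB
(R = 0.0112372) and atmospheric N₂ (R = 0.0036765). These equations and
constants are the standard forms of the isotope-tracer literature for this
kind of experiment; the derived natural-abundance backgrounds are
1.11123 atom% ¹³C and 0.36630 atom% ¹⁵N.

Design choices:

- **Backgrounds.** Default is the natural abundance implied by the
  standards; if measured unlabelled control capsules are present,
  `TracerIncorporation(background="controls")` learns the per-element mean
  of the controls instead, which is preferable because real "unlabelled"
  tissue deviates slightly from the standard scales.
- **Negative excess.** Control capsules can read slightly below background.
  The signed excess is preserved (`excess_raw`) for transparency, but mass
  quantities are computed from the zero-clamped excess so budgets cannot
  contain negative carbon.
- **Food enrichment.** Default 98 atom% for both isotopes — the enrichment
  of the label substrate. Algal isotope fractionation makes the true
  detritus value slightly lower; a measured detritus atom% can be supplied
  via `FoodSource`, and using the substrate value biases pC/pN marginally
  low (by the ratio of the two excesses, <2% for ≥96 atom% detritus).
- **Units.** Element masses in µg throughout; areal doses and pools in
  mg m⁻²; the single volumetric→areal conversion (×10 per cm of layer) is
  centralised in `to_areal`.

## Decalcification correction

Dissolving the calcite test with HCl leaves CaCl₂ in the dried capsule
(CaCO₃ + 2HCl → CaCl₂ + H₂O + CO₂, 1:1 molar), so the cytoplasm dry mass is
`measured − carbonate·(110.98/100.09)`. The carbonate mass is an explicit
input (CSV column `carbonate_ug`) rather than an assumed fraction, because
how it was quantified in any given lab workflow is not something the
arithmetic should guess; a correction that consumes the whole measured mass
raises an error instead of returning a non-physical weight. Pooled
replicates are represented simply as capsules with larger `n_individuals`;
dead individuals are excluded upstream (rows with no live specimens are
dropped with a logged warning).

## Allometric scaling

Power laws `Y = a·W^b` are fitted by ordinary least squares on natural-log
transformed data (statsmodels OLS; optional weights switch to WLS). No
variance or correlation structure beyond that is assumed — with replicate
capsules that are exchangeable within a day × fraction cell, log–log OLS is
the defensible default. The exponent's 95% interval is t-based;
`classify_scaling` calls a relation isometric when the interval covers 1,
hypo-/hyperallometric when it lies entirely below/above. The coefficient
`a = exp(intercept)` is reported back-transformed; `b` is invariant to the
log base and to rescaling of W (`a` transforms as `k^(−b)`, verified by a
property test). The default fit set uses the size-experiment capsules; the
inclusion set is a parameter, since content fits can also legitimately pool
single-pulse adults and juveniles from a constant-feed treatment.

Group comparisons use a two-sided Mann–Whitney U test. For `n1·n2 ≤ 400`
the p-value is exact under ties: the permutation distribution of U over all
C(n1+n2, n1) relabellings of the observed multiset is computed by a
subset-sum recursion over doubled midranks (midranks are integers or
half-integers, so doubling makes them exact integers), and the two-sided p
is the probability of a deviation from the null mean n1·n2/2 at least as
large as observed. Larger problems use the midrank normal approximation
with the standard tie correction and continuity correction. scipy's
implementation serves as an independent cross-check in the tests on
tie-free cases only (its exact method is invalid under ties).

## Population budgets and processing fractions

`extrapolate_pools` multiplies per-individual means per sieve fraction by
living densities (individuals cm⁻³ in the counted surface layer, default
1 cm) and sums over fractions per station. Stations whose total abundance
is too low for reliable fraction ratios can be excluded by name (a filter,
not hard-coded). Totals, per-fraction shares (summing to 100% per
quantity) and areal equivalents are all derived from the same per-fraction
table, so they are consistent by construction.

The processing fraction compares the population's areal pC accrual rate
(areal pool / incubation days) with a regional daily production flux. The
specific configuration behind any single reported "maximum" number —
which station, which sampling day's pools, which end of the production
range — is usually not recoverable, so `processing_matrix` reports the full
grid: each station plus the station sum, intake rates from each sampling
day and from the mean of the per-day rates, and both production bounds,
flagging the carbon maximum. Nitrogen fractions require a phytodetrital N
flux, derived from the C flux and the food's C:N mass ratio (default 5.6
from the `FoodSource` elemental fractions); because the measured pN:pC of
the population need not equal the food's N:C, the nitrogen fraction is not
forced to track the carbon fraction.

## Synthetic experiment generator

The generator exists so every downstream stage is testable without any
measured data, and its defaults are the study conditions the pipeline
targets:

| parameter | default | rationale |
|---|---|---|
| design | 3 fractions × 3 replicates × days (2, 4) | triplicate capsules, two post-pulse sampling days |
| individuals per capsule | 150 / 100 / 50 | more small specimens needed per capsule |
| median dry weight W | 0.8 / 2.5 / 6.0 µg | ~4× mass steps between sieve fractions |
| TOC = a·W^b | a = 0.2875, b = 0.90 | content scales almost isometrically |
| TN = a·W^b | a = 0.0573, b = 0.75 | nitrogen scales like metabolic rate |
| intake pC = amp·W^b·f(t) | amp = 0.0677, b = 0.57 | intake strongly hypoallometric |
| pN amplitude | 0.01286 | pN:pC ≈ 0.19 by mass |
| f(t), single pulse | (t/τ)·e^(1−t/τ), τ = 7 d | uptake peaks about a week after a pulse |
| f(t), constant feed | 1 − e^(−t/τ) | saturating standing stock under repeated feeding |
| noise | σ_log(intake) = 0.2, CV(TOC/TN) = 0.05, σ(atom%) = 0.01 | replicate scatter dominates; IRMS noise is minor |
| abundances | 105 / 136 / 4.5 ind cm⁻³ by station | small fraction dominates; one sparse station |

The allometric prefactors and intake amplitudes were calibrated once,
analytically, so that the day-mean pools extrapolated over the densest
station's abundances land at ~55 (TOC), ~10 (TN), ~7.9 (pC) and ~1.5 (pN)
µg cm⁻³ — the magnitudes such intertidal *Ammonia* populations reach in
spring. The second station's round-number densities then give pools of
~49 / 8.7 / 6.6 / 1.3 µg cm⁻³; with one shared per-individual value set an
exact simultaneous match of all four pools at both stations is
overdetermined (the linear system in the three densities has no
non-negative solution), so the second station is approximate by design.
A warm-temperature regime is a scalar multiplier on the uptake amplitude.

Atom% readings are produced by inverting the mixing model on the true
incorporation and adding instrument noise, so a zero-noise scenario
round-trips exactly (pools, exponents with zero standard error) through
the full pipeline — this identity, not any fitted number, is the
generator's correctness anchor. C and N intake share one lognormal draw
per capsule (coupled uptake); the capsule's mean individual weight is
drawn lognormally within its fraction, which is structure, not noise, and
is never zeroed. The `recovery_scenario` variant flattens the time course
across the two sampling days (τ = 2/ln 2 makes f(2) = f(4)) so exponent
recovery studies see exactly the configured log-scale scatter.

What the generator does **not** emulate: mortality dynamics (beyond the
dropped-row bookkeeping), bacterial label dilution, storage-product
turnover that decouples pC from TOC late in an incubation, within-capsule
weight heterogeneity, and spatial structure between stations. Passing
tests therefore demonstrate that the arithmetic, fits and budgets are
correct under the assumed statistical structure — not that the structure
captures every feature of real incubations.

## Numerical choices and problem sizes

- Exponent recovery calibration: 200 simulated experiments of n = 18
  capsules at b = 0.57 and σ_log = 0.2; with exact-t intervals on
  log-normal errors the nominal 95% coverage is exact, and the suite
  checks the realised coverage and the mean estimate. The whole suite runs
  in a few seconds.
- Stochastic end-to-end checks average 5 pre-specified seeds to test the
  mean behaviour rather than a single draw.
- Tolerances: tracer arithmetic and budget identities at 1e-12 relative;
  zero-noise round trips at 1e-9; exact-fit recoveries at 1e-8 absolute on
  exponents.
- Degenerate inputs fail loudly: non-positive ratios/atom%, food
  enrichment at or below background, constant predictors, corrections
  exceeding the measured mass, abundance fractions without a matching
  aggregate.

## Known limitations

- The mixing model is two-member; bacterial reworking of the label or
  selective assimilation of food fractions would bias pC/pN.
- OLS on log–log data estimates the conditional median under lognormal
  error; if measured data had strongly heteroscedastic replicates a
  weighted fit (supported) or SMA regression (not implemented, noted as an
  alternative) could shift exponents slightly.
- Processing fractions assume the incubation intake rate is representative
  of field rates at matching food supply; temperature and food-history
  effects enter only through the scenario parameters.
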