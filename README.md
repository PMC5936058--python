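# foramtracer

Analysis pipeline for dual-label (¹³C/¹⁵N) phytodetritus feeding experiments
with benthic foraminifera, from raw EA-IRMS capsule measurements to
population-level carbon and nitrogen budgets in intertidal sediment.

Who it is for: isotope-tracer ecologists running pulse-chase or constant
feeding experiments with labelled algal detritus (e.g. *Dunaliella
tertiolecta* fed to *Ammonia tepida*) who need a tested, reproducible path
from instrument output to per-individual intake, size-scaling relations and
community-scale processing estimates.

## The model

A pooled capsule of *n* individuals yields total organic carbon (TOC),
total nitrogen (TN) and the isotope ratios of both elements. The pipeline
applies the standard tracer arithmetic:

- atom% from an isotope ratio R (heavy/light): `A = 100·R/(1+R)`, with
  δ-notation inputs converted via `R = R_std·(δ/1000 + 1)`
  (R_VPDB = 0.0112372 for C, R_airN2 = 0.0036765 for N);
- excess above background: `E = A_sample − A_background`;
- incorporated heavy isotope: `I_iso = (E/100)·TOC` (or TN);
- phytodetrital element: `pC = I_iso / ((A_food − A_background)/100)`,
  and likewise pN — the food-derived mass in the cytoplasm.

Dry weights are corrected for the CaCl₂ residue left by decalcification
(CaCO₃ + 2 HCl → CaCl₂ + H₂O + CO₂; subtract carbonate mass × 110.98/100.09).

Per-individual quantities Y are then related to individual dry weight W by
the allometric power law `Y = a·W^b`, fitted by least squares on
(ln W, ln Y); b ≈ 1 is isometry, b < 1 means the weight-specific quantity
falls with size. Group contrasts (size classes, sampling days) use a
Mann–Whitney U test that is exact — tie-aware, by enumeration of the
permutation distribution via a subset-sum recursion — for small samples.

Finally, per-individual means per sieve fraction (125–250, 250–355,
>355 µm) are projected onto living-abundance densities from stained
sediment cores: `pool = mean per individual × individuals cm⁻³`, converted
to areal units (µg cm⁻³ × layer cm × 10 = mg m⁻²), and compared with the
regional phytodetritus production flux to estimate the fraction of the flux
the population can process.

## Worked example

The package ships a synthetic-experiment generator whose defaults encode
the study conditions the pipeline was built around (triplicate capsules of
three size fractions sampled 2 and 4 days after a labelled food pulse, plus
three stations of core abundances). End to end from a shell:

```bash
foramtracer simulate --seed 42 --out-dir sim
foramtracer run --samples sim/samples.csv --abundances sim/abundances.csv \
                --food sim/food.yaml --out-dir out
foramtracer fit-scaling --intake out/intake.csv --out fits.json
foramtracer budget --intake out/intake.csv --abundances sim/abundances.csv \
                   --food-cn 5.6 --out budget.json
```

which prints

```
toc_per_ind~dw_per_ind: Y = 0.2846 * X^0.903 (b = 0.903 [0.885, 0.921], hypoallometric)
tn_per_ind~dw_per_ind: Y = 0.05803 * X^0.736 (b = 0.736 [0.722, 0.750], hypoallometric)
pc_per_ind~dw_per_ind: Y = 0.05033 * X^0.528 (b = 0.528 [0.368, 0.687], hypoallometric)
pn_per_ind~dw_per_ind: Y = 0.009559 * X^0.528 (b = 0.528 [0.368, 0.687], hypoallometric)
pc_per_ind~toc_per_ind: Y = 0.1048 * X^0.582 (b = 0.582 [0.405, 0.760], hypoallometric)
pn_per_ind~tn_per_ind: Y = 0.07303 * X^0.714 (b = 0.714 [0.494, 0.933], hypoallometric)
max C processing fraction: 11.7% (combined, day2, 500 mg C m-2 d-1)
```

Reading this: cytoplasmic carbon content rises almost in proportion to
body mass (b ≈ 0.90), nitrogen content and nitrogen demand scale with
b ≈ 0.75, and phytodetritus intake per individual scales with b ≈ 0.5–0.6 —
so the weight-specific intake of small individuals is much higher, and a
population dominated by the smallest sieve fraction processes
disproportionately much of the incoming detritus. At the low end of a
500–2000 mg C m⁻² day⁻¹ production range, the summed station populations
can match ~12% of the daily phytodetrital carbon flux.

The same steps are available as a library — `simulate_experiment`,
`TracerIncorporation` (a fit/transform transformer that can learn
backgrounds from control capsules), `aggregate_by_group`,
`PowerLawScaling`/`fit_power_law`, `extrapolate_pools`,
`processing_matrix` — see the module docstrings.

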