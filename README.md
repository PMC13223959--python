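# pfasvar

**Individual-level PFAS exposure variability as an ecological signal.**

Biomonitoring studies usually summarise contaminant burdens by group means
and treat the spread between individuals as noise. `pfasvar` implements the
opposite reading for per- and polyfluoroalkyl substances (PFAS) in seabird
plasma: the *between-individual variability* of a bird's compound profile is
itself a structured signal of its foraging ecology. The package is aimed at
ecotoxicologists and movement/foraging ecologists working with paired
contaminant panels and dual-tissue stable-isotope data — the motivating
system is two guillemot species (*Uria aalge*, UA; *Uria lomvia*, UL)
sampled at five Icelandic colonies — but every stage works on any cohort in
the same shape.

## The analysis

1. **Variability z-scores.** Plasma concentrations of a 15-analyte PFAS
   panel (9 PFCAs C5–C13, 5 PFSAs, HFPO-DA; non-detects censored at the
   method detection limit, MDL) are substituted (MDL/2 by default),
   log-transformed and decomposed by correlation-mode PCA over the fully
   detected compounds (C9–C13 PFCAs + PFOS). The standardized scores on the
   PFCA-dominated and PFOS-dominated components are the per-bird indices
   z_PFCA and z_PFOS.
2. **Exposure states.** k-means on (z_PFCA, z_PFOS) with the number of
   clusters chosen by mean silhouette over k = 2…8.
3. **Isotopic consistency.** For each isotope (δ¹³C, δ¹⁵N), a two-variable
   PCA of the standardized (plasma, RBC) pair gives a shared-level axis;
   its standardized PC1 score (δ¹³C_consist, δ¹⁵N_consist) indexes how
   consistently a bird forages across the two tissues' integration windows.
4. **Bivariate segmented regression.** With c = δ¹³C_consist,
   n = δ¹⁵N_consist and fixed breakpoints ψ = (ψ_c, ψ_n) = (0.2, 0.0):

   z = β₀ + β₁·c + β₂·(c − ψ_c)₊ + β₃·n + β₄·(n − ψ_n)₊ + β₅·c·n + ε

   where (u)₊ = u·I(u > 0). β₂ and β₄ are *segment* coefficients — the
   slope change after each breakpoint — so the post-breakpoint slope is
   always β_pre + β_segment and the surface is continuous. Inference uses
   HC1-robust standard errors; the breakpoints split the isotopic plane
   into four foraging quadrants (LL/LH/HL/HH; quadrants with < 10 birds are
   excluded); per-quadrant residual scale is the MAD-rescaled sigma
   (1.4826 × MAD), which drives distance-weighted 95% prediction intervals
   and a gridded exposure surface. An 80/20 quadrant-stratified hold-out
   reports R² and RMSE on both partitions.

A seeded synthetic-cohort generator reproduces the statistical structure of
the study cohort (design, censored lognormal panels, isotopic gradient with
plasma–RBC r ≈ 0.7, the three-component exposure-state mixture, and the
published hinge-surface coefficients), so the full pipeline is testable
without any field data.

## Worked example

```sh
pfasvar all --seed 7 --out run1
```

simulates the default 112-bird cohort and runs every stage. Selected output
(from `run1/pca.json`, `correlations.json`, `validation.json`):

```
explained variance ratio: [0.758, 0.167]
plasma-RBC correlation:   d13C r = 0.66, d15N r = 0.66 (n = 112)
z_PFOS validation:        R2_train 0.02, RMSE_train 0.96, RMSE_test 1.09
```

The PCA split (75.8% PFCA-block component, 16.7% PFOS component) mirrors the
class-structured covariation the generator encodes; the tissue correlations
sit near the configured pooled 0.7. The segmented fit on this cohort is
weak by design — the concentration-space generator does not plant a hinge
relationship between its isotope and concentration fields, so the near-zero
R² is the expected negative control. Parameter recovery of the segmented
engine is exercised by the score-space generator instead
(`generate_surface_data`), which draws directly from a known hinge surface:

```python
from pfasvar import SurfaceParams, generate_surface_data, fit_bivariate_segmented
data = generate_surface_data(SurfaceParams(), n=2000, seed=42)
fit = fit_bivariate_segmented(data)
print(fit.coef)   # recovers the configured beta to ~0.04
```

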