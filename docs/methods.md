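# Methods

This note documents the statistical model behind `pfasvar`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make outputs reproducible.

## Censored concentration panels

Non-detects are censored at the per-compound method detection limit (MDL).
The default panel assigns every compound an MDL of 0.06 ng g⁻¹ DM, the
midpoint of the reported 0.05–0.07 range; per-compound MDLs are
configurable. Substitution of censored cells is deterministic — MDL/2 by
default, MDL/√2 or zero as alternatives — because MDL/2 is the standard
ecotoxicology convention and the downstream z-scoring makes the analysis
insensitive to the exact constant as long as it is shared within a
compound. The zero rule is allowed for completeness but the subsequent
natural-log transform rejects it explicitly.

Detection summaries report detection frequency as the integer percentage of
uncensored cells and compute median/min/max **over detected values only**.
The all-samples alternative (with substitution) was rejected because it
cannot reproduce a detected-median above the MDL for a compound detected in
fewer than half of the birds, which the reference summaries for this system
contain.

## Variability scores

PCA is run on column-standardized log concentrations (i.e. on the compound
correlation matrix). Covariance-mode PCA was rejected because the panel
spans two orders of magnitude and PFOS would dominate every component. The
default compound set is the six analytes detected in 100% of samples of
both species (PFNA, PFDA, PFUnDA, PFDoDA, PFTrDA, PFOS); partially detected
compounds can be included after substitution.

Two components are retained. Each compound class (long-chain PFCAs; PFOS)
is mapped to the component carrying its largest absolute loading mass.
Signs are fixed deterministically — the PFCA component is flipped so the
total C9–C13 loading is positive, the PFOS component so the PFOS loading is
positive — making score signs stable across linear-algebra backends. When
both classes map to the same component the construct is undefined and
scoring raises rather than guessing; the same applies when the assigned
component carries (numerically) no variance. Scores are standardized with
the sample SD (ddof = 1); z-scores are therefore invariant to the log base
and to any per-compound rescaling.

## Exposure-state clustering

k-means in (z_PFCA, z_PFOS) with Euclidean distance (the axes are already
standardized), 25 restarts, and silhouette-based selection of k over 2–8,
ties toward the smaller k. The search range and restart count are package
choices; they are recorded in the output. Cluster labels are canonicalized
by descending size then lexicographic centroid so repeated runs produce
identical artifacts. A KDE (Gaussian kernel, Scott bandwidth) of the score
cloud is exported as gridded values for density contours; no styling is
produced.

## Isotopic consistency scores

Plasma integrates diet over roughly days-to-weeks, red blood cells over
weeks-to-months. For each isotope separately, the (plasma, RBC) pair is
column-standardized and decomposed; for a standardized 2-variable system
the leading eigenvector is (1, 1)/√2 whenever the tissues correlate
non-negatively, so PC1 is the shared-level axis and its explained-variance
ratio is (1 + r)/2 exactly. The standardized PC1 score is the consistency
index; both tissue loadings are positive, so birds consistently above the
cohort mean in both tissues score positive. Standardizing the tissues first
absorbs tissue-specific variances and constant turnover/discrimination
offsets — the construct targets shared ordering, not shared scale. If the
tissues are anti-correlated the shared axis does not exist and the function
errors, demanding an explicit override, rather than silently returning a
difference axis. Tissue-turnover modelling, trophic-discrimination
correction and isotopic baseline correction are out of scope.

## Bivariate segmented regression

The model is a continuous piecewise-linear (hinge) regression,

z = β₀ + β₁c + β₂(c − ψ_c)₊ + β₃n + β₄(n − ψ_n)₊ + β₅cn + ε,

with breakpoints **fixed** at ψ = (0.2, 0.0) in consistency-z units. The
hinge parameterisation (rather than disjoint per-quadrant fits) was chosen
because the segment coefficients are then literally "slope change after the
breakpoint" and the fitted surface is continuous; the interaction is the
raw product c·n, not a hinge product. A diagnostic R² profile over a
breakpoint grid is available for inspection but is never used for
selection.

Quadrant conventions: equality is assigned to the low side (c ≤ ψ_c is
"L"), so quadrant labels agree with the hinge indicator I(x > ψ). Quadrants
with fewer than `min_quadrant_n = 10` birds are excluded from fitting with
a recorded reason; any threshold between the observed excluded (n = 6) and
retained (n = 15) group sizes reproduces the reference behaviour, and 10 is
configurable. Fits require ≥ 12 retained birds and a full-rank design.

Inference: OLS with an HC1 sandwich covariance (the minimal standard
"robust SE" choice) and two-tailed p-values from the normal approximation,
α = 0.05. Per-quadrant uncertainty uses the MAD-rescaled residual scale
σ_q = 1.4826 × median(|r − median(r)|), consistent for the SD under
normality and insensitive to outlying birds. The distance-weighted interval
at a point is ±z₀.₉₇₅ · σ_q · (1 + d/s_q), where d is the distance to the
quadrant's training centroid and s_q the RMS of training distances
(s_q = 0 ⇒ weight 1). The linear (1 + d/s_q) kernel is an explicit package
choice: it equals the nominal width at the centroid and grows conservative
away from the data. Coverage at the centroid is therefore approximately
nominal and strictly conservative elsewhere (verified by simulation in the
test suite).

Validation: quadrant exclusion is applied before splitting; the 20% test
set (ceil(0.2·n), allocated across quadrants by largest remainder, at least
one training bird per quadrant) reproduces an 84/22 split at n = 106. If a
redraw is ever needed to keep every quadrant in training, the seed bump is
recorded. Test R² is computed against the test-set mean.

Variance attribution uses sequential (type-I) sums of squares in the fixed
order C, N, C-segment, N-segment, C×N, each reported as a percentage of the
model SS (shares sum to 100). The sequential convention is a documented
choice — the headline "share of model variance attributable to the segment
effect" is not otherwise identified — and with orthogonalized covariates it
reduces to squared-projection shares.

Univariate segmented fits (z against a single consistency axis with one
hinge) report β_pre, the segment coefficient, and β_post = β_pre + segment
exactly; the marginal univariate post-slope and the bivariate slice
post-slope answer different questions and are both computed and reported
separately, never merged.

The exposure surface evaluates the fitted model on a regular grid (default
101 × 101 over the observed covariate range ± 0.25) with the
distance-weighted CI per node; nodes in excluded quadrants keep the
prediction but carry no CI.

## Synthetic cohort generator

The generator's defaults encode the study conditions: 112 birds — 15 UA +
15 UL at each of NW/N/NE, 15 UA at SE, 7 UA at SW — and per-species
compound lognormals parameterised from the published detection frequencies
and detected medians. For fully detected compounds the log-median is the
printed median and the scale is set so the printed min–max range holds
≥ 95% of the distribution. For partially detected compounds (μ, σ) solve
P(X > MDL) = DF and median(X | X > MDL) = printed median in closed form,
with σ clipped to [0.2, 2.5]; inside the clip DF holds exactly. Where the
printed detected-median is itself "<MDL" (a summary-table inconsistency), a
proxy median √(MDL·max) is used. Never-detected compounds are generated
essentially entirely below MDL. Censoring is by truncation of the same
lognormal — a censored cell is a real draw that fell below MDL — so
generated detection frequencies converge to the configured values.

Within-bird class covariation is induced by a latent per-bird factor per
compound class (weight √ρ, default ρ = 0.9 for PFCAs, 0.5 for PFSAs),
which preserves each compound's marginal and produces the PFCA-block PC1 /
PFOS PC2 structure (~76%/17% on a default cohort, against the published
79%/13%).

Isotopes are bivariate-normal (plasma, RBC) pairs with colony-level means
on a north–south gradient and a constant tissue offset. The published
plasma–RBC correlation (0.7) is a cohort-pooled statistic, and the colony
gradient itself contributes shared variance; the generator therefore solves
the within-colony correlation from the design so that the *pooled*
correlation matches 0.7. Species-level colony effects on concentrations,
spatial autocorrelation and toxicokinetics are not modelled.

Score-space generators are deliberately separate from the cohort generator:
`generate_surface_data` draws (c, n, z) directly from a known hinge surface
(uniform covariates on [−2.5, 2.5]², optionally exact per-quadrant counts
65/15/26/6 or per-quadrant means), and `generate_cluster_scores` draws the
three-component Gaussian exposure-state mixture (sizes 46/48/18) with true
labels. PCA scores of a generated concentration panel do **not** follow the
configured surface — the cohort generator plants no isotope–concentration
hinge — so parameter-recovery claims rest on the score-space generators,
and a segmented fit on a default synthetic cohort is a negative control.
Passing tests therefore demonstrate correctness of the estimators under the
assumed data-generating processes, not ecological validity on real
cohorts.

## Problem sizes and determinism

Every generator is a pure function of (config, seed); k-means uses a fixed
seed with 25 restarts and all seeds are recorded in the output artifacts.
Simulation-based checks use 2000-point regressions, 50-seed cluster
replicates and 500-replicate coverage runs — sizes at which the Monte Carlo
error is an order of magnitude below the tolerances being asserted.
Degenerate inputs (zero-variance columns, single-quadrant designs, empty
residual sets, k = 1 silhouettes) raise typed errors rather than returning
best-effort numbers.

## Known limitations

- Breakpoints are inputs, not estimates; no Davies-type test or ML
  breakpoint search is provided.
- No mixed-effects structure (colony random effects) in the segmented
  model; colony enters only through the generator and composition tables.
- The distance-weighted interval is a calibrated heuristic, not a formal
  predictive distribution; it is exact at the centroid under normality and
  conservative elsewhere.
- The consistency construct is undefined for anti-correlated tissues and
  the package refuses to score such cohorts.
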