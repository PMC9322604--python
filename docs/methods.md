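# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Study design being modelled

A reciprocal transplant of two closely related plant taxa along an
elevational gradient: a lowland species (native ~500 m, dissected leaves)
and an upland species (native ~2000 m, entire leaves), each sampled as many
field genotypes, propagated as clonal cuttings, and planted into replicate
blocks at four sites (500/1000/1500/2000 m) spanning both native ranges plus
two intermediate elevations. Clones of the same genotype are genetically
identical replicates, so genotype-level reaction norms are estimable.

## Univariate reaction norms

Per trait, a linear mixed model with species, site and species × site fixed
effects, and genotype-by-site and block-within-site random intercepts with
one shared residual variance. Variance components are reported from REML;
the species × site interaction is tested by a likelihood-ratio test between
**full-ML** refits of the full and additive fixed structures (REML
likelihoods are not comparable across fixed structures), χ² df =
(n_species−1)(n_sites−1). Multiplicity over traits is handled by the plain
multiply-by-number-of-tests rule, capped at one.

*Exact likelihood on balanced designs.* When the layout is perfectly
balanced (equal genotypes per species, blocks per site, clones per
genotype × block), the marginal covariance is block-diagonal by site and its
eigenspaces are the classical ANOVA strata: within-cell and genotype × block
interaction contrasts (variance σe²), block contrasts (σe² + PGC·σb²),
genotype-within-species contrasts (σe² + BC·σg²), the per-site species
contrast (same), and the per-site grand mean. The profile ML likelihood of
either fixed structure then depends only on a handful of sums of squares,
and is maximised over the three variance parameters by Nelder–Mead on the
log scale from two starts (one near-zero start so variance components on the
boundary are found). The generic numeric fit (statsmodels MixedLM, bfgs with
a powell retry) is used for unbalanced data and for REML variance
components; a test verifies the exact path agrees with the numeric optimiser
and only ever finds an equal-or-better optimum. Monte-Carlo calibration of
the LRT is run at the emulated experiment's own scale (40 genotypes/species,
3 blocks, 3 clones) because the full-ML fixed-effect LRT is mildly liberal
on much smaller designs (downward-biased ML variance components) — a
property of the method, not of this implementation.

Pairwise within-species site contrasts use Welch t-tests on genotype means
(the analysis-level replicate), p multiplied by the number of pairs, with a
greedy compact letter display (sites sharing a letter do not differ; ties
broken by ascending elevation). The common-garden species comparison is a
Welch t-test (unequal variances, Satterthwaite df) with the same
multiplicity rule.

## Derived traits

Leaf complexity = perimeter²/area; indent density = indentations/perimeter;
SLA = area/dry mass (mm²/mg); intrinsic water-use efficiency = A/gs.
Saturation-pulse quantum yields use the standard lake-model partition
Y(II) = (Fm′−F)/Fm′, Y(NO) = F/Fm, Y(NPQ) = F/Fm′ − F/Fm (summing to one by
construction). PI_total is the standard JIP-test product
(RC/ABS)·[φP0/(1−φP0)]·[ψE0/(1−ψE0)]·[δR0/(1−δR0)]. The fluorescence
formulas are the standard forms of the field, implemented as such.

## Multivariate geometry

Traits are mean-standardised by their grand mean over all species, sites and
genotypes of one experiment, making traits dimensionless and angles
unit-free. The MANOVA uses genotype × site means as observations and the
scatter of genotype means about their (species × site) cell mean as the
error stratum — the appropriate denominator when asking whether species/site
differences exceed genotype-level differences. Wilks' λ = det E/det(H+E)
with the balanced two-way SSCP decomposition for H and Rao's F
approximation.

The D-matrix is the covariance of the equally weighted cell mean vectors
(a genotype-count-weighted variant is available behind a flag; the two are
nearly identical for near-balanced designs). Eigenvalues are sorted
descending, eigenvectors unit-norm with the largest-magnitude loading made
positive, proportions = eigenvalue/trace.

Vector conventions for the alignment report: each species' plasticity vector
points **from its native phenotype toward its phenotype at the opposite
extreme site**; the divergence vector used for species X points from X's
native phenotype toward the other species' native phenotype. With this
orientation "adaptive plasticity" is a small angle, and the same convention
applies symmetrically to both species. The "aligned" flag defaults to 45°
and is a reporting convenience only. Intermediate sites contribute to the
mean standardisation and to the D-matrix but not to the extreme-to-extreme
vectors.

*Precision of estimated angles.* Block effects are shared by the two species
within a site and their site-level averages are statistically confounded with
site means, so block variance sets a floor of a few degrees on
single-experiment angle estimates that genotype replication cannot reduce
(an optional within-site block adjustment removes the between-block scatter
that matters for unbalanced data, but not this site-confounded component).
The planted-angle recovery fixture therefore uses zero block variance and
150 genotypes/species, where the sampling error of the recovered angle is
well under one degree; under the full default conditions the recovered
angles scatter ±3° around the planted 66/33/95° geometry.

## Survival

Kaplan–Meier product-limit curves with Greenwood variance and log-log 95%
bands (via lifelines). The proportional-hazards model is fit by direct
Newton maximisation of the partial likelihood with Breslow tie handling
(Efron available; day-resolution field data are heavily tied). The species ×
site interaction is tested by 2·ΔlogPL against χ²(3). A shared gamma frailty
per genotype is available: EM with posterior-mean frailties as offsets and
the frailty variance maximising the gamma-marginal profile likelihood; on
failure the fit falls back to fixed effects with a logged note. Deaths
within a configurable transplant-shock window (default 3 days) are removed
before fitting, as they reflect failed establishment rather than the site
environment.

## Expression

Filtering: a gene is discarded when ≥50% of samples have counts <5 unless
>75% of those low-count samples are in one species (then kept as a candidate
species-specific gene). The rule is applied to counts; applying it to
mapping rates would require upstream alignment data that is out of scope.

Normalisation: median-of-ratios against the per-gene geometric-mean
reference (genes with any zero excluded from the reference; library-size
fallback with a warning), log2 abundances with pseudo-count 0.5. Note the
estimator assumes most genes are not differentially expressed;
one-directional shifts in a large fraction of genes are partially absorbed
into the size factors.

Per-gene model: negative-binomial GLM with a cell-mean design (one column
per species × site cell) plus sum-to-zero-coded genotype effects within
species, so species and cell contrasts stay identifiable; log size factors
enter as offsets. Dispersion is per-gene method-of-moments pooled over
cells, floored at 1e-4, with no empirical-Bayes shrinkage — a documented
simplification; the Wald test is asymptotic. Numeric parity with DESeq2 or
limma/voom is not claimed; the verification surface is simulation
calibration (null p-value uniformity, planted-effect recovery). Significance
is BH-adjusted p < 0.01.

Quadrant classification of the two species' extreme-vs-extreme fold changes
(both oriented low → high elevation): opposite-direction (both significant,
opposite signs), species-specific (one significant), shared-same-direction
vs magnitude-divergent (both significant, same sign, |Δlfc| above/below 1
log2 unit — the magnitude threshold is a package default, as no canonical
value exists), else unchanged. Exactly one category per gene.

Modules: average-linkage hierarchical clustering on 1 − |Pearson r| between
gene profiles, tree cut at 0.4 by default, minimum module size 20, leftovers
unassigned. This deliberately replaces the full weighted-coexpression
machinery (soft thresholds, topological overlap, consensus trees) with a
transparent clustering; the eigengene layer — first principal component of
standardised member expression, sign-oriented to mean expression, Pearson
correlation with elevation per species — follows the standard definition
exactly. GO enrichment is a one-sided Fisher exact test per term against the
filtered-gene universe, significance reported at p < 0.05.

## Synthetic-data generator

The generator is the package's study-condition definition. Defaults: 2
species × 4 sites (500–2000 m) × 40 genotypes/species × 3 blocks × 3 clones;
four leaf traits with cell means built by an exact geometric constructor —
divergence and per-species plasticity vectors are specified on the
mean-standardised scale and converted to raw cell means whose grand mean per
trait is exactly the trait scale, so empirical standardisation reproduces the
planted geometry without approximation. Default geometry: between-species
plasticity angle 66°, lowland plasticity 33° from divergence (adaptive),
upland 95° (nonadaptive), mirroring the motivating system. Variance
components are not published for the motivating experiment, so defaults are
coefficients of variation chosen once for realism and testability: genotype ×
site 5%, block 3%, residual 10% of each trait's grand mean.

Survival: exponential event times with log-rates per species × site
(defaults cross: lowland hazard rises with elevation, upland falls),
log-normal genotype frailty, censoring at follow-up (default 180 d).
Seasonal piecewise hazards are not modelled. Expression: gamma-Poisson
(NB2) counts, log-normal library sizes (σ=0.25), per-gene log2 effects for
species/site/interaction, genotype effects (σ=0.1), and per-module latent
factors (elevation weight × scaled elevation + N(0, 0.1) sample noise) with
per-gene loadings. All randomness derives from one master seed through
deterministic substreams.

What the generator does **not** emulate: spatial autocorrelation within
transplant grids, seasonal mortality waves, trait measurement batch effects,
mapping-rate artefacts, unbalanced genotype replication, and missing data.
Passing tests therefore demonstrate correctness of the estimators under the
assumed model, not robustness to these real-data features.

## Verification choices and problem sizes

Monte-Carlo studies use 500 replicates for type-I error (bounds [0.03,
0.07] at α=0.05), 150 for power, at the full 40 × 3 × 3 design; DE
calibration uses 1000 genes (null) and 200 planted genes at |lfc|=2 in a
1000-gene background with balanced directions (one-directional planting
would bias the size factors — see above). The Wilks' λ oracle is an
explicit-loop SSCP computation on 50 random instances (≤4 traits, ≤6
groups, agreement to 1e-10). The planted-60° end-to-end fixture uses 150
genotypes and zero block variance (rationale above) and is checked within
2°. Numerical tie-breaks: eigenvector signs by largest-magnitude loading;
MDS axis signs by largest-magnitude coordinate; letter groupings greedy in
ascending-elevation order; angle arccos clipped to [−1, 1].

## Known limitations

- The NB Wald test is anticonservative for very small replication or very
  large dispersion; no shrinkage is applied.
- The gamma-frailty EM reports an approximate profile likelihood; frailty
  and fixed-effects LRTs should use the same frailty setting.
- The exact balanced-design likelihood covers exactly two species; other
  layouts take the slower numeric path.
- Classification thresholds (aligned angle 45°, magnitude delta 1 log2)
  are reporting conventions, not inferential claims.
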