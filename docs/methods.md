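# Methods

## The statistical model

Within one (donor, cell type) analysis group, the association between an SNV
locus *s* and a gene *g* is estimated by ordinary least squares of
normalized expression on the per-cell variant allele fraction,

    expr_gc = α + β · VAF_sc + Σ_j γ_j PC_cj + ε_c ,   ε_c ~ N(0, σ²),

restricted to the cells where the locus is informative (coverage ≥ minR).
This is a complete-case analysis by design: a cell without enough reads at
the locus carries no VAF measurement, and that missingness is structural
(driven by expression level of the harboring gene), not imputable noise.
Expression is the response and VAF the regressor, matching the convention
of standard eQTL engines. The reported statistics are the VAF
coefficient β, its *t* statistic, and the two-sided p-value on
n − (k + 2) residual degrees of freedom (intercept + VAF + k covariates).
With no covariates this reduces exactly to the Pearson-correlation *t*
test, which the test suite checks in closed form.

Per locus, all genes are fitted in one vectorised pass (a single QR
decomposition of the shared design, applied to every gene's response), so
a group with hundreds of loci and thousands of genes runs in seconds.
Rank-deficient designs (e.g. a constant covariate column) fall back to a
pseudoinverse solution with degrees of freedom counted at the effective
rank. Pairs with a constant VAF across informative cells, or with
exhausted degrees of freedom, are skipped and reported with a reason
rather than silently dropped.

q-values are Benjamini–Hochberg step-up values computed within the group
(tests across groups answer different questions and are not pooled); ties
in p receive equal q, and records are ordered deterministically by
(q, locus, gene). A pair is annotated **cis** when the SNV position lies
inside the correlated gene's transcribed interval (closed interval,
chromosome match, strand ignored — positional residence is the criterion,
not distance), otherwise **trans**; pairs whose gene has no model are
flagged `unannotated` and retained.

## Filters and their parameters

| parameter | default | meaning |
|---|---|---|
| `min_reads_per_allele` | 50 | pooled reads required for each allele across all cells of the sample, establishing the locus as biallelic |
| `minR` | 10 | per-(locus, cell) coverage below which the VAF is undefined ("informative" threshold) |
| stable band | [0.4, 0.6] | VAF range read as stable biallelic expression |
| mono bands | [0, 0.25] ∪ [0.75, 1] | VAF ranges read as monoallelic/skewed expression |
| dominance fraction | 0.75 | a locus is non-variable when **more than** 75% of its informative VAFs sit in one band family (strictly greater: a 15/20 locus survives) |
| `min_cells` | 20 | informative cells required per locus per analysis |
| QC: mito ≤ 0.06, genes in [3000, 8000], counts ≤ 12,500 | | cells violating any bound on strict inequality are removed; the boundaries themselves are kept |
| variable-gene rule | 80% / 20% | a gene is removed when ≥ 80% of cells sit within 20% of either end of its expression range (range-relative, both tails, computed on depth-normalized log1p values); constant genes are removed |
| `n_pcs` | 15 | expression principal components used as covariates, computed within the analysis group |
| `fdr` | 0.05 | significance threshold on q |

The 20-cell floor is justified by an exact binomial computation: if each
informative cell independently landed in the "variable" VAF range with
probability ½, the chance that at least 75% of 20 cells do so is
P(X ≥ 15) = 21700/2²⁰ ≈ 0.0206, and this false-variability probability
falls as the cell count grows (at 10 cells it would be 56/1024 ≈ 0.055).
`chance_variability_probability` evaluates the tail exactly (rational
arithmetic, no normal approximation).

Two textual conventions deserve note, both configurable. The coverage rule
is implemented as coverage ≥ minR with minR = 10 ("a minimum of 10 reads").
The non-variability rule has an alternative, stricter phrasing — keep a
locus only when ≥ 75% of its VAFs lie inside [0.25, 0.4] ∪ [0.6, 0.75] —
which disagrees with the two-band removal rule on mixed loci (half the
cells at 0.5, half at 0.1); the two-band removal rule is the default and
the strict form is available as `strict_variable_band=True`.

## Normalization

Expression normalization is median-depth scaling, log1p, then per-gene
centering/unit-variance scaling. Regularized negative-binomial variance
stabilization (sctransform-style) is deliberately not reproduced: the
package's contribution is the VAF–expression correlation, and externally
normalized matrices can be supplied directly. Two scales are kept:
`lognorm` (depth-normalized log1p), on which the variable-gene rule
operates and on which slope estimates are commensurable across genes, and
`scaled` (per-gene z-scores), used for the regression and PCA. Because
z-scaling is a per-gene affine transform it changes β's units but not *t*,
p, or q — detection is identical on either scale.

PC covariates are the top-k scores of the SVD of the gene-centered matrix,
with the sign fixed by making each component's largest-magnitude loading
positive, so results are bit-reproducible. When k meets or exceeds the
matrix rank it is reduced to the rank with a logged warning. PCA is
computed within each (sample, cell type) group, on the variable genes,
consistent with the per-group regressions.

## Enrichment statistics

The permutation test draws, per permutation, the same number of distinct
unordered gene pairs as observed, uniformly from all pairs over the
analysis gene universe (no self-pairs, no duplicates within a
permutation), via exact unranking of pair indices — the sampler is a
bijection, verified against exhaustive enumeration on a 4-gene universe.
The p-value is the fraction of permutations whose overlap with the
interaction set is at least the observed overlap; a p of 0 is reported as
"< 1/n_perm" since the fraction definition otherwise overstates evidence.
The universe is a required argument (SNV-harboring genes plus tested
genes, in the pipeline) to prevent silent misuse. Overlap proportions are
compared by Pearson chi-square on the 2×2 table, one degree of freedom, no
continuity correction by default; a zero expected cell raises an error
advising an exact test.

## The synthetic-data generator

`generate_dataset` emulates exactly the structure the method assumes, with
known ground truth:

- **Coverage**: per (locus, cell), negative binomial with mean 25 and
  dispersion 5, zeroed with dropout probability 0.2 — deep enough that a
  meaningful fraction of cells pass minR = 10, as in real data only
  moderately-to-highly expressed loci are analyzable.
- **Locus archetypes** (proportions 0.5 stable / 0.25 monoallelic / 0.25
  variable; stable loci dominate, mirroring the observation that the
  stable-biallelic filter removes the majority of loci): per-cell latent
  allelic ratios are Beta-distributed — tight around 0.5 (concentration 60)
  for stable loci, tight around 0.05 or 0.95 for monoallelic loci, and
  broad Beta(3, 3) for variable loci, which places ~79% of cells in
  [0.25, 0.75].
- **Reads**: n_var ~ Binomial(coverage, latent ratio); absent records mean
  zero coverage.
- **Expression**: per-gene log-normal baseline (log-mean 3.4, log-sd 1.0),
  per-entry Gaussian noise (sd 0.5) on the log scale, planted effects
  added as β · (latent ratio) on the log scale, then exponentiated and
  rounded.
- **Geometry**: genes tile a toy chromosome and each locus is placed inside
  a host gene, so cis pairs exist by construction. A multi-type mode
  assigns cells to blocks of cell types to exercise stratification.

Everything derives from a single seeded generator; identical configs give
byte-identical outputs. Planting an effect on a monoallelic locus is a
config error — such an effect is undetectable by design, since the locus
cannot survive the variability filter.

What the generator does **not** emulate: UMI deduplication (generated
counts are already unique reads), transcriptome-wide count structure,
ambient RNA, doublets, batch or cell-cycle effects, allele-mapping bias.
Passing tests therefore demonstrate the statistical machinery — filter
fidelity, FDR control, power against planted linear effects — not
robustness to those real-data artifacts.

## Recovery, attenuation, and what the numbers mean

Planted slopes are defined against the cell's **latent** allelic ratio, but
the fitted regressor is the sequencing-sampled VAF. This is a classical
errors-in-variables setting: at coverage ~25 the binomial sampling
variance (~0.01 at VAF 0.5) against a latent variance of ~0.036 gives a
reliability ratio near 0.8, and log1p/rounding discretization shaves a few
more percent. A planted slope of 1.5 is therefore recovered around 1.1 on
the depth-normalized log scale — well within 3 standard errors at the
simulated sizes, and with the *t* test unaffected (attenuation costs
power, not validity). The recovery checks measure the slope on the
`lognorm` scale without PC covariates, since the generator plants no
confounding for them to remove and empirical expression PCs partially
absorb single-gene effects in small gene panels.

Problem sizes used by the tests and the acceptance script — null
calibration at 200 cells × 20 loci × 100 genes over 100 replicates,
recovery at 300 cells over 50 replicates, permutation exactness at 50,000
draws — were chosen so the full suite completes in well under a minute on
one core while keeping Monte-Carlo error far below the decision margins.

## Known limitations

- The normalization stand-in is deliberately simple; strongly
  overdispersed genes are better handled by feeding an externally
  normalized matrix.
- Slope estimates are attenuated at low coverage (see above); interpret β
  comparatively, or correct externally using the coverage-implied
  reliability if absolute effect sizes matter.
- FDR control is within-group; no cross-group aggregation beyond set
  intersection is provided.
- cis/trans annotation is purely positional (gene residence); SNVs in
  genes adjacent to their correlated gene are trans by definition.
- The pipeline trusts upstream deduplication and SNV calling; it performs
  no alignment-level work (no BAM/CRAM parsing, no mapping-bias
  correction).
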