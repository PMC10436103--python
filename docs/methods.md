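# Methods

This note documents the statistical procedures implemented in `tcellsig`,
the defaults chosen where the design was open, and what the synthetic
generators do and do not emulate.

## Coordinates and interval algebra

All genomic coordinates are 0-based, half-open (BED convention). An overlap
of ≥ 1 bp counts as detection. Catalog construction is a union merge in
per-base-pair coverage semantics: transitively overlapping *and bookended*
intervals collapse into one covered run (this is what a membership oracle
over individual bases produces, and matches `bedtools merge`). The merge is
idempotent, and all interval operations are tested against brute-force
per-base oracles on small chromosomes.

## Consensus, gained/lost and subtype-specific sites

A site is a consensus site of a condition when it is detected in at least
`ceil(min_fraction × n_replicates)` replicates; `min_fraction` defaults to
2/3, which makes "at least 2/3 of samples" and "at least 3 replicates"
coincide for the 3- and 4-replicate designs this package targets. Consensus
calling against a shared catalog puts all conditions on common coordinates,
so gained/lost sets are exact set differences:
`gained = subtype_consensus \ effector_consensus` and vice versa for lost.
A subtype-specific site is gained by that subtype and by no other. These
definitions force the invariants `gained ∩ effector = ∅` and pairwise
disjointness of specific sets, both under test.

## Differential accessibility

A deliberately simplified negative-binomial Wald test:

* **Normalization** — trimmed mean of M-values (double trim, 30% on M and
  5% on A) against a reference sample chosen by the upper-quartile rule;
  effective library sizes rescale counts to a common geometric-mean scale.
* **Dispersion** — per-peak method-of-moments estimate
  φ = (s² − μ)/μ² pooled across the two groups, clipped at 0, shrunk toward
  the median (common) dispersion with 20 prior degrees of freedom. The
  shrinkage weight trades a small conservative bias for stability at
  n = 3–6 replicates per group.
* **Test** — log2 fold change of normalized group means with pseudocount
  0.5 per group mean (keeping fold changes finite for empty peaks); Wald
  z with the delta-method variance Var(log μ̂) ≈ (1/μ + φ)/n per group;
  Benjamini–Hochberg FDR across peaks. All-zero peaks get p = 1 and are
  excluded from the FDR ranking. Significance requires FDR < 0.05 and
  |log2FC| ≥ 1 by default ("a minimum of log 2-fold change" read as ≥ 1,
  configurable).

On effect-free simulations the fraction of peaks at FDR < 0.05 stays below
0.07, and planted |log2FC| = 3 effects at dispersion 0.05 with n = 6 per
group are recovered at ≥ 90% sensitivity with empirical FDR ≤ 1.5× nominal
(acceptance suite).

## Peak annotation and peak-to-gene links

Promoter windows span 2.5 kb upstream to 0.5 kb downstream of the TSS,
mirrored on the minus strand and clipped at 0. Annotation precedence is
promoter > exon > intron > intergenic (the precedence rule is a package
decision; the window is the published one). Promoter and exon links require
literal overlap. Distal links follow the correlation strategy for linking
distal elements to promoters: a peak within ±500 kb of the TSS is linked
when the Pearson correlation across samples between its signal and the mean
signal of the gene's promoter peaks reaches 0.7. Both parameters are
configurable; correlation needs ≥ 8 samples, below which distal linking is
disabled with a warning. Genes without a promoter peak get no distal links.

## Deconvolution

The signature matrix S holds, per subtype, the mean accessibility of that
subtype's replicate samples over the union of subtype-specific sites. The
primary engine solves non-negative least squares `min ‖S·f − y‖², f ≥ 0`
and renormalizes f to the simplex. Renormalizing the unconstrained-sum NNLS
solution is equivalent to minimizing the *scale-profiled* residual
`min_c ‖c·S·f − y‖²` over the simplex — the oracle used by the
grid-search equivalence tests. The estimate is therefore invariant to the
overall scale of the profile. A ν-SVR engine (linear kernel, ν = 0.5,
negative coefficients clipped, renormalized) reproduces the flavor of the
SVR-based deconvolution algorithm the field commonly uses; NNLS is the
default because it is deterministic and dependency-light.

**Significance.** The permutation null shuffles the profile across
features, re-runs the engine, and uses the Pearson correlation between
reconstruction and (shuffled) profile as the statistic;
p = (1 + #{null ≥ observed}) / (1 + n_permutations), so p is never 0.
Default 499 permutations.

**Validation.** `validate_on_synthetic` draws mixtures `S·p` with
p ~ Dirichlet(α) (α = 1, flat on the simplex) times element-wise
lognormal(0, σ) noise, deconvolves each, and summarizes the **maximum**
per-mixture mean absolute deviation between estimated and true proportions
(in percentage points, "in all cases") and the maximum permutation p. The
pass thresholds are 1 percentage point and 0.05. The error is defined
per-mixture as the mean over subtypes of |estimated − true| — the source
states only a "<1%" error, so this mean-absolute reading is a package
definition, recorded here rather than asserted as the original computation.
Censoring of estimated proportions below 1% flags them as omitted without
renormalizing the rest, because omission, not redistribution, is what the
threshold describes.

## Variant-set enrichment

Risk variants are expanded to LD blocks: each seed collects catalog
variants linked at r² ≥ 0.8 (default; the upstream tool's setting is not
published) and blocks sharing variants merge transitively. Null families
are drawn per experiment: each of n_null (default 500, ≥ 100 required)
random sets matches every AVS block with a distinct catalog block of equal
variant count, falling back to the nearest count when the size class is
exhausted (recorded in a provenance trace); AVS blocks themselves are never
sampled. The enrichment score of any block family against a region set is
the number of blocks with ≥ 1 variant inside a region. One null family is
shared across region sets so per-set p-values are comparable. The add-one
empirical p replaces the distribution-normalization (Box–Cox) step of the
cited enrichment method — a deliberate simplification; an optional
normal-approximation mode attaches a z-score for score-distribution
displays. Bonferroni correction multiplies by the number of region sets;
significance is corrected p < 0.01. Matching is on block size only: the
synthetic catalog carries no MAF or gene-density covariates, and the
matching key is the documented extension point.

## Single-cell scoring

QC keeps cells with ≥ `min_genes` detected genes (200 for in-house-style
data, 500 for public-data-style settings) and a mitochondrial count
fraction ≤ `max_mito_fraction`. The public-data phrasing that reads as
removing *low*-mito cells contradicts convention; high-mito cells are the
ones removed here, and the interpretation is flagged. Normalization is
counts-per-ten-thousand, log(CP10K + 1) with the natural log (the cited
implementation's convention; base 2 is used only where "log2" is
explicit). Signature scores are the per-cell mean of the gene-wise
mean-centered expression Er over signature genes; genes missing from a
matrix are dropped with the coverage recorded, since public matrices differ
in gene universes. Centering makes scores invariant to per-gene additive
shifts and is idempotent.

Markers are Welch two-sided t tests of cluster vs rest on log-normalized
values, log2 fold changes computed on expm1-back-transformed group means
with pseudocount 1 (the cited implementation's convention), BH-corrected
within cluster, reported at |log2FC| > 0.5 and adjusted p < 0.05.
Reference signatures (e.g. from sorted-population transcriptomes) use the
same test at log2FC > 1 (up only), FDR < 0.05. Zero-variance genes with
equal means get p = 1.

A cell "co-expresses" the cytotoxic program (GZMA, GZMB, GNLY, IFNG, PRF1)
when ≥ 2 signature genes are detected and its signature score is positive;
both knobs are exposed, as the original co-expression rule is qualitative.

Preranked GSEA uses the Kolmogorov–Smirnov-style running sum in which a hit
at rank i adds |stat|^w (normalized over hits, w = 1 default) and every
position subtracts 1/N; the enrichment score is the maximum deviation from
zero. This convention has the closed form ES = 1 − k/N for a top-k set at
w = 0 and is antisymmetric under ranking reversal. The null permutes gene
labels (random same-size sets); NES divides by the mean |null ES| of the
same sign and the p-value is the add-one same-sign tail.

## Bulk tissue scoring

The CD4 fraction of each bulk sample is the sum of CD4-labelled proportions
from deconvolving the TPM profile against a user-supplied immune signature
matrix (which CD4 columns to sum is an explicit input — the external
reference's grouping is not published). Samples with deconvolution
permutation p > 0.05 are excluded. Weighting by the CD4 fraction precedes
the log2(x + 1) transform, matching the stated order of operations, and
per-gene centering uses only retained samples, so scores are mean-zero per
gene across the cohort analyzed. Two-group comparisons use Welch's t test;
multi-group, one-way ANOVA.

## Synthetic data: what it emulates, and what it does not

Defaults are the study-scale conditions: 5 polarized subtypes (Treg, Th1,
Th2, pTh17, rTh17) with 3 replicates each plus an effector baseline of
shared sites only (so the gained/lost rule is exercised exactly as stated);
600 specific sites per subtype so that ≥ 500 survive 10% per-replicate
dropout at the 2/3 consensus rule; NB counts at dispersion 0.05 with an
8-fold signal-over-background contrast; lognormal library factors
(σ = 0.3, typical of ATAC/scRNA libraries); mixture noise multiplicative
lognormal σ = 0.1 (the original synthetic design states no noise magnitude;
σ = 0.1 — a ~10% coefficient of variation — is the package's choice,
matching the positivity and scale-dependence of accessibility signal, and
the headline validation numbers are evaluated at that default); flat
Dirichlet proportions; LD genomes of 200 disjoint blocks of 1–20 variants;
three single-cell clusters with disjoint planted marker sets (log2FC 2)
and `MT-` genes at a 5% expected count share; bulk cohorts of 15 + 15
samples mixing CD4/CD8/epithelial profiles with a log2 = 1 cytotoxic
effect inside the inflamed group's CD4 component.

All randomness derives from one seed through fixed per-generator salted
streams, so adding a generator call never perturbs another's output, and
identical configs give bit-identical outputs. The generators do **not**
emulate: genome sequence, fragment-level reads, GC or batch effects,
doublets, LD decay within blocks (blocks are exchangeable units), or
realistic gene-gene correlation. Passing recovery tests therefore shows
the estimators are correct under the assumed noise models, not that the
models capture every property of real libraries.

Two non-obvious generator notes. First, planting risk-block enrichment
with background rate b and excess δ requires b + δ ≤ 1 and at least one
catalog block inside the target set; a saturation setting (all risk blocks
inside) is expressed as δ = 1 − b. Second, cohort-level proportion
variability in the group-comparison power simulations uses
Dirichlet(30, 30, 30) (≈ 5-percentage-point spread), a realistic
biopsy-to-biopsy spread against which a +0.15 pTh17 shift is detectable at
the tested power.

## Problem sizes in the test and acceptance runs

The acceptance suite runs the validation experiment at full stated scale
(5 subtypes, ≥ 500 features each, 100 mixtures, 499 permutations). The
property checks use 50–200 simulation replicates per criterion with
matrices of a few hundred features/genes and cohorts of 16–30 samples —
sizes at which the binomial confidence intervals of the calibration checks
are informative while the whole suite stays fast.

## Known limitations

* The NB Wald test is a simplified stand-in for a full GLM framework: no
  quantile-adjusted dispersion (qCML), no quasi-likelihood moderation; its
  calibration is verified empirically at the tested sample sizes only.
* The empirical VSE p-value is lower-bounded by 1/(n_null + 1); detecting
  enrichment at Bonferroni-corrected p < 0.01 across many region sets
  requires proportionally more null sets.
* Deconvolution assumes the mixture is a non-negative combination of the
  reference profiles; collinear signature columns are flagged but not
  resolved, and proportions for such pairs are unstable.
* The signature score is a simple mean of centered expression; no control
  gene sets are subtracted, so scores are comparable within, not across,
  datasets.
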