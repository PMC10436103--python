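# tcellsig

Chromatin-accessibility signatures, reference-based deconvolution,
variant-set enrichment and transcriptional signature scoring for CD4 T-cell
subtypes in inflammatory bowel disease (IBD) — implemented as a tested,
reusable pipeline that runs end-to-end on generated data.

## The problem

Intestinal inflammation in IBD is driven by dysregulated CD4 T cells, but
bulk assays average over a mixture of subtypes (Th1, Th2, Treg, and the
pathogenic vs regulatory Th17 states, pTh17/rTh17). This package implements
the chain of computations that links ATAC-seq of in-vitro polarized CD4
subtypes and single-cell transcriptomes to tissue inflammation:

1. **ATAC signature construction** (`tcellsig.atac`) — merged peak catalogs
   over 0-based half-open BED intervals; *consensus sites* detected in at
   least a fraction (default 2/3, integer ceiling) of replicates; *gained* /
   *lost* sites of each polarized subtype relative to an effector baseline
   (`gained = subtype \ effector`); *subtype-specific* sites gained by
   exactly one subtype; a simplified negative-binomial Wald test for
   differential accessibility (TMM normalization, moment dispersion shrunk
   to the common value, Benjamini–Hochberg FDR); peak annotation against
   promoter windows (2.5 kb upstream to 0.5 kb downstream of the TSS) and
   correlation-based distal peak-to-gene linking (r ≥ 0.7 within ±500 kb).
2. **Deconvolution** (`tcellsig.deconvolution`) — a features × subtypes
   signature matrix S (mean accessibility of each subtype over its specific
   sites); mixture proportions f estimated by non-negative least squares,
   min ‖S·f − y‖² s.t. f ≥ 0, renormalized to the simplex (a ν-SVR engine
   is also provided); significance by feature-shuffle permutations of the
   profile with the reconstruction correlation as statistic, add-one rule.
   `validate_on_synthetic` reruns the validation design — Dirichlet-random
   mixtures with multiplicative lognormal noise — against the published
   thresholds: maximum per-mixture mean absolute error < 1 percentage point
   and maximum permutation p < 0.05. Estimated proportions below 1% can be
   flagged as censored (omitted, not redistributed).
3. **Variant-set enrichment** (`tcellsig.vse`) — risk variants expanded to
   LD blocks (r² ≥ 0.8, transitive merge); enrichment of a block set inside
   accessible-region sets scored against size-matched random block families;
   add-one empirical p, Bonferroni-corrected across region sets
   (significance at corrected p < 0.01).
4. **Single-cell signatures** (`tcellsig.singlecell`) — QC (≥ 200 genes
   detected, mitochondrial-fraction cap), log(CP10K + 1) normalization, the
   mean-centered expression `Er(i,j) = E(i,j) − mean_j E(i,·)`, per-cell
   signature scores as the mean Er over signature genes (cytotoxicity =
   GZMA, GZMB, GNLY, IFNG, PRF1; Th1 and Th17 panels included); Welch-t
   cluster markers and reference-derived signatures (log2FC > 1, FDR
   < 0.05); hypergeometric overlap tests; co-expression fractions;
   cytotoxic-cell classification; preranked GSEA with a permutation null.
5. **Bulk scoring** (`tcellsig.bulk`) — per-sample CD4 fraction from the
   deconvolution engine (samples with deconvolution p > 0.05 excluded), TPM
   columns weighted by that fraction, log2(x+1) + per-gene centering, and
   the tissue cytotoxic score compared across groups (Welch t test /
   one-way ANOVA).
6. **Synthetic data** (`tcellsig.simulate`) — generators for every input
   with planted ground truth: replicate peak landscapes with dropout,
   negative-binomial counts with library-size factors, signature mixtures,
   LD-block variant catalogs with plantable enrichment, clustered
   single-cell counts with markers and `MT-` genes, and bulk TPM mixtures
   with a plantable cytotoxic effect. All generators are deterministic in
   `(config, seed)`.

`tcellsig.pipelines` wires these into the end-to-end workflows and
`tcellsig.io` reads/writes the plain-text formats (BED, TSV, MTX, JSON).

## Worked example

Build a subtype signature from a generated landscape and validate the
deconvolution on synthetic mixtures:

```python
from tcellsig import pipelines, simulate, deconvolution

cfg = simulate.SimulationConfig(seed=1)        # 5 subtypes + effector, 3 reps
built = pipelines.build_subtype_signature(cfg)
print("catalog peaks:", len(built["catalog"]))
print("specific sites per subtype:",
      {s: len(v) for s, v in sorted(built["specific"].items())})

report = deconvolution.validate_on_synthetic(
    built["signature"], n_mixtures=100, noise_sigma=0.1,
    n_permutations=499, seed=1)
print(f"max mixture error: {report.max_error:.3f} percentage points")
print(f"max permutation p: {report.max_p:.3f}")
print("validation passed:", report.passed)
```

Output:

```
catalog peaks: 3998
specific sites per subtype: {'Th1': 586, 'Th2': 583, 'Treg': 592, 'pTh17': 585, 'rTh17': 586}
max mixture error: 0.313 percentage points
max permutation p: 0.002
validation passed: True
```

Every mixture's estimated proportions sit within a third of a percentage
point (mean absolute deviation) of the planted Dirichlet proportions, and
every permutation p is far below 0.05 — the two bounds the validation
design is judged by.

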