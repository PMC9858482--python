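# subsea

Subtype set enrichment analysis of tumor-microenvironment (TME) cell
infiltration, with the scoring and testing machinery around it.

## The problem

Molecular subtypes of a cancer (e.g. the PAM50 subtypes of breast cancer:
Luminal A/B, HER2-enriched, Basal-like, Normal-like) differ in their tumor
microenvironment — the immune and stromal cells infiltrating the tumor.
Given a bulk expression cohort with subtype labels, `subsea` answers: which
TME cell types are *specifically* enriched (or depleted) in which subtype,
and do those subtype-specific cells carry prognostic information? It is
aimed at computational oncology / tumor-immunology analysts working with
cohorts like METABRIC or TCGA-BRCA.

## The method

1. **Per-sample scoring.** Single-sample gene set enrichment (ssGSEA):
   within each sample, genes are ranked by expression and a gene set's score
   is the integral of the difference between the weighted in-set empirical
   CDF (weights = rank^α, α = 0.25) and the uniform out-of-set CDF. This
   drives the TME signature panel, the T-cell-inflamed GEP score, the
   ESTIMATE-style immune/stromal/purity scores, and marker-set-based cell
   infiltration abundance (cells × samples, shifted so each cell's cohort
   minimum is 0). The MHC score (mean of log-transformed, median-centered
   core MHC-I gene expression) and TMB (non-silent mutations per coding Mb)
   complete the per-sample feature table.

2. **Subtype set enrichment (SubSEA) — the core statistic.** For a cell
   type, rank the N samples by decreasing infiltration abundance r. For a
   subtype S, walk the ranked list accumulating

       F_hit(S,i) = Σ_{j∈S, j≤i} |r_j|^p / N_R,   N_R = Σ_{j∈S} |r_j|^p
       F_miss(S,i) = Σ_{j∉S, j≤i} / N_NotS

   The sample enrichment score SES is the signed maximum deviation of
   F_hit − F_miss (a weighted Kolmogorov–Smirnov statistic over samples;
   p = 1 by default). SES = +1 when the subtype packs the top of the list,
   −1 at the bottom, ≈ 0 when scattered. Significance comes from a
   gene-permutation null: shuffle gene labels, recompute abundances and SES,
   and set p = M/N where M counts permuted SES values more extreme than the
   observed one in its own direction. Pairs with p < 0.001 are called
   subtype-specific.

3. **Profiling and downstream testing.** Cohen's d with pooled SD
   (d = (M₁−M₂)/SD_pooled) for one-vs-rest subtype profiles with
   Mann–Whitney U p-values and Benjamini–Hochberg FDR; univariate Cox
   screens of specific cells within their subtype; maximally selected
   survival cutpoints with Kaplan–Meier/log-rank (the optimized split's
   naive p is flagged as selection-biased, with an optional
   permutation-adjusted p); chi-square tests of subtype-specific mutation
   and copy-number patterns (>1% frequency filter, FDR < 0.01, seeded
   Monte-Carlo p for sparse tables).

A seeded synthetic cohort generator (`subsea.synthetic`) produces
multi-omics cohorts with planted structure (subtype-shifted cell activity,
marker coexpression blocks, biased mutation/CNV rates, abundance-dependent
hazards) plus truth tables, so every stage is testable without any download.

## Worked example

Simulate a 70-sample cohort with two cell types and T cells planted into
subtype B at +2 SD, then run the analysis:

```bash
cat > cohort.yaml <<'YAML'
n_per_subtype: {A: 25, B: 25, C: 20}
n_genes: 400
cells:
  - {name: T_cells, n_markers: 12, lineage: immune}
  - {name: Fibroblasts, n_markers: 12, lineage: stromal}
planted_specific:
  - [T_cells, B, 2.0]
survival_spec: {baseline_hazard: 0.1, coefficients: {T_cells: 0.5}, censoring_rate: 0.3}
seed: 11
YAML
subsea simulate --config cohort.yaml --out cohort/
subsea run --expr cohort/expression.tsv --subtypes cohort/subtypes.tsv \
           --markers cohort/markers.gmt --n-perm 500 --seed 3 --out out/
```

Output (`out/specific_cells.tsv`):

```
cell     subtype  ses      n_extreme  n_perm  p_value  specific
T_cells  B         0.798   0          500     0.0      True
T_cells  A        -0.461   0          500     0.0      True
```

The planted pair is recovered: T-cell abundance is enriched at the top of
the ranking for subtype B (SES = 0.80) and, as the complement of that shift,
depleted in subtype A (SES = −0.46); no permuted SES was as extreme
(M = 0 of N = 500, p = 0). Fibroblasts, which received no planted shift,
are not called. The same library calls are available in Python
(`subsea.subsea_analysis`, `subsea.cox_screen`, ...).

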