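# Methods

This note documents the models and procedures implemented in `subsea`, the
parameter choices that matter, the statistical behavior of each stage, and
what the synthetic-cohort tests do and do not demonstrate about real data.

## Single-sample enrichment (ssGSEA)

For sample j, genes are ranked by decreasing expression; ties are broken by
gene-id lexicographic order so every score is fully deterministic. With G
genes, the gene at position i has rank value c = G − i + 1. For a gene set
of size m, walking down the ranking accumulates the difference between the
weighted in-set ECDF (in-set gene weights c^α) and the uniform out-of-set
ECDF; the score is the sum of that running difference over all G positions.
Because each gene's CDF contribution persists from its position to the end
of the list, the integral collapses exactly to

    ES = Σ_set c^(1+α) / Σ_set c^α − (G(G+1)/2 − Σ_set c) / (G − m),

which is what the matrix routine computes (O(m) per sample per set after
one sort). The literal running sum is retained as `ssgsea_one_sample` and
the two are tested for equality; an independent brute-force oracle in the
test suite re-derives scores from the definition in plain Python.

Parameters: `alpha` (rank weight exponent) defaults to 0.25, the common
ssGSEA convention; `normalize=True` divides the entire score matrix by its
global max − min (used for the GEP score). A score matrix that is exactly
constant cannot be rescaled; normalization is then a warned no-op. Set
genes absent from the matrix are dropped per set with a warning — they are
not treated as zero-expression genes. Scoring is rank-based, so any
strictly monotone within-sample transform of expression leaves scores
unchanged; consequently the declared input scale (`fpkm` vs `log2p1`)
matters only for the MHC score, which averages actual (log) expression
values.

## Per-sample TME features

- **MHC score** — per core MHC-I gene (HLA-A/B/C, TAP1/2, NLRC5, PSMB9,
  PSMB8, B2M), log2(x+1)-transform (if the input is linear FPKM) and center
  on the gene's median across patients; a sample's score is the mean of the
  centered values. Median centering makes the score a within-cohort
  contrast: it needs ≥ 2 samples and is not comparable across cohorts.
- **GEP score** — normalized ssGSEA score of the 18-gene T-cell-inflamed
  panel (bundled).
- **TMB** — non-silent variants per coding megabase. The coding-area
  denominator is a config parameter, default 38 Mb (a standard exome
  estimate). The non-silent vocabulary defaults to the usual MAF
  protein-affecting classes and is configurable; unknown classes are a hard
  error unless `lenient`.
- **ESTIMATE-style scores** — immune and stromal ssGSEA scores of
  user-supplied gene sets, their sum, and tumor purity via the original
  cos-transform calibration cos(0.6049872018 + 0.0001467884·combined),
  clamped to [0, 1]. The transform's constants were calibrated on the
  original method's score scale; with other gene sets the absolute purity
  values should be read as indicative only, and `purity_in_range` flags
  samples inside the monotone-decreasing region of the transform.
- **TME signature panel** — 8 fixed set names (cytolytic activity,
  lymphocytes, hypoxia, lymphangiogenesis, stromal, glycolysis, lipid
  metabolism, pentose phosphate pathway). The bundled gene memberships are
  synthetic stand-ins (the published memberships are not redistributed
  here); users supply their own GMT for real analyses.

## Cell infiltration abundance

Each cell type is a marker gene set scored by raw ssGSEA per sample, then
shifted per cell so the cohort minimum is exactly 0. Non-negative
abundances make the |r|^p weights of the downstream statistic directionally
unambiguous. The scorer is deliberately pluggable: output from dedicated
tools (e.g. xCell) can be loaded from TSV instead and flows through the
same downstream interface. Cells with fewer than 2 usable markers are
dropped with a warning. Note the sample enrichment statistic is invariant
to positive rescaling of abundances but not to shifts; the min-0 convention
is therefore part of the statistic's definition here.

## Subtype set enrichment (SubSEA)

Samples are ranked by decreasing abundance; ties are broken by sample id
(stable sort), making the statistic deterministic — the running-sum
definition assumes a total order. Walking positions i = 1..N,

    F_hit(S,i) = Σ_{j∈S, j≤i} |r_j|^p / N_R,  F_miss(S,i) = Σ_{j∉S, j≤i} / N_NotS,

and SES is the signed value of D = F_hit − F_miss at the position of
maximal |D|. Among positions whose |D| ties (within 1e-12, so float
rounding cannot override the rule), the earliest wins. The weight exponent
p defaults to 1; p = 0 reduces |SES| to the classic two-sample KS statistic
between member and non-member rank distributions (tested against scipy).
Exact identities: SES = +1 iff the subtype occupies the top |S| ranks, −1
iff the bottom, and |SES| ≤ 1 always.

**Null model.** Gene labels of the expression matrix are permuted — one
global relabeling per permutation, shared by all cells, which is the
computationally coherent reading of a gene-label shuffle (per-cell
independent shuffles are available as a flag). Abundances and SES are then
recomputed exactly as in the observed pipeline. Since per-gene expression
vectors are preserved and scoring is positional, a permuted marker set is a
uniformly random set of rows of the rank matrix; the implementation
exploits this with the closed form above, and a test verifies the
vectorized engine equals literally relabeling the matrix and rerunning the
observed path. p = M/N counts permuted SES values beyond the observed one
in its own direction; SES = 0 is treated as maximally null-like (p = 1).
An add-one correction (M+1)/(N+1) is available but off by default, matching
the plain M/N definition. Default n_perm = 1000, the minimum resolution for
the default specificity threshold alpha = 0.001 (strict inequality); a
warning fires when alpha < 1/n_perm. SubSEA p-values are reported raw, as
the method defines them; BH-adjusted values are appended as an extra column
but do not drive the `specific` call.

**Calibration caveat.** The gene-permutation null is exactly exchangeable
with the observed scorer only when marker genes are statistically like
random genes. When markers are strongly co-expressed (as real cell markers
are), observed abundances have heavier weight spread than permuted ones and
the null is mildly misspecified — a known property of gene-permutation
nulls in enrichment analysis. The calibration suite therefore zeroes marker
coexpression in its null cohorts; the recovery suite keeps coexpressed
markers and planted effects, and its decoy false-call rate empirically
stays at the nominal level under the simulated conditions.

## Effect sizes and group tests

Cohen's d uses the pooled standard deviation
sqrt((SS₁+SS₂)/(df₁+df₂)); a zero pooled SD yields a NaN sentinel (flagged,
never ±inf) so downstream heatmaps stay finite. d is affine-invariant and
antisymmetric under group swap (property-tested). Interpretive bands:
|d| < 0.2 small, 0.5–0.8 medium, > 0.8 large. One-vs-rest profiles compute
d plus a two-sided Mann–Whitney U p per feature × subtype; BH-FDR is
applied over the whole feature × subtype family of one analysis (one
heatmap = one correction family), configurable. MWU uses the exact
distribution for small tie-free groups and the tie-corrected normal
approximation otherwise; two identical constant groups get p = 1 by
convention. Kruskal–Wallis supplies the overall K-group test, with star
labels at the conventional 0.05/0.01/0.001/0.0001 thresholds.

## Survival screening

Univariate Cox proportional-hazards fits (lifelines, Efron ties) of
survival on continuous abundance, one fit per (subtype, cell), restricted
to that subtype's samples; subtypes without events and constant covariates
are skipped with warnings; the screening significance threshold defaults to
p < 0.01. The maximally selected cutpoint scans all observed values whose
high/low split keeps at least `minprop` (default 0.1) of samples on each
side and picks the split maximizing the absolute standardized log-rank
statistic; the scan is rank-based, so monotone transforms of the covariate
select the same split. The reported log-rank p of the chosen split is the
naive one and is anti-conservative by construction — the result carries a
`selection_biased` flag, and a permutation-adjusted p (max-statistic null
under joint (time, event) permutation) is available. The sample-size gate
for cutpoint selection is exposed as `min_n` (default 20). One behavioral
note: under complete separation the maximal log-rank statistic can prefer a
split one sample off the perfectly balanced boundary; this is a property of
the statistic, not an implementation artifact.

## Subtype-specific aberrations

Variant calls are binarized to gene × sample 0/1 (≥ 1 qualifying non-silent
variant; idempotent), genes at cohort frequency strictly > 1% are retained,
and each gene's 2 × K mutated/wild-type-by-subtype table is tested by
chi-square without continuity correction. BH-FDR across the tested genes;
`specific` at FDR < 0.01 (strict). Genes mutated in no or all samples are
degenerate and excluded. When any expected cell count is < 5 the asymptotic
chi-square tail is unreliable (empirically anti-conservative by an order of
magnitude in the far tail), so such genes get a seeded Monte-Carlo p by
default: tables are redrawn conditional on both margins (multivariate
hypergeometric) and p = (1 + #{χ²_sim ≥ χ²_obs})/(n_sim + 1). The
Monte-Carlo resolution must sit well below the decision threshold — with BH
at q = 0.01 over tens of genes, n_sim of 10⁴–2·10⁴ is appropriate; the
default n_sim = 2000 mirrors common practice and suffices for q = 0.05
analyses. CNV codes in {−2,−1,0,1,2} are split into amplification (> 0) and
deletion (< 0) indicators — optionally ±2 only — and the two directions are
tested as independent BH families.

## Synthetic cohorts

The generator draws, per cell type c and sample j, a latent activity
a_cj ~ N(0,1), adds δ to samples of a planted (cell, subtype, δ) pair, and
loads the activity onto the cell's disjoint marker block with coefficient
`marker_loading` (default 1.0 SD of expression per SD of activity) on top
of N(0,1) log-scale noise; the matrix is shifted non-negative and declared
log2p1. Default subtype proportions mirror the PAM50 composition of a large
breast-cancer cohort (largest-remainder split of 199:220:679:461:140).
Mutations are per-gene × subtype Bernoulli draws; CNV codes draw
amplification/deletion per subtype with half the calls high-level (±2).
Survival times are exponential with log-hazard Σ_c β_c · z(a_c) on the
standardized activities, censored administratively at the empirical
(1 − censoring_rate) quantile of the drawn times (default censoring 0.3),
so the realized censoring rate matches the target by construction. Truth
tables (latent activities, planted pairs, biased genes, coefficients) ship
with every cohort so recovery tests never re-derive the design.

`null_cohort` zeroes *every* effect, including marker coexpression, which
makes marker sets exchangeable with permuted gene sets — the condition
under which permutation p-values are exactly uniform. What the synthetic
cohorts do not emulate: gene–gene correlation beyond marker blocks, batch
effects, subtype-correlated library composition, realistic marker overlap
between related cell types, and non-proportional hazards. Passing the
recovery and calibration suites therefore demonstrates correctness of the
statistics under their stated assumptions, not performance on real cohorts.

## Problem sizes used in the checks

The statistical suites run at sizes chosen to make their Monte-Carlo error
small relative to the asserted margins while staying desk-scale: 1000
random instances for the enumeration oracle; a 150-sample, 10-cell,
5-subtype cohort with 200 permutations for calibration; 20 runs of a
250-sample, 5-cell cohort with 1000 permutations for recovery (δ = 1.5 SD,
30 markers); 200 + 500 replicates of n = 200 for Cox recovery and type-I
error; 20 runs of a 500-sample cohort with 5 planted and 50 decoy genes for
mutation specificity. One caution on the last suite: an FDR procedure at
q = 0.01 over 55 genes legitimately produces ≥ 1 null discovery in ~5% of
runs, so "zero false flags per run" is not a property any calibrated
implementation can guarantee in 19 of 20 runs with high probability; the
decoy-clean run rate should be read as an estimate near 95%, not a floor.
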