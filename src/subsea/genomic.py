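"""Subtype-specific somatic mutation and copy-number analysis.

Long-form variant calls are binarized to a gene x sample 0/1 matrix, genes
below a cohort-wide frequency floor are dropped (strictly greater than 1%
by default), and each remaining gene is tested for subtype specificity with
a chi-square test on its 2 x K mutated/wild-type by subtype contingency
table (no continuity correction, matching standard practice for K > 2
tables). BH-FDR is applied across the gene family; genes with FDR < 0.01
are called subtype-specific. Amplifications (code > 0) and deletions
(code < 0) are tested the same way as two independent families.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import CNVMatrix, MutationTable, SubtypeAnnotation
from .effect_size import bh_fdr
from .features import NONSILENT_CLASSES

logger = logging.getLogger("subsea")

DEFAULT_MIN_RATE = 0.01
DEFAULT_FDR_THRESHOLD = 0.01


def binarize_mutations(table: MutationTable, samples: list[str],
                       qualifying_classes: frozenset[str] = NONSILENT_CLASSES) -> pd.DataFrame:
    """Gene x sample 0/1 matrix: 1 iff the sample carries >= 1 qualifying
    variant of the gene. Samples without variants get all-zero columns;
    repeated (sample, gene) hits collapse to a single 1 (idempotent)."""
    tab = table.table
    tab = tab[tab["Variant_Classification"].isin(qualifying_classes)]
    tab = tab[tab["Tumor_Sample_Barcode"].isin(set(samples))]
    if tab.empty:
        warnings.warn("no qualifying variants; mutation matrix is all zero", stacklevel=2)
        return pd.DataFrame(0, index=pd.Index([], dtype=str), columns=list(samples), dtype=int)
    mat = (pd.crosstab(tab["Hugo_Symbol"], tab["Tumor_Sample_Barcode"]) > 0).astype(int)
    mat = mat.reindex(columns=list(samples), fill_value=0)
    mat.index.name = None
    mat.columns.name = None
    return mat


def filter_by_frequency(matrix: pd.DataFrame, min_rate: float = DEFAULT_MIN_RATE) -> list[str]:
    """Genes whose cohort-wide mutation rate is strictly greater than
    ``min_rate`` (a gene mutated in exactly min_rate of samples is dropped)."""
    if not 0 < min_rate < 1:
        raise ValueError("min_rate must lie in (0, 1)")
    rate = matrix.mean(axis=1)
    return list(matrix.index[rate > min_rate])


def _mc_chi2_pvalue(counts: np.ndarray, sizes: np.ndarray, chi2_obs: float,
                    rng: np.random.Generator, n_sim: int) -> float:
    """Monte-Carlo p-value of the 2 x K chi-square statistic, conditional on
    both margins (mutated samples assigned by multivariate hypergeometric)."""
    m = int(counts.sum())
    n = int(sizes.sum())
    e1 = sizes * m / n
    e0 = sizes - e1
    sims = rng.multivariate_hypergeometric(sizes, m, size=n_sim)
    chi2_sim = ((sims - e1) ** 2 / e1 + (sims - e1) ** 2 / e0).sum(axis=1)
    return float((1 + (chi2_sim >= chi2_obs - 1e-9).sum()) / (n_sim + 1))


def _chi2_by_subtype(indicator: pd.DataFrame, subtypes: SubtypeAnnotation,
                     fdr_threshold: float, monte_carlo: str = "never",
                     n_sim: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Chi-square specificity of a gene x sample 0/1 indicator matrix."""
    if monte_carlo not in ("never", "auto", "always"):
        raise ValueError("monte_carlo must be 'never', 'auto' or 'always'")
    labels = subtypes.labels.loc[indicator.columns]
    levels = sorted(labels.unique())
    group_sizes = {lvl: int((labels == lvl).sum()) for lvl in levels}
    rng = np.random.default_rng(seed)
    rows = []
    for gene in indicator.index:
        vec = indicator.loc[gene].to_numpy(dtype=int)
        total = int(vec.sum())
        if total == 0 or total == len(vec):
            logger.info("gene %s excluded: mutated in %d of %d samples (degenerate)",
                        gene, total, len(vec))
            continue
        counts = {lvl: int(vec[(labels == lvl).to_numpy()].sum()) for lvl in levels}
        table = np.array([[counts[lvl] for lvl in levels],
                          [group_sizes[lvl] - counts[lvl] for lvl in levels]])
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        low_expected = bool((expected < 5).any())
        if monte_carlo == "always" or (monte_carlo == "auto" and low_expected):
            p = _mc_chi2_pvalue(np.array([counts[lvl] for lvl in levels]),
                                np.array([group_sizes[lvl] for lvl in levels]),
                                float(chi2), rng, n_sim)
        row = {"gene": gene, "chi2": float(chi2), "p": float(p),
               "low_expected": low_expected}
        for lvl in levels:
            row[f"n_{lvl}"] = counts[lvl]
            row[f"rate_{lvl}"] = counts[lvl] / group_sizes[lvl]
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["specific"] = out["fdr"] < fdr_threshold
    return out.sort_values("p").reset_index(drop=True)


def subtype_specific_mutations(matrix: pd.DataFrame, subtypes: SubtypeAnnotation,
                               fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                               monte_carlo: str = "auto", n_sim: int = 2000,
                               seed: int = 0) -> pd.DataFrame:
    """Per-gene chi-square test of mutated/wild-type by subtype.

    ``matrix`` is the binarized (and typically frequency-filtered) gene x
    sample matrix. Genes mutated in no or all samples are excluded as
    degenerate. FDR is BH across the tested genes; ``specific`` flags
    fdr < threshold (default 0.01). Expected counts below 5 set the
    ``low_expected`` warning column; by default (``monte_carlo="auto"``)
    those genes get a seeded Monte-Carlo p conditional on both table
    margins, because the asymptotic chi-square tail is unreliable for
    sparse tables ("never"/"always" switch the behavior).
    """
    if len(set(matrix.columns) - set(subtypes.sample_ids)):
        raise ValueError("mutation matrix has samples without subtype labels")
    return _chi2_by_subtype(matrix, subtypes, fdr_threshold,
                            monte_carlo=monte_carlo, n_sim=n_sim, seed=seed)


def subtype_specific_cnv(cnv: CNVMatrix, subtypes: SubtypeAnnotation,
                         fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                         high_level_only: bool = False, monte_carlo: str = "auto",
                         n_sim: int = 2000, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Amplification and deletion specificity, tested independently.

    Amplification indicator = code > 0, deletion indicator = code < 0
    (``high_level_only`` restricts to codes +/-2). Each direction forms its
    own BH family. Returns (amp_rows, del_rows).
    """
    vals = cnv.values
    amp_floor = 2 if high_level_only else 1
    amp = (vals >= amp_floor).astype(int)
    dele = (vals <= -amp_floor).astype(int)
    amp_rows = _chi2_by_subtype(amp, subtypes, fdr_threshold,
                                monte_carlo=monte_carlo, n_sim=n_sim, seed=seed)
    del_rows = _chi2_by_subtype(dele, subtypes, fdr_threshold,
                                monte_carlo=monte_carlo, n_sim=n_sim, seed=seed)
    return amp_rows, del_rows
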