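"""Cell-based subtype set enrichment analysis (SubSEA).

For one cell type, the cohort's samples are ranked by decreasing infiltration
abundance r. Walking positions i = 1..N down the ranked list L, with S the
set of samples of one subtype,

    F_hit(S, i)  = sum_{j in S, j <= i} |r_j|^p / N_R,   N_R = sum_{j in S} |r_j|^p
    F_miss(S, i) = sum_{j not in S, j <= i} 1 / N_NotS

and the sample enrichment score (SES) is the signed value of
D(i) = F_hit - F_miss at the position where |D| is maximal (the weighted
Kolmogorov-Smirnov statistic over samples). SES = 1 when the subtype packs
the top of the list, -1 when it packs the bottom, and is small when the
subtype is scattered. The weight exponent p defaults to 1.

Significance comes from a gene-permutation null: gene labels of the
expression matrix are shuffled (one global relabeling per permutation), cell
abundances are recomputed with the same scorer, and SES is recomputed for
every (cell, subtype). The empirical p-value is M/N with M the number of
permuted SES values more extreme than the observed one in its own direction.
Cells with p < 0.001 against a subtype are called subtype-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSetCollection, SubtypeAnnotation, match_genes
from .enrichment import DEFAULT_ALPHA, rank_values, scores_from_rank_values
from .infiltration import CellAbundanceMatrix, cell_abundance

DEFAULT_WEIGHT_P = 1.0  # abundance weight exponent
DEFAULT_SPECIFICITY_ALPHA = 0.001


def running_difference(abundances: np.ndarray, member_mask: np.ndarray,
                       p: float = DEFAULT_WEIGHT_P) -> np.ndarray:
    """D(i) = F_hit - F_miss along an already-ranked sample list."""
    r = np.abs(np.asarray(abundances, dtype=float))
    mask = np.asarray(member_mask, dtype=bool)
    n_in = int(mask.sum())
    if n_in == 0 or n_in == len(mask):
        raise ValueError("subtype must be a proper, non-empty subset of the samples")
    w = np.where(mask, r ** p, 0.0)
    n_r = w.sum()
    if n_r == 0:
        raise ValueError("all member abundances are zero (N_R = 0)")
    f_hit = np.cumsum(w) / n_r
    f_miss = np.cumsum(~mask) / (len(mask) - n_in)
    return f_hit - f_miss


def sample_enrichment_score(abundances, member_mask, p: float = DEFAULT_WEIGHT_P,
                            sample_ids=None) -> float:
    """SES for one (cell, subtype): signed maximum deviation of D(i).

    ``abundances`` need not be pre-sorted; samples are ranked by decreasing
    abundance with ties broken by sample id (or input position when ids are
    not given), making the statistic deterministic. Among positions with
    equal |D| the earliest wins.
    """
    r = np.asarray(abundances, dtype=float)
    mask = np.asarray(member_mask, dtype=bool)
    if r.shape != mask.shape:
        raise ValueError("abundances and membership mask differ in length")
    if sample_ids is not None:
        tie = np.argsort(np.argsort(np.asarray(sample_ids, dtype=str), kind="stable"))
    else:
        tie = np.arange(len(r))
    order = np.lexsort((tie, -r))
    d = running_difference(r[order], mask[order], p=p)
    return float(d[_argmax_abs(np.abs(d))])


#: tolerance for |D| ties; rounding noise must not override the
#: earliest-position tie-break rule
_TIE_EPS = 1e-12


def _argmax_abs(abs_d: np.ndarray) -> int:
    m = abs_d.max()
    return int(np.argmax(abs_d >= m - _TIE_EPS))


def _ses_batch(abund: np.ndarray, masks: np.ndarray, p: float) -> np.ndarray:
    """SES for a batch of abundance rows against several subtype masks.

    ``abund``: (B, N) rows of per-sample abundances, columns already in the
    deterministic tie-break order (sample id); ``masks``: (K, N) boolean.
    Returns (K, B).
    """
    B, N = abund.shape
    order = np.argsort(-abund, axis=1, kind="stable")
    r = np.take_along_axis(np.abs(abund), order, axis=1)
    rp = r ** p
    out = np.empty((masks.shape[0], B), dtype=float)
    for k, mask in enumerate(masks):
        msk = mask[order]  # (B, N)
        w = rp * msk
        n_r = w.sum(axis=1)
        if np.any(n_r == 0):
            bad = int(np.nonzero(n_r == 0)[0][0])
            raise ValueError(f"N_R = 0 for batch row {bad}, subtype index {k}")
        f_hit = np.cumsum(w, axis=1) / n_r[:, None]
        f_miss = np.cumsum(~msk, axis=1) / float(N - mask.sum())
        d = f_hit - f_miss
        abs_d = np.abs(d)
        m = abs_d.max(axis=1, keepdims=True)
        idx = np.argmax(abs_d >= m - _TIE_EPS, axis=1)  # earliest within tolerance
        out[k] = d[np.arange(B), idx]
    return out


@dataclass
class NullDistributions:
    """Permutation SES values: array (n_cells, n_subtypes, n_perm)."""

    values: np.ndarray
    cells: list[str]
    subtypes: list[str]
    n_perm: int
    seed: int

    def vector(self, cell: str, subtype: str) -> np.ndarray:
        return self.values[self.cells.index(cell), self.subtypes.index(subtype)]


def _marker_rows(expr: ExpressionMatrix, markers: GeneSetCollection,
                 min_markers: int) -> tuple[pd.Index, np.ndarray, dict[str, np.ndarray]]:
    genes, c = rank_values(expr)
    lookup = {g: i for i, g in enumerate(genes)}
    rows = {}
    for cell, gene_set in markers.sets.items():
        present = match_genes(gene_set, lookup, set_name=cell)
        if len(present) < min_markers:
            continue
        rows[cell] = np.array([lookup[g] for g in present])
    if not rows:
        raise ValueError("no cell has enough usable markers")
    return genes, c, rows


def _subtype_masks(subtypes: SubtypeAnnotation, sample_ids: list[str]) -> tuple[list[str], np.ndarray]:
    labels = subtypes.labels.loc[sample_ids]
    levels = sorted(labels.unique())
    masks = np.stack([(labels == lvl).to_numpy() for lvl in levels])
    return levels, masks


def gene_permutation_null(expr: ExpressionMatrix, marker_collection: GeneSetCollection,
                          subtypes: SubtypeAnnotation, n_perm: int, seed: int,
                          ssgsea_alpha: float = DEFAULT_ALPHA,
                          p: float = DEFAULT_WEIGHT_P, min_markers: int = 2,
                          per_cell_shuffle: bool = False,
                          chunk: int = 200) -> NullDistributions:
    """Null SES distributions per (cell, subtype) under gene-label shuffling.

    Each permutation relabels the genes of the expression matrix once
    (globally, shared by all cells unless ``per_cell_shuffle``), recomputes
    every cell's abundance with the same ssGSEA scorer and min-0 shift, and
    recomputes SES for every (cell, subtype) pair. Per-gene expression
    vectors are preserved exactly; only the label-to-row assignment moves,
    so under the null a marker set is a uniformly random set of rows.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # deterministic tie-break: work in sample-id-sorted column order
    id_order = sorted(expr.sample_ids)
    expr_sorted = expr.subset_samples(id_order)
    genes, c, rows = _marker_rows(expr_sorted, marker_collection, min_markers)
    levels, masks = _subtype_masks(subtypes, id_order)
    G = c.shape[0]
    ca = c ** ssgsea_alpha
    c1a = c * ca
    total = G * (G + 1) / 2.0
    cells = list(rows)
    null = np.empty((len(cells), len(levels), n_perm), dtype=float)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        if per_cell_shuffle:
            perms = {cell: np.stack([rng.permutation(G) for _ in range(b)]) for cell in cells}
        else:
            shared = np.stack([rng.permutation(G) for _ in range(b)])
            perms = {cell: shared for cell in cells}
        for ci, cell in enumerate(cells):
            sel = perms[cell][:, rows[cell]]  # (b, m) permuted row indices
            m = sel.shape[1]
            try:
                hit = c1a[sel].sum(axis=1) / ca[sel].sum(axis=1)  # (b, n)
                miss = (total - c[sel].sum(axis=1)) / (G - m)
                scores = hit - miss
                scores -= scores.min(axis=1, keepdims=True)
                null[ci, :, done:done + b] = _ses_batch(scores, masks, p)
            except ValueError as exc:
                raise RuntimeError(
                    f"scorer failed for cell {cell!r} at permutation block "
                    f"starting {done}: {exc}") from exc
        done += b
    return NullDistributions(null, cells, levels, n_perm, seed)


def ses_pvalue(observed_ses: float, null_vector, add_one: bool = False) -> tuple[float, int]:
    """Empirical p-value of an observed SES against its permutation null.

    M counts permuted SES values greater than the observed one when it is
    positive, and smaller when negative; p = M/N (or (M+1)/(N+1) with the
    add-one correction). An observed SES of exactly 0 is treated as
    maximally null-like (M = N).
    """
    null = np.asarray(null_vector, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    n = null.size
    if observed_ses > 0:
        m = int((null > observed_ses).sum())
    elif observed_ses < 0:
        m = int((null < observed_ses).sum())
    else:
        m = n
    if add_one:
        return (m + 1) / (n + 1), m
    return m / n, m


def call_subtype_specific(results: pd.DataFrame,
                          alpha: float = DEFAULT_SPECIFICITY_ALPHA) -> pd.DataFrame:
    """Rows with p strictly below ``alpha``, sorted by (subtype, p, -|ses|)."""
    if results.empty:
        return results
    hits = results[results["p_value"] < alpha].copy()
    hits["abs_ses"] = hits["ses"].abs()
    hits = hits.sort_values(["subtype", "p_value", "abs_ses"],
                            ascending=[True, True, False]).drop(columns="abs_ses")
    return hits.reset_index(drop=True)


def observed_ses_table(abundance: CellAbundanceMatrix, subtypes: SubtypeAnnotation,
                       p: float = DEFAULT_WEIGHT_P) -> pd.DataFrame:
    """Observed SES for every (cell, subtype) pair."""
    id_order = sorted(abundance.sample_ids)
    vals = abundance.values.loc[:, id_order].to_numpy(dtype=float)
    levels, masks = _subtype_masks(subtypes, id_order)
    ses = _ses_batch(vals, masks, p)  # (K, n_cells)
    rows = []
    for ci, cell in enumerate(abundance.cell_names):
        for ki, lvl in enumerate(levels):
            rows.append({"cell": cell, "subtype": lvl, "ses": ses[ki, ci]})
    return pd.DataFrame(rows)


def subsea_analysis(expr: ExpressionMatrix, marker_collection: GeneSetCollection,
                    subtypes: SubtypeAnnotation, n_perm: int = 1000, seed: int = 0,
                    specificity_alpha: float = DEFAULT_SPECIFICITY_ALPHA,
                    p: float = DEFAULT_WEIGHT_P, ssgsea_alpha: float = DEFAULT_ALPHA,
                    lineage_map: dict[str, str] | None = None,
                    add_one: bool = False, add_bh: bool = True,
                    per_cell_shuffle: bool = False) -> pd.DataFrame:
    """Full SubSEA run: abundance, observed SES, permutation null, calls.

    Returns one row per (cell, subtype) with columns cell, subtype, lineage,
    ses, n_extreme (M), n_perm (N), p_value and the boolean ``specific``
    flag (p < specificity_alpha, strict). ``add_bh`` appends BH-adjusted
    p-values as an extra column; the specificity call stays on the raw p.
    """
    if specificity_alpha < 1.0 / n_perm:
        warnings.warn(
            f"alpha={specificity_alpha} is below the permutation resolution "
            f"1/{n_perm}; calls require the observed SES to beat every permutation",
            stacklevel=2,
        )
    abund = cell_abundance(expr, marker_collection, lineage_map=lineage_map,
                           alpha=ssgsea_alpha)
    obs = observed_ses_table(abund, subtypes, p=p)
    null = gene_permutation_null(expr, marker_collection, subtypes, n_perm, seed,
                                 ssgsea_alpha=ssgsea_alpha, p=p,
                                 per_cell_shuffle=per_cell_shuffle)
    pvals, ms = [], []
    for _, row in obs.iterrows():
        pv, m = ses_pvalue(row["ses"], null.vector(row["cell"], row["subtype"]),
                           add_one=add_one)
        pvals.append(pv)
        ms.append(m)
    obs["lineage"] = abund.lineage.loc[obs["cell"]].to_numpy()
    obs["n_extreme"] = ms
    obs["n_perm"] = n_perm
    obs["p_value"] = pvals
    obs["specific"] = obs["p_value"] < specificity_alpha
    if add_bh:
        from .effect_size import bh_fdr
        obs["bh_fdr"] = bh_fdr(obs["p_value"].to_numpy())
    return obs
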