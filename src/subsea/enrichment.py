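"""Single-sample gene set enrichment (ssGSEA).

For one sample, genes are ranked by expression in decreasing order (ties
broken by gene id, so scores are fully deterministic). Walking down the
ranking, the score accumulates the difference between the weighted in-set
empirical CDF — in-set genes weighted by rank^alpha, where the top gene has
rank G — and the uniform out-of-set CDF; the enrichment score is the sum of
that running difference over all positions (the Barbie-style integral).

Because each gene's CDF contribution persists from its position to the end
of the list, the integral collapses to a closed form over in-set genes only:

    ES = sum(c_g^(1+alpha)) / sum(c_g^alpha)
         - (G(G+1)/2 - sum(c_g)) / (G - m)

with c_g = G - position(g) + 1 the rank value of in-set gene g, G the number
of genes and m the set size. ``ssgsea_scores`` uses this identity (exact, not
an approximation); ``ssgsea_one_sample`` keeps the literal running sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSetCollection, match_genes

DEFAULT_ALPHA = 0.25


@dataclass
class SignatureScoreMatrix:
    """Set x sample enrichment scores; ``normalized`` records whether the
    whole matrix was divided by its global (max - min)."""

    values: pd.DataFrame
    normalized: bool = False

    @property
    def set_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _check_matrix(expr: ExpressionMatrix) -> None:
    if expr.n_genes < 2:
        raise ValueError("ssGSEA needs >= 2 genes to rank")


def rank_values(expr: ExpressionMatrix) -> tuple[pd.Index, np.ndarray]:
    """Rank value c for every gene in every sample (genes x samples).

    c = G for the most expressed gene down to 1 for the least, ties broken
    by gene-id lexicographic order (earlier id gets the higher rank value).
    Returns (gene index in lexicographic order, rank-value matrix aligned
    to that order).
    """
    _check_matrix(expr)
    df = expr.values.sort_index(kind="stable")
    arr = df.to_numpy(dtype=float)
    G = arr.shape[0]
    # stable argsort of -expr: equal values keep lexicographic gene order
    order = np.argsort(-arr, axis=0, kind="stable")  # order[i, j] = gene at position i
    pos = np.empty_like(order)
    cols = np.arange(arr.shape[1])
    pos[order, cols] = np.arange(G)[:, None]
    c = (G - pos).astype(float)  # rank value: position 0 -> G
    return df.index, c


def scores_from_rank_values(c: np.ndarray, set_rows: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form ssGSEA scores for one set (rows into the rank-value
    matrix), vectorized across samples."""
    G = c.shape[0]
    m = len(set_rows)
    if m == 0:
        raise ValueError("gene set has no genes in the matrix")
    if m >= G:
        raise ValueError("gene set covers the whole matrix; no out-of-set genes")
    sel = c[set_rows, :]
    w = sel ** alpha
    hit = (sel * w).sum(axis=0) / w.sum(axis=0)
    total = G * (G + 1) / 2.0
    miss = (total - sel.sum(axis=0)) / (G - m)
    return hit - miss


def ssgsea_one_sample(expr_column: pd.Series, gene_set: list[str],
                      alpha: float = DEFAULT_ALPHA) -> float:
    """Literal running-sum enrichment score for a single sample.

    Kept as the transparent reference path; the matrix routine uses the
    algebraically identical closed form.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    col = expr_column.sort_index(kind="stable")
    G = len(col)
    if G < 2:
        raise ValueError("ssGSEA needs >= 2 genes to rank")
    present = [g for g in gene_set if g in col.index]
    if not present:
        raise ValueError("no gene of the set is present in the sample")
    if len(present) >= G:
        raise ValueError("gene set covers the whole matrix; no out-of-set genes")
    vals = col.to_numpy(dtype=float)
    order = np.argsort(-vals, kind="stable")
    in_set = np.isin(np.asarray(col.index), present)[order]
    c = np.arange(G, 0, -1, dtype=float)  # rank value at each position
    w = np.where(in_set, c ** alpha, 0.0)
    f_hit = np.cumsum(w) / w.sum()
    f_miss = np.cumsum(~in_set) / (G - len(present))
    return float(np.sum(f_hit - f_miss))


def ssgsea_scores(expr: ExpressionMatrix, collection: GeneSetCollection,
                  alpha: float = DEFAULT_ALPHA, normalize: bool = False) -> SignatureScoreMatrix:
    """Per-set, per-sample enrichment scores.

    Genes of a set absent from the matrix are dropped (with a warning);
    ``normalize`` divides the whole matrix by its global max - min, the
    ssGSEA normalization convention.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes, c = rank_values(expr)
    lookup = {g: i for i, g in enumerate(genes)}
    out = {}
    for name, gene_set in collection.sets.items():
        present = match_genes(gene_set, lookup, set_name=name)
        if not present:
            raise ValueError(f"gene set {name!r}: no gene present in the matrix")
        rows = np.array([lookup[g] for g in present])
        try:
            out[name] = scores_from_rank_values(c, rows, alpha)
        except ValueError as exc:
            raise ValueError(f"gene set {name!r}: {exc}") from exc
    scores = pd.DataFrame(out, index=expr.sample_ids).T
    scores.columns = expr.sample_ids
    if normalize:
        span = scores.to_numpy().max() - scores.to_numpy().min()
        if span == 0:
            # all scores identical: rescaling is undefined and unnecessary
            warnings.warn("score matrix is constant; normalization left it unchanged",
                          stacklevel=2)
        else:
            scores = scores / span
    return SignatureScoreMatrix(scores, normalized=normalize)


def write_scores(scores: SignatureScoreMatrix, path) -> None:
    scores.values.rename_axis("set_name").to_csv(path, sep="\t")
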