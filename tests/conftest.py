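"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive the statistics from their
definitions with plain Python loops, independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from subsea.data import ExpressionMatrix, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_expr(rng):
    """30 genes x 8 samples of positive noise, declared log2p1."""
    vals = rng.gamma(2.0, 2.0, size=(30, 8))
    genes = [f"G{i:03d}" for i in range(30)]
    samples = [f"S{j}" for j in range(8)]
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), "log2p1")


@pytest.fixture
def toy_collection():
    return GeneSetCollection({
        "setA": ["G000", "G005", "G010"],
        "setB": ["G001", "G002", "G003", "G004"],
        "setC": ["G020", "G025"],
    })


def brute_ssgsea(column: pd.Series, gene_set, alpha: float) -> float:
    """Literal walk down the ranking, accumulating F_hit - F_miss.

    Genes ranked by decreasing expression, ties broken by gene id.
    In-set genes weighted by rank_value^alpha where the top gene has rank
    value G; score is the sum of the running difference over positions.
    """
    items = sorted(column.items(), key=lambda kv: (-kv[1], kv[0]))
    G = len(items)
    in_set = set(g for g in gene_set if g in column.index)
    n_out = G - len(in_set)
    n_w = sum((G - pos) ** alpha for pos, (g, _) in enumerate(items) if g in in_set)
    score = 0.0
    hit = miss = 0.0
    for pos, (g, _) in enumerate(items):
        if g in in_set:
            hit += (G - pos) ** alpha / n_w
        else:
            miss += 1.0 / n_out
        score += hit - miss
    return score


def brute_ses(abundances, member_mask, p) -> float:
    """Exhaustive enumeration of the running difference at every position,
    in exact rational arithmetic (p must be a small integer exponent).

    Assumes the inputs are already in ranked order (decreasing abundance).
    Returns the signed D at the position of maximal |D| (earliest wins).
    """
    from fractions import Fraction

    r = [abs(Fraction(float(v))) for v in abundances]
    mask = [bool(m) for m in member_mask]
    ip = int(p)
    assert ip == p, "exact oracle needs an integer weight exponent"
    n_r = sum(ri ** ip for ri, m in zip(r, mask) if m)
    n_not = sum(1 for m in mask if not m)
    best = Fraction(0)
    best_abs = Fraction(-1)
    hit = Fraction(0)
    miss = Fraction(0)
    for ri, m in zip(r, mask):
        if m:
            hit += (ri ** ip) / n_r
        else:
            miss += Fraction(1, n_not)
        d = hit - miss
        if abs(d) > best_abs:
            best_abs = abs(d)
            best = d
    return float(best)


def random_ses_instance(rng, max_n=20, allow_ties=True):
    """A random ranked abundance vector + proper-subset membership mask."""
    n = int(rng.integers(3, max_n + 1))
    if allow_ties and rng.random() < 0.3:
        vals = rng.integers(0, 5, size=n).astype(float)  # many ties
    else:
        vals = rng.random(n) * 10
    vals = np.sort(vals)[::-1]
    k = int(rng.integers(1, n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    if vals[mask].sum() == 0:  # keep N_R > 0 (the error path is tested separately)
        if vals[0] == 0:
            vals[0] = 1.0  # still sorted decreasing
        if not mask[0]:  # move one member to the top position
            mask[int(np.argmax(mask))] = False
            mask[0] = True
    return vals, mask
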