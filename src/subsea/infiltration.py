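"""Marker-set-based cell infiltration abundance (cells x samples).

A pluggable scorer with the interface of xCell-style tools: each cell type
is represented by a marker gene set, scored per sample with raw ssGSEA, and
shifted per cell so the cohort minimum is 0. Non-negative abundances make
the |r|^p weighting of the downstream subtype enrichment statistic
unambiguous in direction. Genuine xCell output can be supplied instead via
``load_external_abundance``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSetCollection, match_genes
from .enrichment import DEFAULT_ALPHA, rank_values, scores_from_rank_values

logger = logging.getLogger("subsea")

LINEAGES = ("immune", "stromal", "other")


@dataclass
class CellAbundanceMatrix:
    """Cell x sample infiltration abundances with a lineage tag per cell."""

    values: pd.DataFrame
    lineage: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate cell names")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("non-finite abundance values")
        if self.lineage is None:
            self.lineage = pd.Series("other", index=self.values.index, name="lineage")
        else:
            self.lineage = self.lineage.reindex(self.values.index).fillna("other")
            bad = sorted(set(self.lineage.unique()) - set(LINEAGES))
            if bad:
                raise ValueError(f"unknown lineage tag(s): {bad}")

    @property
    def cell_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def cell_abundance(expr: ExpressionMatrix, marker_collection: GeneSetCollection,
                   lineage_map: dict[str, str] | None = None,
                   alpha: float = DEFAULT_ALPHA,
                   min_markers: int = 2) -> CellAbundanceMatrix:
    """Score every cell's marker set per sample (raw ssGSEA) and shift each
    cell so its cohort minimum is exactly 0.

    Cells with fewer than ``min_markers`` usable markers are dropped with a
    warning rather than scored on a degenerate set.
    """
    genes, c = rank_values(expr)
    lookup = {g: i for i, g in enumerate(genes)}
    rows = {}
    for cell, markers in marker_collection.sets.items():
        present = match_genes(markers, lookup, set_name=cell)
        if len(present) < min_markers:
            logger.warning("cell %s dropped: %d usable marker(s) < %d",
                           cell, len(present), min_markers)
            continue
        idx = np.array([lookup[g] for g in present])
        scores = scores_from_rank_values(c, idx, alpha)
        rows[cell] = scores - scores.min()
    if not rows:
        raise ValueError("no cell has enough usable markers")
    values = pd.DataFrame(rows, index=expr.sample_ids).T
    lineage = pd.Series({cell: (lineage_map or {}).get(cell, "other") for cell in values.index},
                        name="lineage")
    return CellAbundanceMatrix(values, lineage)


def load_external_abundance(path, cohort_samples: list[str] | None = None,
                            lineage_path=None) -> CellAbundanceMatrix:
    """Read a cells x samples abundance TSV (e.g. genuine xCell output).

    When ``cohort_samples`` is given, the file must not mention unknown
    samples; lineage tags come from an optional sidecar TSV (cell, lineage),
    defaulting to "other".
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    if cohort_samples is not None:
        unknown = [s for s in df.columns if s not in set(cohort_samples)]
        if unknown:
            raise ValueError(f"abundance file mentions unknown sample(s): {unknown[:5]}")
    lineage = None
    if lineage_path is not None:
        side = pd.read_csv(lineage_path, sep="\t")
        lineage = pd.Series(side.iloc[:, 1].values, index=side.iloc[:, 0].values,
                            name="lineage")
    return CellAbundanceMatrix(df.astype(float), lineage)


def write_abundance(abund: CellAbundanceMatrix, path, lineage_path=None) -> None:
    abund.values.rename_axis("cell").to_csv(path, sep="\t")
    if lineage_path is not None:
        abund.lineage.rename_axis("cell").to_frame().to_csv(lineage_path, sep="\t")
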