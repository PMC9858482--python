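"""Data containers and I/O for the TME heterogeneity pipeline.

All tables are tab-separated text. Expression matrices follow the cBioPortal
convention (genes as rows, samples as columns); gene sets use the Broad GMT
dialect; mutations use a minimal MAF-like layout. Every container validates
its invariants on construction so downstream code can assume them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("subsea")

VALID_SCALES = ("fpkm", "log2p1")

#: gene-level copy-number codes (GISTIC convention)
CNV_CODES = (-2, -1, 0, 1, 2)


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with a declared scale.

    ``scale`` is ``"fpkm"`` (non-negative linear values) or ``"log2p1"``
    (values already log2(x+1)-transformed). The scale travels with the
    matrix so score operations can enforce the scale they expect.
    """

    values: pd.DataFrame
    scale: str = "log2p1"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        if np.any(arr < 0):
            raise ValueError(f"negative values not allowed on scale {self.scale!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.scale)


def log2p1_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(v + 1) every value; declared scale becomes ``log2p1``."""
    if m.scale != "fpkm":
        raise ValueError(f"log2p1_transform expects scale 'fpkm', got {m.scale!r}")
    return ExpressionMatrix(np.log2(m.values + 1.0), "log2p1")


class GeneSetCollection:
    """Ordered, named gene lists (GMT semantics).

    Set names are unique, each set is non-empty and holds no duplicate
    genes; gene order within a set is preserved.
    """

    def __init__(self, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None):
        if not sets:
            raise ValueError("empty gene set collection")
        self.sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = {}
        for name, genes in sets.items():
            genes = list(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
            self.sets[name] = genes
            self.descriptions[name] = (descriptions or {}).get(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names}, self.descriptions)


def read_gmt(path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name <TAB> description <TAB> genes..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_expression(path, scale_declared: str, samples_as_rows: bool = False,
                    impute_median: bool = False) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column = gene ids, header = samples).

    ``samples_as_rows`` transposes on read. Missing values are rejected
    unless ``impute_median``, which fills each gene's median (logged).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        for col in non_numeric:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value {bad.iloc[0]!r} at gene "
                    f"{bad.index[0]!r}, sample {col!r}"
                )
        df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        if not impute_median:
            n = int(df.isna().sum().sum())
            raise ValueError(f"{path}: {n} missing value(s); pass impute_median=True to fill")
        n = int(df.isna().sum().sum())
        df = df.apply(lambda row: row.fillna(row.median()), axis=1)
        logger.info("imputed %d missing expression values with gene-wise medians", n)
    return ExpressionMatrix(df.astype(float), scale_declared)


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class SubtypeAnnotation:
    """Sample -> subtype label map; each subtype needs >= 2 samples."""

    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)
        _check_unique(self.labels.index, "sample")
        counts = self.labels.value_counts()
        if len(counts) < 2:
            raise ValueError("need >= 2 subtype levels")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"subtype(s) with < 2 samples: {list(small.index)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def subtypes(self) -> list[str]:
        return sorted(self.labels.unique())

    def subset(self, samples) -> "SubtypeAnnotation":
        return SubtypeAnnotation(self.labels.loc[list(samples)])


def read_subtypes(path) -> SubtypeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id, subtype")
    return SubtypeAnnotation(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values,
                                       name="subtype"))


def write_subtypes(ann: SubtypeAnnotation, path) -> None:
    ann.labels.rename_axis("sample_id").rename("subtype").to_frame().to_csv(path, sep="\t")


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time > 0 and event in {0, 1} (1 = death)."""

    table: pd.DataFrame  # index sample_id, columns time, event

    def __post_init__(self) -> None:
        need = {"time", "event"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"survival table needs columns {sorted(need)}")
        self.table.index = self.table.index.astype(str)
        _check_unique(self.table.index, "sample")
        t = self.table["time"].to_numpy(dtype=float)
        e = self.table["event"].to_numpy()
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("survival times must be finite and > 0")
        if not np.isin(e, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        self.table = self.table.assign(time=t, event=e.astype(int))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, samples) -> "SurvivalTable":
        keep = [s for s in samples if s in self.table.index]
        return SurvivalTable(self.table.loc[keep])


def read_survival(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SurvivalTable(df)


def write_survival(surv: SurvivalTable, path) -> None:
    surv.table.rename_axis("sample_id").to_csv(path, sep="\t")


#: minimal MAF-like column set
MAF_COLUMNS = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")


@dataclass
class MutationTable:
    """Long-form somatic variants; (sample, gene) pairs may repeat."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MAF_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"mutation table missing column(s) {missing}")
        self.table = self.table.astype({c: str for c in MAF_COLUMNS})

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.table["Tumor_Sample_Barcode"].unique())

    def subset(self, samples) -> "MutationTable":
        keep = self.table["Tumor_Sample_Barcode"].isin(set(samples))
        return MutationTable(self.table.loc[keep].reset_index(drop=True))


def read_mutations(path) -> MutationTable:
    return MutationTable(pd.read_csv(path, sep="\t", dtype=str))


def write_mutations(mut: MutationTable, path) -> None:
    mut.table.to_csv(path, sep="\t", index=False)


@dataclass
class CNVMatrix:
    """Gene x sample integer copy-number codes in {-2,-1,0,1,2}."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.isin(arr, CNV_CODES).all():
            bad = sorted(set(arr.ravel()) - set(CNV_CODES))
            raise ValueError(f"CNV codes outside {CNV_CODES}: {bad[:5]}")
        self.values = self.values.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, samples) -> "CNVMatrix":
        keep = [s for s in samples if s in self.values.columns]
        return CNVMatrix(self.values.loc[:, keep])


def read_cnv(path) -> CNVMatrix:
    return CNVMatrix(pd.read_csv(path, sep="\t", index_col=0))


def write_cnv(cnv: CNVMatrix, path) -> None:
    cnv.values.rename_axis("gene_id").to_csv(path, sep="\t")


@dataclass
class CohortBundle:
    """All data layers restricted to one sample universe.

    The universe is expression ∩ subtype samples (in expression column
    order); optional layers are restricted to it and their coverage is
    recorded in ``coverage`` (layer -> number of universe samples present).
    """

    expression: ExpressionMatrix
    subtypes: SubtypeAnnotation
    survival: SurvivalTable | None = None
    mutations: MutationTable | None = None
    cnv: CNVMatrix | None = None
    coverage: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


def align_cohort(expr: ExpressionMatrix, subtypes: SubtypeAnnotation,
                 survival: SurvivalTable | None = None,
                 mutations: MutationTable | None = None,
                 cnv: CNVMatrix | None = None) -> CohortBundle:
    """Restrict every layer to the expression ∩ subtype sample universe.

    Partial overlap of the optional layers is expected (e.g. not every
    sample has mutation calls); per-layer coverage counts are recorded and
    logged. Idempotent: aligning an aligned bundle changes nothing.
    """
    universe = [s for s in expr.sample_ids if s in set(subtypes.sample_ids)]
    if not universe:
        raise ValueError("expression and subtype annotation share no samples")
    expr2 = expr.subset_samples(universe)
    sub2 = subtypes.subset(universe)
    coverage = {"expression": len(universe), "subtypes": len(universe)}
    surv2 = mut2 = cnv2 = None
    if survival is not None:
        surv2 = survival.subset(universe)
        coverage["survival"] = len(surv2.table)
    if mutations is not None:
        mut2 = mutations.subset(universe)
        coverage["mutations"] = len(set(mut2.table["Tumor_Sample_Barcode"]) & set(universe))
    if cnv is not None:
        cnv2 = cnv.subset(universe)
        coverage["cnv"] = cnv2.values.shape[1]
    for layer, n in coverage.items():
        if n < len(universe):
            logger.info("layer %s covers %d of %d universe samples", layer, n, len(universe))
    return CohortBundle(expr2, sub2, surv2, mut2, cnv2, coverage)


def match_genes(gene_set: list[str], available, set_name: str = "") -> list[str]:
    """Exact, case-sensitive gene matching; drops (and counts) misses."""
    avail = set(available)
    present = [g for g in gene_set if g in avail]
    n_missing = len(gene_set) - len(present)
    if n_missing:
        warnings.warn(
            f"gene set {set_name or '<unnamed>'}: {n_missing} of {len(gene_set)} "
            f"genes absent from the expression matrix and dropped",
            stacklevel=2,
        )
    return present
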