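"""Per-sample TME feature scores.

Implements the named scores used to characterize the tumor microenvironment
of each sample: the 8-set TME signature panel (ssGSEA), the MHC class-I
antigen-presentation score (mean of log-transformed, median-centered core
gene expression), the 18-gene T-cell-inflamed GEP score (normalized ssGSEA),
tumor mutation burden, and ESTIMATE-style immune/stromal/purity scores.
"""

from __future__ import annotations

from importlib import resources as _importlib_resources

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSetCollection, MutationTable, match_genes, read_gmt
from .enrichment import DEFAULT_ALPHA, SignatureScoreMatrix, ssgsea_scores

#: MAF variant classes counted as non-silent (protein-affecting)
NONSILENT_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Ins", "Frame_Shift_Del",
    "In_Frame_Ins", "In_Frame_Del", "Splice_Site", "Translation_Start_Site",
    "Nonstop_Mutation",
})

#: MAF variant classes explicitly treated as silent/non-coding
SILENT_CLASSES = frozenset({
    "Silent", "Synonymous", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "Intron",
    "IGR", "RNA", "lincRNA", "Targeted_Region",
})

# cos-transform constants from the original ESTIMATE purity calibration
_PURITY_A = 0.6049872018
_PURITY_B = 0.0001467884

#: default exome size (megabases) for the TMB denominator
DEFAULT_CODING_MB = 38.0


def _bundled(name: str):
    return _importlib_resources.files("subsea.resources").joinpath(name)


def load_gep18() -> GeneSetCollection:
    """The bundled 18-gene T-cell-inflamed GEP set."""
    return read_gmt(_bundled("gep18.gmt"))


def load_mhc_core() -> GeneSetCollection:
    """The bundled 9-gene core MHC-I set."""
    return read_gmt(_bundled("mhc_core.gmt"))


def load_tme_panel() -> GeneSetCollection:
    """The 8-set TME signature panel (two immune, two vascularization, one
    stromal, three metabolism sets). Set names and categories are fixed; the
    bundled gene memberships are synthetic stand-ins meant to be replaced by
    user-supplied published signatures."""
    return read_gmt(_bundled("tme_panel_synthetic.gmt"))


def load_demo_cell_markers() -> tuple[GeneSetCollection, dict[str, str]]:
    """Small synthetic demo marker collection (10 cells) with lineage tags."""
    markers = read_gmt(_bundled("cell_markers_demo_synthetic.gmt"))
    lineage_df = pd.read_csv(_bundled("cell_lineage_demo_synthetic.tsv"), sep="\t")
    lineage = dict(zip(lineage_df["cell"], lineage_df["lineage"]))
    return markers, lineage


def mhc_score(expr: ExpressionMatrix, core_set: list[str] | None = None) -> pd.Series:
    """Mean of log-transformed, median-centered core MHC-I gene expression.

    Per gene the (log2(x+1)) expression is centered on its median across
    patients; a sample's score is the mean of the centered values over the
    core genes. Input on FPKM scale is log-transformed first; log2p1 input
    is used as-is.
    """
    if expr.n_samples < 2:
        raise ValueError("MHC score needs >= 2 samples for median centering")
    if core_set is None:
        core_set = load_mhc_core()["mhc_core"]
    vals = expr.values
    if expr.scale == "fpkm":
        vals = np.log2(vals + 1.0)
    present = match_genes(core_set, vals.index, set_name="mhc_core")
    if not present:
        raise ValueError("no core MHC gene present in the matrix")
    sub = vals.loc[present]
    centered = sub.sub(sub.median(axis=1), axis=0)
    return centered.mean(axis=0).rename("mhc_score")


def gep_score(expr: ExpressionMatrix, gep_set: GeneSetCollection | None = None,
              alpha: float = DEFAULT_ALPHA) -> pd.Series:
    """Normalized ssGSEA score of the T-cell-inflamed GEP gene set."""
    if gep_set is None:
        gep_set = load_gep18()
    scores = ssgsea_scores(expr, gep_set, alpha=alpha, normalize=True)
    return scores.values.iloc[0].rename("gep_score")


def tmb(mutations: MutationTable, samples: list[str] | None = None,
        coding_mb: float = DEFAULT_CODING_MB, lenient: bool = False,
        nonsilent_classes: frozenset[str] = NONSILENT_CLASSES) -> pd.Series:
    """Tumor mutation burden: non-silent variants per coding megabase.

    ``samples`` fixes the output universe (samples without variants get 0).
    Unknown variant classifications raise unless ``lenient``, which drops
    them. Row order of the input never matters.
    """
    if coding_mb <= 0:
        raise ValueError("coding_mb must be > 0")
    tab = mutations.table
    known = nonsilent_classes | SILENT_CLASSES
    unknown = sorted(set(tab["Variant_Classification"]) - known)
    if unknown:
        if not lenient:
            raise ValueError(f"unknown variant classification(s): {unknown}")
        tab = tab[~tab["Variant_Classification"].isin(unknown)]
    nonsilent = tab[tab["Variant_Classification"].isin(nonsilent_classes)]
    counts = nonsilent.groupby("Tumor_Sample_Barcode").size()
    if samples is None:
        samples = mutations.sample_ids
    counts = counts.reindex(samples, fill_value=0)
    return (counts / coding_mb).rename("tmb")


def estimate_scores(expr: ExpressionMatrix, immune_set: GeneSetCollection,
                    stromal_set: GeneSetCollection,
                    alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """ESTIMATE-style immune/stromal/combined scores and tumor purity.

    Immune and stromal scores are raw ssGSEA scores of the respective gene
    sets; their sum is the combined (ESTIMATE) score; purity applies the
    original cos-transform calibration, clamped to [0, 1] with an
    ``purity_in_range`` flag marking samples inside the calibrated interval
    of the transform (where cos is monotone decreasing).
    """
    immune = ssgsea_scores(expr, immune_set, alpha=alpha).values.iloc[0]
    stromal = ssgsea_scores(expr, stromal_set, alpha=alpha).values.iloc[0]
    est = immune + stromal
    arg = _PURITY_A + _PURITY_B * est
    purity_raw = np.cos(arg)
    in_range = (arg >= _PURITY_A) & (arg <= np.pi)
    purity = purity_raw.clip(0.0, 1.0)
    return pd.DataFrame({
        "immune_score": immune,
        "stromal_score": stromal,
        "estimate_score": est,
        "tumor_purity": purity,
        "purity_in_range": in_range & (purity_raw >= 0.0) & (purity_raw <= 1.0),
    })


def signature_panel(expr: ExpressionMatrix, tme_collection: GeneSetCollection | None = None,
                    alpha: float = DEFAULT_ALPHA) -> SignatureScoreMatrix:
    """ssGSEA scores of the 8-set TME signature panel."""
    if tme_collection is None:
        tme_collection = load_tme_panel()
    return ssgsea_scores(expr, tme_collection, alpha=alpha)


def feature_table(expr: ExpressionMatrix, mutations: MutationTable | None = None,
                  immune_set: GeneSetCollection | None = None,
                  stromal_set: GeneSetCollection | None = None,
                  coding_mb: float = DEFAULT_CODING_MB) -> pd.DataFrame:
    """Convenience assembly of the per-sample feature score table."""
    out = pd.DataFrame(index=expr.sample_ids)
    out["mhc_score"] = mhc_score(expr)
    out["gep_score"] = gep_score(expr)
    if immune_set is not None and stromal_set is not None:
        est = estimate_scores(expr, immune_set, stromal_set)
        out = out.join(est.drop(columns="purity_in_range"))
    if mutations is not None:
        out["tmb"] = tmb(mutations, samples=expr.sample_ids, coding_mb=coding_mb)
    return out
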