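"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a multi-omics breast-cancer-like cohort: K subtype
groups of unequal size (defaults mirror the PAM50 proportions of a large
breast cancer cohort), marker-gene coexpression blocks driven by a latent
per-sample cell activity (which induces cell-abundance gradients), planted
(cell, subtype) enrichments as mean shifts of that latent activity,
subtype-dependent per-gene mutation and copy-number probabilities, and
exponential survival times whose log-hazard is a linear function of the
standardized planted cell activities, with administrative censoring at a
horizon calibrated to the target censoring rate.

Expression noise is standard normal on the log scale (log-normal in linear
space), shifted to be non-negative; all downstream scoring is rank-based,
so the exact noise family is not critical. Truth tables carry everything a
recovery test needs: the latent activity matrix, planted pairs, biased
aberration genes and the true hazard coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (CNVMatrix, ExpressionMatrix, GeneSetCollection, MutationTable,
                   SubtypeAnnotation, SurvivalTable, write_cnv, write_expression,
                   write_gmt, write_mutations, write_subtypes, write_survival)

#: PAM50 subtype proportions of the METABRIC-scale reference cohort
REFERENCE_SUBTYPE_WEIGHTS = {
    "Basal_like": 199, "HER2_enriched": 220, "Luminal_A": 679,
    "Luminal_B": 461, "Normal_like": 140,
}


def reference_subtype_sizes(n: int) -> dict[str, int]:
    """Split n samples across the 5 reference subtypes by largest remainder."""
    total = sum(REFERENCE_SUBTYPE_WEIGHTS.values())
    exact = {k: n * w / total for k, w in REFERENCE_SUBTYPE_WEIGHTS.items()}
    sizes = {k: int(np.floor(v)) for k, v in exact.items()}
    short = n - sum(sizes.values())
    for k in sorted(exact, key=lambda k: exact[k] - sizes[k], reverse=True)[:short]:
        sizes[k] += 1
    return sizes


@dataclass
class CellSpec:
    name: str
    n_markers: int
    lineage: str = "other"


@dataclass
class SurvivalSpec:
    baseline_hazard: float = 0.1
    coefficients: dict[str, float] = field(default_factory=dict)  # cell -> log-hazard per SD
    censoring_rate: float = 0.3


@dataclass
class SyntheticConfig:
    n_per_subtype: dict[str, int]
    n_genes: int
    cells: list[CellSpec]
    planted_specific: list[tuple[str, str, float]] = field(default_factory=list)
    mutation_spec: dict[str, dict[str, float]] = field(default_factory=dict)
    cnv_spec: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    marker_loading: float = 1.0  # SD shift of a marker gene per SD of cell activity
    seed: int = 0

    def validate(self) -> None:
        if any(n < 2 for n in self.n_per_subtype.values()):
            raise ValueError("every subtype needs >= 2 samples")
        demand = sum(c.n_markers for c in self.cells)
        if demand > self.n_genes:
            raise ValueError(f"marker demand {demand} exceeds n_genes {self.n_genes}")
        names = [c.name for c in self.cells]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell names")
        for cell, subtype, delta in self.planted_specific:
            if cell not in names:
                raise ValueError(f"planted cell {cell!r} not declared")
            if subtype not in self.n_per_subtype:
                raise ValueError(f"planted subtype {subtype!r} not declared")
            if delta < 0:
                raise ValueError("planted shift delta must be >= 0")
        for spec in self.mutation_spec.values():
            if any(not 0 <= q <= 1 for q in spec.values()):
                raise ValueError("mutation probabilities must lie in [0, 1]")
        for spec in self.cnv_spec.values():
            for a, d in spec.values():
                if not (0 <= a <= 1 and 0 <= d <= 1 and a + d <= 1):
                    raise ValueError("CNV amp/del probabilities invalid")
        if not 0 <= self.survival_spec.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")


@dataclass
class TruthTables:
    activity: pd.DataFrame  # latent cell activity, cells x samples
    planted_pairs: list[tuple[str, str, float]]
    biased_mutation_genes: list[str]
    biased_cnv_genes: list[str]
    hazard_coefficients: dict[str, float]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    markers: GeneSetCollection
    lineage: dict[str, str]
    subtypes: SubtypeAnnotation
    mutations: MutationTable | None
    cnv: CNVMatrix | None
    survival: SurvivalTable | None
    truth: TruthTables
    config: SyntheticConfig


def _is_biased(spec: dict) -> bool:
    return len(set(spec.values())) > 1


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one cohort from the configured generative model (seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subtype_labels = []
    for name, size in config.n_per_subtype.items():
        subtype_labels += [name] * size
    n = len(subtype_labels)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    labels = pd.Series(subtype_labels, index=sample_ids, name="subtype")
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]

    # latent per-sample cell activity, with planted subtype shifts
    activity = rng.standard_normal((len(config.cells), n))
    cell_index = {c.name: i for i, c in enumerate(config.cells)}
    for cell, subtype, delta in config.planted_specific:
        activity[cell_index[cell], (labels == subtype).to_numpy()] += delta

    # expression: baseline noise + marker blocks loaded on cell activity
    expr = rng.standard_normal((config.n_genes, n))
    marker_sets: dict[str, list[str]] = {}
    offset = 0
    for ci, cell in enumerate(config.cells):
        block = list(range(offset, offset + cell.n_markers))
        offset += cell.n_markers
        marker_sets[cell.name] = [gene_ids[g] for g in block]
        expr[block, :] += config.marker_loading * activity[ci][None, :]
    expr -= expr.min()
    expression = ExpressionMatrix(pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
                                  "log2p1")
    markers = GeneSetCollection(marker_sets,
                                {c.name: f"synthetic markers ({c.lineage})"
                                 for c in config.cells})
    lineage = {c.name: c.lineage for c in config.cells}
    subtypes = SubtypeAnnotation(labels)

    mutations = None
    if config.mutation_spec:
        rows = []
        for gene, probs in config.mutation_spec.items():
            prob = labels.map(probs).fillna(0.0).to_numpy(dtype=float)
            hit = rng.random(n) < prob
            for s in np.asarray(sample_ids)[hit]:
                rows.append({"Tumor_Sample_Barcode": s, "Hugo_Symbol": gene,
                             "Variant_Classification": "Missense_Mutation"})
        mutations = MutationTable(pd.DataFrame(
            rows, columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]))

    cnv = None
    if config.cnv_spec:
        mat = np.zeros((len(config.cnv_spec), n), dtype=int)
        for gi, (gene, spec) in enumerate(config.cnv_spec.items()):
            amp_p = labels.map({k: v[0] for k, v in spec.items()}).fillna(0.0).to_numpy()
            del_p = labels.map({k: v[1] for k, v in spec.items()}).fillna(0.0).to_numpy()
            u = rng.random(n)
            level = np.where(rng.random(n) < 0.5, 2, 1)  # half the calls high-level
            mat[gi] = np.where(u < amp_p, level, np.where(u < amp_p + del_p, -level, 0))
        cnv = CNVMatrix(pd.DataFrame(mat, index=list(config.cnv_spec), columns=sample_ids))

    survival = None
    if config.survival_spec is not None:
        spec = config.survival_spec
        lp = np.zeros(n)
        for cell, beta in spec.coefficients.items():
            a = activity[cell_index[cell]]
            sd = a.std()
            z = (a - a.mean()) / sd if sd > 0 else np.zeros(n)
            lp += beta * z
        rate = spec.baseline_hazard * np.exp(lp)
        t = rng.exponential(1.0 / rate)
        if spec.censoring_rate > 0:
            horizon = np.quantile(t, 1.0 - spec.censoring_rate)
            event = (t <= horizon).astype(int)
            t = np.minimum(t, horizon)
        else:
            event = np.ones(n, dtype=int)
        survival = SurvivalTable(pd.DataFrame({"time": t, "event": event}, index=sample_ids))

    truth = TruthTables(
        activity=pd.DataFrame(activity, index=[c.name for c in config.cells],
                              columns=sample_ids),
        planted_pairs=list(config.planted_specific),
        biased_mutation_genes=[g for g, s in config.mutation_spec.items() if _is_biased(s)],
        biased_cnv_genes=[g for g, s in config.cnv_spec.items() if _is_biased(s)],
        hazard_coefficients=dict(config.survival_spec.coefficients),
    )
    return SyntheticCohort(expression, markers, lineage, subtypes, mutations, cnv,
                           survival, truth, config)


def null_cohort(n: int = 150, n_cells: int = 10, n_subtypes: int = 5, seed: int = 0,
                n_genes: int = 1000, n_markers: int = 10) -> SyntheticCohort:
    """Cohort with every effect zeroed: no planted enrichment, no marker
    coexpression, no aberration bias, hazard independent of cells.

    With the loading zeroed, marker sets are plain noise genes — exactly
    exchangeable with the gene-permutation null — which is what calibration
    suites need.
    """
    if n_subtypes == 5:
        sizes = reference_subtype_sizes(n)
    else:
        base = n // n_subtypes
        sizes = {f"subtype_{k}": base + (1 if k < n % n_subtypes else 0)
                 for k in range(n_subtypes)}
    cells = [CellSpec(f"cell_{i}", n_markers,
                      "immune" if i % 2 == 0 else "stromal") for i in range(n_cells)]
    cfg = SyntheticConfig(n_per_subtype=sizes, n_genes=n_genes, cells=cells,
                          planted_specific=[], marker_loading=0.0, seed=seed,
                          survival_spec=SurvivalSpec())
    return generate_cohort(cfg)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write every layer in the pipeline's input formats plus truth tables."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, out / "expression.tsv")
    write_gmt(cohort.markers, out / "markers.gmt")
    write_subtypes(cohort.subtypes, out / "subtypes.tsv")
    pd.Series(cohort.lineage, name="lineage").rename_axis("cell") \
        .to_frame().to_csv(out / "lineage.tsv", sep="\t")
    if cohort.mutations is not None:
        write_mutations(cohort.mutations, out / "mutations.tsv")
    if cohort.cnv is not None:
        write_cnv(cohort.cnv, out / "cnv.tsv")
    if cohort.survival is not None:
        write_survival(cohort.survival, out / "survival.tsv")
    cohort.truth.activity.rename_axis("cell").to_csv(out / "truth_activity.tsv", sep="\t")
    pd.DataFrame(cohort.truth.planted_pairs,
                 columns=["cell", "subtype", "delta"]).to_csv(
        out / "truth_planted_pairs.tsv", sep="\t", index=False)
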