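"""Prognostic screening of subtype-specific cells.

Univariate Cox proportional-hazards fits on continuous infiltration
abundance (Efron ties, via lifelines), maximally selected cutpoints (the
observed abundance value whose high/low split maximizes the standardized
log-rank statistic, subject to a minimum group proportion), and
Kaplan-Meier curves with the log-rank test.

The p-value reported for an optimized cutpoint is the naive log-rank p of
the chosen split; because the split was selected to maximize the statistic
it is anti-conservative, and every cutoff result carries a
``selection_biased`` flag plus an optional permutation-adjusted p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .data import SubtypeAnnotation, SurvivalTable
from .infiltration import CellAbundanceMatrix

logger = logging.getLogger("subsea")

DEFAULT_MINPROP = 0.1
COX_P_THRESHOLD = 0.01


@dataclass
class CoxScreenRow:
    subtype: str
    cell: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    cox_p: float
    n: int
    n_events: int
    significant: bool


def univariate_cox(values: pd.Series, survival: SurvivalTable) -> dict:
    """One univariate Cox PH fit of survival on a continuous covariate."""
    common = [s for s in values.index if s in survival.table.index]
    df = pd.DataFrame({
        "x": values.loc[common].astype(float),
        "time": survival.table.loc[common, "time"],
        "event": survival.table.loc[common, "event"],
    })
    if df["x"].nunique() < 2:
        raise ValueError("constant covariate; Cox fit is degenerate")
    if df["event"].sum() == 0:
        raise ValueError("no events")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.loc["x"]
    return {
        "log_hr": float(s["coef"]),
        "hazard_ratio": float(s["exp(coef)"]),
        "ci_low": float(np.exp(s["coef lower 95%"])),
        "ci_high": float(np.exp(s["coef upper 95%"])),
        "p": float(s["p"]),
        "n": int(len(df)),
        "n_events": int(df["event"].sum()),
    }


def cox_screen(abundance: CellAbundanceMatrix, survival: SurvivalTable,
               subtypes: SubtypeAnnotation,
               which_cells: dict[str, list[str]] | None = None,
               p_threshold: float = COX_P_THRESHOLD,
               min_samples: int = 10) -> pd.DataFrame:
    """Univariate Cox fit per (subtype, cell), within that subtype's samples.

    ``which_cells`` restricts each subtype to its specific cells (e.g. from
    the subtype enrichment calls); by default all cells are screened in all
    subtypes. Subtypes with no events and constant covariates are skipped
    with a warning. Rows are ordered by p with a significance flag at
    p < 0.01.
    """
    rows = []
    labels = subtypes.labels
    for lvl in sorted(labels.unique()):
        members = [s for s in abundance.sample_ids
                   if s in labels.index and labels[s] == lvl and s in survival.table.index]
        if len(members) < min_samples:
            logger.warning("subtype %s skipped: %d samples with survival < %d",
                           lvl, len(members), min_samples)
            continue
        surv = survival.subset(members)
        if surv.table["event"].sum() == 0:
            logger.warning("subtype %s skipped: no events", lvl)
            continue
        cells = (which_cells or {}).get(lvl, abundance.cell_names) if which_cells \
            else abundance.cell_names
        for cell in cells:
            values = abundance.values.loc[cell, members]
            try:
                fit = univariate_cox(values, surv)
            except ValueError as exc:
                logger.warning("subtype %s, cell %s skipped: %s", lvl, cell, exc)
                continue
            rows.append({"subtype": lvl, "cell": cell, **fit,
                         "significant": fit["p"] < p_threshold})
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("p").reset_index(drop=True)
    return out


@dataclass
class CutoffSplit:
    cutoff: float
    n_high: int
    n_low: int
    logrank_p: float
    statistic: float  # |standardized| log-rank statistic of the chosen split
    direction: str  # which group has better survival: "high" or "low"
    selection_biased: bool = True
    adjusted_p: float | None = None


def optimal_cutoff(values, survival: SurvivalTable, minprop: float = DEFAULT_MINPROP,
                   n_perm_adjust: int = 0, seed: int = 0, min_n: int = 20) -> CutoffSplit:
    """Maximally selected cutpoint of a continuous covariate.

    Candidates are observed values whose low (x <= cut) / high (x > cut)
    split leaves at least ``minprop`` of the samples on both sides; the
    chosen cutoff maximizes the absolute standardized log-rank statistic.
    The scan is rank-based, so strictly monotone transforms of the values
    select the same split. ``n_perm_adjust`` > 0 additionally estimates a
    selection-adjusted p by recomputing the maximal statistic under
    survival-label permutations.
    """
    values = pd.Series(values)
    common = [s for s in values.index if s in survival.table.index]
    x = values.loc[common].to_numpy(dtype=float)
    time = survival.table.loc[common, "time"].to_numpy(dtype=float)
    event = survival.table.loc[common, "event"].to_numpy(dtype=int)
    n = len(x)
    if n < min_n:
        raise ValueError(f"need >= {min_n} samples for cutpoint selection, got {n}")
    lo = int(np.ceil(minprop * n))
    candidates = [v for v in np.unique(x) if lo <= (x > v).sum() and (x <= v).sum() >= lo]
    if not candidates:
        raise ValueError("no candidate cutoff satisfies minprop on both sides")

    def best_split(t: np.ndarray, ev: np.ndarray):
        best = (-np.inf, None, None)
        for v in candidates:
            high = x > v
            if ev.sum() == 0:
                continue
            res = logrank_test(t[high], t[~high],
                               event_observed_A=ev[high], event_observed_B=ev[~high])
            stat = float(res.test_statistic)
            if stat > best[0]:
                best = (stat, float(res.p_value), v)
        return best

    stat, pval, cut = best_split(time, event)
    if cut is None:
        raise ValueError("no candidate split has any event")
    high = x > cut
    km_high = KaplanMeierFitter().fit(time[high], event[high])
    km_low = KaplanMeierFitter().fit(time[~high], event[~high])
    # compare restricted mean survival over the common horizon
    horizon = min(time[high].max(), time[~high].max())
    grid = np.linspace(0, horizon, 64)
    rmst_high = np.trapezoid(km_high.survival_function_at_times(grid).to_numpy(), grid)
    rmst_low = np.trapezoid(km_low.survival_function_at_times(grid).to_numpy(), grid)
    direction = "high" if rmst_high >= rmst_low else "low"
    adjusted_p = None
    if n_perm_adjust > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm_adjust):
            perm = rng.permutation(n)  # (time, event) permuted jointly relative to x
            s, _, _ = best_split(time[perm], event[perm])
            if s >= stat:
                exceed += 1
        adjusted_p = (exceed + 1) / (n_perm_adjust + 1)
    return CutoffSplit(cutoff=float(cut), n_high=int(high.sum()), n_low=int((~high).sum()),
                       logrank_p=pval, statistic=float(np.sqrt(stat)),
                       direction=direction, selection_biased=True, adjusted_p=adjusted_p)


def km_logrank(group_a: SurvivalTable | pd.DataFrame, group_b: SurvivalTable | pd.DataFrame,
               labels: tuple[str, str] = ("high", "low")):
    """Kaplan-Meier curves for two groups plus the two-sided log-rank p.

    Returns (curves, logrank_p) where ``curves`` maps each label to the
    fitted product-limit survival function (a step function starting at 1,
    non-increasing and right-continuous).
    """
    tables = []
    for g in (group_a, group_b):
        t = g.table if isinstance(g, SurvivalTable) else g
        if len(t) == 0:
            raise ValueError("each group needs >= 1 subject")
        tables.append(t)
    curves = {}
    for label, t in zip(labels, tables):
        km = KaplanMeierFitter()
        km.fit(t["time"], t["event"], label=label)
        curves[label] = km.survival_function_
    ta, tb = tables
    if ta.reset_index(drop=True).equals(tb.reset_index(drop=True)):
        return curves, 1.0  # identical groups: log-rank statistic 0 by construction
    res = logrank_test(ta["time"], tb["time"],
                       event_observed_A=ta["event"], event_observed_B=tb["event"])
    return curves, float(res.p_value)
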