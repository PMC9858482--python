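"""One-vs-rest subtype profiling of per-sample quantities.

Cohen's d with the pooled standard deviation

    d = (M1 - M2) / SDpooled,   SDpooled = sqrt((SS1 + SS2) / (df1 + df2))

where SSi is the within-group sum of squared deviations and dfi = ni - 1,
plus the two-sided Mann-Whitney U test, the Kruskal-Wallis overall test,
and Benjamini-Hochberg FDR over a declared family. Interpretive bands:
|d| < 0.2 small, 0.5-0.8 medium, > 0.8 large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import SubtypeAnnotation

logger = logging.getLogger("subsea")

#: star-label thresholds for pairwise p-values
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def cohens_d(group1, group2) -> float:
    """Pooled-SD standardized mean difference; NaN when the pooled SD is 0.

    A zero pooled SD leaves d undefined; the NaN sentinel keeps downstream
    heatmaps finite (logged, never +/-inf).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    m1, m2 = x.mean(), y.mean()
    ss1 = ((x - m1) ** 2).sum()
    ss2 = ((y - m2) ** 2).sum()
    sd_pooled = np.sqrt((ss1 + ss2) / (len(x) - 1 + len(y) - 1))
    if sd_pooled == 0:
        logger.info("zero pooled SD; Cohen's d undefined (NaN sentinel)")
        return float("nan")
    return float((m1 - m2) / sd_pooled)


def effect_band(d: float) -> str:
    """Interpretive label for |d| (small / medium / large)."""
    if np.isnan(d):
        return "undefined"
    a = abs(d)
    if a < 0.2:
        return "small"
    if a < 0.5:
        return "small-medium"
    if a <= 0.8:
        return "medium"
    return "large"


def mannwhitney_p(x, y) -> float:
    """Two-sided MWU p; exact for small tie-free groups, normal
    approximation with tie correction otherwise. Two identical constant
    groups are maximally null-like (p = 1 by convention)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    method = "exact" if (len(x) <= 8 and len(y) <= 8
                         and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)) \
        else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values over one correction family."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def p_to_stars(p: float) -> str:
    for thr, label in STAR_THRESHOLDS:
        if p <= thr:
            return label
    return "ns"


def one_vs_rest_profile(score_matrix: pd.DataFrame, subtypes: SubtypeAnnotation,
                        fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Cohen's d + MWU p for every feature x subtype, subtype vs all others.

    ``score_matrix`` is features x samples. BH-FDR is applied across the
    whole feature x subtype family (one heatmap = one family). Subtypes
    with fewer than 2 samples are excluded with a warning.
    """
    labels = subtypes.labels.loc[[s for s in score_matrix.columns if s in subtypes.labels.index]]
    if score_matrix.shape[1] != len(labels):
        score_matrix = score_matrix.loc[:, labels.index]
    levels = []
    for lvl in sorted(labels.unique()):
        n = int((labels == lvl).sum())
        if n < 2 or len(labels) - n < 2:
            logger.warning("subtype %s excluded from profile (n=%d)", lvl, n)
            continue
        levels.append(lvl)
    if len(levels) < 2:
        raise ValueError("need >= 2 usable subtypes")
    rows = []
    for feature in score_matrix.index:
        vals = score_matrix.loc[feature].to_numpy(dtype=float)
        for lvl in levels:
            mask = (labels == lvl).to_numpy()
            g1, g2 = vals[mask], vals[~mask]
            d = cohens_d(g1, g2)
            rows.append({
                "feature": feature, "subtype": lvl, "d": d,
                "n1": len(g1), "n2": len(g2),
                "M1": g1.mean(), "M2": g2.mean(),
                "mwu_p": mannwhitney_p(g1, g2),
                "band": effect_band(d),
            })
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["mwu_p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out


@dataclass
class GroupTestResult:
    kw_p: float
    pairwise: pd.DataFrame  # long form: group1, group2, mwu_p, stars


def group_tests(feature_values: pd.Series, subtypes: SubtypeAnnotation) -> GroupTestResult:
    """Kruskal-Wallis across all subtype groups plus all pairwise MWU tests
    with star labels (ns > 0.05, * <= 0.05, ** <= 0.01, *** <= 0.001,
    **** <= 0.0001)."""
    labels = subtypes.labels.loc[feature_values.index]
    groups = {lvl: feature_values[labels == lvl].to_numpy(dtype=float)
              for lvl in sorted(labels.unique())}
    for lvl, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"subtype {lvl} has no samples")
    arrs = list(groups.values())
    if np.ptp(np.concatenate(arrs)) == 0:
        kw_p = 1.0
    else:
        kw_p = float(stats.kruskal(*arrs).pvalue)
    rows = []
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = mannwhitney_p(groups[names[i]], groups[names[j]])
            rows.append({"group1": names[i], "group2": names[j],
                         "mwu_p": p, "stars": p_to_stars(p)})
    return GroupTestResult(kw_p=kw_p, pairwise=pd.DataFrame(rows))
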