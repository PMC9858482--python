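"""Basic plots: effect-size heatmap and Kaplan-Meier curves.

Requires matplotlib (optional dependency, ``pip install subsea[plot]``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def effect_size_heatmap(profile: pd.DataFrame, path=None, fdr_threshold: float = 0.05):
    """Feature x subtype heatmap of Cohen's d with dots marking FDR-significant
    cells, from a ``one_vs_rest_profile`` table. Returns the matplotlib axes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = profile.pivot(index="feature", columns="subtype", values="d")
    sig = profile.pivot(index="feature", columns="subtype", values="fdr") < fdr_threshold
    fig, ax = plt.subplots(figsize=(1.2 * mat.shape[1] + 2, 0.4 * mat.shape[0] + 2))
    vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
    im = ax.imshow(mat.to_numpy(), cmap="RdYlGn_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index)
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            if sig.iloc[i, j]:
                ax.plot(j, i, "k.", markersize=6)
    fig.colorbar(im, ax=ax, label="Cohen's d (one vs rest)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def km_plot(curves: dict[str, pd.DataFrame], logrank_p: float, path=None, title: str = ""):
    """Two Kaplan-Meier step curves with the log-rank p annotated."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, sf in curves.items():
        ax.step(sf.index, sf.to_numpy().ravel(), where="post", label=label)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_title(title)
    ax.legend()
    ax.annotate(f"log-rank p = {logrank_p:.2g}", xy=(0.55, 0.1), xycoords="axes fraction")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
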