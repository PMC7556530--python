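"""Boxplots of fitted mortality risk by group (wealth quintile by default)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from riskequity.metrics import boxplot_summary

__all__ = ["plot_risk_boxplots"]


def plot_risk_boxplots(values, groups, path=None, ylabel="Posterior mean mortality risk"):
    """Tukey boxplots of per-birth risk by group; outliers are not drawn.

    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    summary = boxplot_summary(values, groups)
    fig, ax = plt.subplots(figsize=(6, 4))
    stats = [
        {
            "med": row["median"],
            "q1": row["q1"],
            "q3": row["q3"],
            "whislo": row["whisker_low"],
            "whishi": row["whisker_high"],
            "label": str(g),
            "fliers": [],
        }
        for g, row in summary.iterrows()
    ]
    ax.bxp(stats, showfliers=False)
    ax.set_xlabel("Group")
    ax.set_ylabel(ylabel)
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
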