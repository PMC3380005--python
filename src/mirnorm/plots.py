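"""Simple diagnostic figures: geNorm V-curves and group boxplots."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["plot_v_curve", "plot_group_boxes"]


def plot_v_curve(v_series: pd.DataFrame, v_cutoff: float = 0.15, path: str | Path | None = None):
    """Bar chart of geNorm pairwise variation V(n/n+1) with the cutoff line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    labels = [f"V{int(n)}/{int(n) + 1}" for n in v_series["n"]]
    ax.bar(labels, v_series["V"], color="#4878d0")
    ax.axhline(v_cutoff, ls="--", color="0.3", lw=1, label=f"cutoff {v_cutoff}")
    ax.set_ylabel("pairwise variation V")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_group_boxes(
    values: pd.DataFrame, groups: pd.Series, path: str | Path | None = None, log: bool = True
):
    """Per-gene boxplots of expression split by sample group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = list(values.index)
    levels = sorted(groups.loc[list(values.columns)].unique())
    fig, axes = plt.subplots(
        1, len(genes), figsize=(1.6 * len(genes) + 1, 3.0), squeeze=False, sharey=False
    )
    for ax, gene in zip(axes[0], genes):
        data = [
            values.loc[gene, groups.loc[list(values.columns)] == lv].dropna() for lv in levels
        ]
        ax.boxplot(data, tick_labels=levels)
        ax.set_title(gene, fontsize=8)
        ax.tick_params(axis="x", rotation=45, labelsize=7)
        if log:
            ax.set_yscale("log")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
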