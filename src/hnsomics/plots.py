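"""Minimal figure exports: volcano, PCA scores, change-vs-change scatter.

Deliberately plain — these are working plots for inspecting a run, not
publication styling.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["volcano_plot", "pca_plot", "correlation_plot"]

_CLASS_COLORS = {"up": "#c23b22", "down": "#2b6cb0", "ns": "#9a9a9a"}


def volcano_plot(diff_table: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """log2FC vs -log10 p, colored by the uncorrected p<0.05 class."""
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        neglog = -np.log10(diff_table["p"].to_numpy())
    for cls, color in _CLASS_COLORS.items():
        m = diff_table["class"] == cls
        ax.scatter(diff_table.loc[m, "log2fc"], neglog[m.to_numpy()], s=6, c=color, label=cls)
    ax.axhline(-np.log10(0.05), lw=0.5, ls="--", c="k")
    ax.set_xlabel("log2 fold change (WD - control)")
    ax.set_ylabel("-log10 p")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pca_plot(pca_summary, design, path: str | Path, title: str = "") -> None:
    """PC1 vs PC2 sample scores, colored by condition."""
    cond = {d.sample_id: d.condition for d in design}
    colors = {"control": "#2b6cb0", "WD": "#c23b22"}
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for sample, row in pca_summary.scores.iterrows():
        ax.scatter(row["PC1"], row["PC2"], c=colors[cond[sample]], s=30)
        ax.annotate(sample, (row["PC1"], row["PC2"]), fontsize=5)
    ve = pca_summary.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({ve[1] * 100:.1f}%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def correlation_plot(x: pd.Series, y: pd.Series, result, path: str | Path,
                     xlabel: str = "x", ylabel: str = "y") -> None:
    """Scatter of two joined change maps annotated with Spearman r and p."""
    shared = x.index.intersection(y.index)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(x.loc[shared], y.loc[shared], s=8, c="#444444")
    ax.axhline(0, lw=0.5, c="k")
    ax.axvline(0, lw=0.5, c="k")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"Spearman r = {result.spearman_r:.3f}, p = {result.p_value:.3g} (n={result.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
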