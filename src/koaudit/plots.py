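"""Figure helpers (headless matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import GeneSet
from .regionscan import RegionCall, WindowDensity


def plot_window_density(
    density: WindowDensity,
    chrom: str,
    path: str,
    regions: list[RegionCall] | None = None,
) -> None:
    """Variants per window along one chromosome, called regions shaded."""
    sub = density.windows[density.windows["chrom"] == chrom]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(sub["start"] / 1e6, sub["count"],
           width=density.window_size / 1e6, align="edge", color="steelblue")
    for r in regions or []:
        if r.chrom == chrom:
            ax.axvspan(r.start / 1e6, r.end / 1e6, color="orange", alpha=0.3)
    ax.set_xlabel(f"{chrom} position (Mb)")
    ax.set_ylabel(f"variants / {density.window_size // 1000} kb")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_signature_box(
    de_table: pd.DataFrame, gene_sets: list[GeneSet], path: str
) -> None:
    """Box plot of per-set log2 fold-change distributions."""
    logfc = dict(zip(de_table["gene"], de_table["log2FC"]))
    data, labels = [], []
    for gs in gene_sets:
        vals = [logfc[g] for g in gs.members if g in logfc]
        if vals:
            data.append(vals)
            labels.append(gs.label)
    fig, ax = plt.subplots(figsize=(1.2 * len(data) + 1, 4))
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_ylabel("log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_volcano(
    de_table: pd.DataFrame, path: str, highlight_prefix: str | None = None
) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    p = np.clip(de_table["pvalue"].to_numpy(), 1e-300, 1.0)
    ax.scatter(de_table["log2FC"], -np.log10(p), s=4, color="0.6")
    if highlight_prefix:
        mask = de_table["gene"].str.startswith(highlight_prefix)
        ax.scatter(de_table.loc[mask, "log2FC"],
                   -np.log10(p[mask.to_numpy()]), s=8, color="red",
                   label=highlight_prefix)
        ax.legend()
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tss_scatter(x: np.ndarray, y: np.ndarray, path: str) -> None:
    """Per-TSS load correlation scatter between groups (log axes)."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=3, color="0.4", alpha=0.5)
    ax.set_xscale("symlog")
    ax.set_yscale("symlog")
    ax.set_xlabel("TSS load, group A")
    ax.set_ylabel("TSS load, group B")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
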