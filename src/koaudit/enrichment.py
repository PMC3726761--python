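"""Positional enrichment of top differentially expressed genes in a region.

Builds the 2x2 table (top-N vs rest) x (in-region vs out) over all scored
genes and reports the Pearson chi-square (no continuity correction)
alongside the Fisher exact test and odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .core import GeneAnnotation, ValidationError
from .regionscan import RegionCall


@dataclass
class EnrichmentResult:
    table: np.ndarray  # rows: top/rest, cols: in-region/out
    chi2: float | None
    chi2_pvalue: float | None
    fisher_pvalue: float
    odds_ratio: float
    degenerate_margin: bool = False
    dof: int = 1


def top_n_genes(de_table: pd.DataFrame, n: int) -> list[str]:
    """The N genes with smallest p-values; ties broken by gene identifier."""
    if n > len(de_table):
        raise ValidationError(
            f"requested top {n} of a {len(de_table)}-gene table"
        )
    ordered = de_table.sort_values(["pvalue", "gene"], kind="mergesort")
    return ordered["gene"].head(n).tolist()


def chromosome_contribution(
    genes: list[str], annotation: GeneAnnotation
) -> pd.Series:
    """Per-chromosome counts of the given genes; unannotated genes are
    excluded with a warning entry of count reported separately."""
    ann = annotation.genes.set_index("gene")["chrom"]
    chroms = [ann[g] for g in genes if g in ann.index]
    counts = pd.Series(chroms).value_counts().sort_index()
    counts.name = "n_genes"
    return counts


def _gene_in_region(
    genes: pd.DataFrame, region: RegionCall, mode: str = "overlap"
) -> np.ndarray:
    on_chrom = genes["chrom"] == region.chrom
    if mode == "overlap":
        hit = (genes["start"] < region.end) & (genes["end"] > region.start)
    elif mode == "midpoint":
        mid = (genes["start"] + genes["end"]) // 2
        hit = (mid >= region.start) & (mid < region.end)
    else:
        raise ValidationError(f"unknown membership mode {mode!r}")
    return (on_chrom & hit).to_numpy()


def region_enrichment_test(
    de_table: pd.DataFrame,
    region: RegionCall,
    annotation: GeneAnnotation,
    n_top: int = 100,
    membership: str = "overlap",
) -> EnrichmentResult:
    """Test concentration of the top-N DE genes inside a called region.

    The universe is every gene in the DE table with coordinates; region
    membership is interval overlap by default (midpoint mode available).
    With a zero margin the chi-square is undefined and only the Fisher
    exact p is reported.
    """
    top = set(top_n_genes(de_table, n_top))
    coords = annotation.genes.set_index("gene")
    scored = de_table[de_table["gene"].isin(coords.index)].copy()
    gene_coords = coords.loc[scored["gene"]][["chrom", "start", "end"]]
    in_region = _gene_in_region(gene_coords.reset_index(drop=True), region,
                                mode=membership)
    is_top = scored["gene"].isin(top).to_numpy()
    a = int(np.sum(is_top & in_region))
    b = int(np.sum(is_top & ~in_region))
    c = int(np.sum(~is_top & in_region))
    d = int(np.sum(~is_top & ~in_region))
    table = np.array([[a, b], [c, d]])
    odds, fisher_p = fisher_exact(table, alternative="two-sided")
    degenerate = (
        min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0
    )
    if degenerate:
        return EnrichmentResult(
            table=table,
            chi2=None,
            chi2_pvalue=None,
            fisher_pvalue=float(fisher_p),
            odds_ratio=float(odds),
            degenerate_margin=True,
        )
    chi2, chi2_p, dof, _ = chi2_contingency(table, correction=False)
    return EnrichmentResult(
        table=table,
        chi2=float(chi2),
        chi2_pvalue=float(chi2_p),
        fisher_pvalue=float(fisher_p),
        odds_ratio=float(odds),
        dof=int(dof),
    )
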