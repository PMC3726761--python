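"""Readers and writers for the on-disk formats the pipeline consumes.

Counts travel as TSV (genes x samples) or MatrixMarket with sidecar
gene/sample lists; annotation as BED6 plus a GTF-like exon file (or a
pre-classified element BED); variants as uncompressed VCF v4.2;
methylation coverage as BedGraph.  All writers emit plain text.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
from cyvcf2 import VCF

from .core import (
    CountMatrix,
    ELEMENT_COLUMNS,
    GENE_COLUMNS,
    GeneAnnotation,
    GeneSet,
    MethylProfile,
    ValidationError,
    VariantTable,
)

# ---------------------------------------------------------------------------
# counts


def write_counts_tsv(counts: CountMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(counts.counts, index=counts.genes, columns=counts.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_counts_tsv(
    counts_path: str | os.PathLike, groups_path: str | os.PathLike
) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    groups = read_groups_tsv(groups_path)
    return CountMatrix(
        genes=list(df.index.astype(str)),
        samples=list(df.columns.astype(str)),
        counts=df.to_numpy(),
        groups=groups,
    )


def write_groups_tsv(groups: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_groups_tsv(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["group"]))


def write_counts_mtx(counts: CountMatrix, prefix: str | os.PathLike) -> None:
    """Write counts as MatrixMarket plus gene/sample sidecar lists.

    Emits ``<prefix>.mtx``, ``<prefix>.genes.txt``, ``<prefix>.samples.txt``.
    """
    prefix = str(prefix)
    spio.mmwrite(prefix + ".mtx", np.asarray(counts.counts))
    Path(prefix + ".genes.txt").write_text("\n".join(counts.genes) + "\n")
    Path(prefix + ".samples.txt").write_text("\n".join(counts.samples) + "\n")


def read_counts_mtx(
    prefix: str | os.PathLike, groups_path: str | os.PathLike
) -> CountMatrix:
    prefix = str(prefix)
    mat = np.asarray(spio.mmread(prefix + ".mtx"))
    genes = Path(prefix + ".genes.txt").read_text().splitlines()
    samples = Path(prefix + ".samples.txt").read_text().splitlines()
    return CountMatrix(
        genes=genes,
        samples=samples,
        counts=mat,
        groups=read_groups_tsv(groups_path),
    )


# ---------------------------------------------------------------------------
# annotation


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_genes_bed(annotation: GeneAnnotation, path: str | os.PathLike) -> None:
    """Gene bodies as BED6 (name = gene id, score = 0)."""
    g = annotation.genes
    bed = pd.DataFrame(
        {
            "chrom": g["chrom"],
            "start": g["start"],
            "end": g["end"],
            "name": g["gene"],
            "score": 0,
            "strand": g["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path: str | os.PathLike) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "gene": bed["name"].astype(str),
            "chrom": bed["chrom"].astype(str),
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "strand": bed["strand"].astype(str),
        }
    )


def write_exons_gtf(
    exons: pd.DataFrame, strands: dict[str, str], path: str | os.PathLike
) -> None:
    """GTF-like exon lines (1-based inclusive coordinates on disk)."""
    with open(path, "w") as fh:
        for row in exons.itertuples(index=False):
            strand = strands.get(row.gene, "+")
            fh.write(
                f"{row.chrom}\tkoaudit\texon\t{row.start + 1}\t{row.end}\t.\t"
                f'{strand}\t.\tgene_id "{row.gene}";\n'
            )


def read_exons_gtf(path: str | os.PathLike) -> pd.DataFrame:
    """Parse exon features from a GTF-like file into 0-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "chrom", "source", "feature", "start", "end",
            "score", "strand", "frame", "attributes",
        ],
    )
    df = df[df["feature"] == "exon"].copy()
    gene = df["attributes"].str.extract(r'gene_id "([^"]+)"')[0]
    return pd.DataFrame(
        {
            "gene": gene.astype(str),
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
        }
    ).reset_index(drop=True)


def write_elements_bed(
    annotation: GeneAnnotation, path: str | os.PathLike
) -> None:
    """Classified element intervals as BED4 (name = element class)."""
    annotation.elements[ELEMENT_COLUMNS].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_elements_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=ELEMENT_COLUMNS
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def derive_elements(
    genes: pd.DataFrame,
    exons: pd.DataFrame,
    chrom_sizes: dict[str, int],
    tss_halfwidth: int = 1000,
) -> pd.DataFrame:
    """Derive the TSS/EXN/INT/ING element map from genes and exons.

    TSS windows are +-``tss_halfwidth`` around the strand-aware start,
    clipped to chromosome bounds.  Introns are the per-gene complement of
    exons inside the gene body; intergenic intervals are the gaps between
    gene bodies (and chromosome ends).
    """
    rows: list[tuple] = []
    for g in genes.itertuples(index=False):
        tss = g.start if g.strand == "+" else g.end - 1
        lo = max(0, tss - tss_halfwidth)
        hi = min(chrom_sizes.get(g.chrom, tss + tss_halfwidth + 1), tss + tss_halfwidth)
        if lo < hi:
            rows.append((g.chrom, lo, hi, "TSS"))
    exn = exons.sort_values(["chrom", "start"])
    for row in exn.itertuples(index=False):
        rows.append((row.chrom, row.start, row.end, "EXN"))
    for gene, sub in exons.groupby("gene", sort=False):
        g = genes[genes["gene"] == gene].iloc[0]
        sub = sub.sort_values("start")
        prev = int(g["start"])
        for row in sub.itertuples(index=False):
            if row.start > prev:
                rows.append((g["chrom"], prev, row.start, "INT"))
            prev = max(prev, int(row.end))
        if prev < int(g["end"]):
            rows.append((g["chrom"], prev, int(g["end"]), "INT"))
    for chrom, size in chrom_sizes.items():
        sub = genes[genes["chrom"] == chrom].sort_values("start")
        prev = 0
        for row in sub.itertuples(index=False):
            if row.start > prev:
                rows.append((chrom, prev, row.start, "ING"))
            prev = max(prev, int(row.end))
        if prev < size:
            rows.append((chrom, prev, size, "ING"))
    out = pd.DataFrame(rows, columns=ELEMENT_COLUMNS)
    return out.sort_values(
        ["chrom", "start", "end", "element_class"], kind="mergesort"
    ).reset_index(drop=True)


def write_annotation(
    annotation: GeneAnnotation, outdir: str | os.PathLike
) -> dict[str, str]:
    """Write genes.bed, exons.gtf, elements.bed and chrom.sizes to a dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_bed": str(outdir / "genes.bed"),
        "exons_gtf": str(outdir / "exons.gtf"),
        "elements_bed": str(outdir / "elements.bed"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
    }
    write_genes_bed(annotation, paths["genes_bed"])
    exn = annotation.elements_of_class("EXN")
    # recover exon->gene assignment by containment in gene bodies
    exn = _assign_genes(exn, annotation.genes)
    strands = dict(zip(annotation.genes["gene"], annotation.genes["strand"]))
    write_exons_gtf(exn, strands, paths["exons_gtf"])
    write_elements_bed(annotation, paths["elements_bed"])
    write_chrom_sizes(annotation.chrom_sizes, paths["chrom_sizes"])
    return paths


def _assign_genes(elements: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    out = elements.copy()
    out["gene"] = ""
    for g in genes.itertuples(index=False):
        mask = (
            (out["chrom"] == g.chrom)
            & (out["start"] >= g.start)
            & (out["end"] <= g.end)
        )
        out.loc[mask & (out["gene"] == ""), "gene"] = g.gene
    return out


def read_annotation(
    genes_bed: str | os.PathLike,
    chrom_sizes: str | os.PathLike,
    elements_bed: str | os.PathLike | None = None,
    exons_gtf: str | os.PathLike | None = None,
    tss_halfwidth: int = 1000,
) -> GeneAnnotation:
    """Load an annotation from BED6 genes plus either a pre-classified
    element BED (exact) or a GTF-like exon file (elements derived)."""
    genes = read_genes_bed(genes_bed)
    sizes = read_chrom_sizes(chrom_sizes)
    if elements_bed is not None:
        elements = read_elements_bed(elements_bed)
    elif exons_gtf is not None:
        exons = read_exons_gtf(exons_gtf)
        elements = derive_elements(genes, exons, sizes, tss_halfwidth)
    else:
        raise ValidationError("need elements_bed or exons_gtf")
    return GeneAnnotation(genes=genes, elements=elements, chrom_sizes=sizes)


# ---------------------------------------------------------------------------
# variants (VCF)


def write_vcf(
    variants: VariantTable,
    path: str | os.PathLike,
    chrom_sizes: dict[str, int] | None = None,
) -> None:
    """Write an uncompressed VCF v4.2 with STRAIN/CODING in INFO."""
    recs = variants.records
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=STRAIN,Number=1,Type=String,'
            'Description="Donor strain of origin">\n'
        )
        fh.write(
            '##INFO=<ID=CODING,Number=0,Type=Flag,'
            'Description="Variant falls in an exon">\n'
        )
        if chrom_sizes:
            for chrom, size in chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={size}>\n")
        else:
            for chrom in recs["chrom"].unique():
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in recs.itertuples(index=False):
            info = []
            if row.strain:
                info.append(f"STRAIN={row.strain}")
            if row.coding:
                info.append("CODING")
            info_str = ";".join(info) if info else "."
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                f"{info_str}\n"
            )


def read_vcf(path: str | os.PathLike) -> VariantTable:
    rows = []
    for rec in VCF(str(path)):
        alt = rec.ALT[0] if rec.ALT else ""
        strain = rec.INFO.get("STRAIN") or ""
        coding = bool(rec.INFO.get("CODING"))
        rows.append((rec.CHROM, rec.POS, rec.REF, alt, strain, coding))
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "strain", "coding"]
    )
    return VariantTable(df)


# ---------------------------------------------------------------------------
# methylation coverage


def write_bedgraph(
    intervals: pd.DataFrame, path: str | os.PathLike
) -> None:
    """Write chrom/start/end/value intervals as BedGraph."""
    intervals[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.10g"
    )


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="t",  # skips optional "track" lines
        names=["chrom", "start", "end", "value"],
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_methyl_profile(
    profile: MethylProfile, path: str | os.PathLike
) -> None:
    profile.elements.to_csv(path, sep="\t", index=False)


def read_methyl_profile(path: str | os.PathLike) -> MethylProfile:
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return MethylProfile(df)


# ---------------------------------------------------------------------------
# gene sets


def write_gene_set(gene_set: GeneSet, path: str | os.PathLike) -> None:
    Path(path).write_text("\n".join(gene_set.members) + "\n")


def read_gene_set(path: str | os.PathLike, label: str | None = None) -> GeneSet:
    path = Path(path)
    members = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return GeneSet(label=label or path.stem, members=members)


def read_gene_sets_dir(directory: str | os.PathLike) -> list[GeneSet]:
    directory = Path(directory)
    return [read_gene_set(p) for p in sorted(directory.glob("*.txt"))]
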