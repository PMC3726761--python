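"""Shared domain types, coordinate conventions, and input validation.

All internal coordinates are 0-based, half-open (BED convention).  VCF
positions are 1-based on disk and converted on read/write.  Strand is
stored per gene but only consulted when placing TSS windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ELEMENT_CLASSES = ("TSS", "EXN", "INT", "ING")

GENE_COLUMNS = ["gene", "chrom", "start", "end", "strand"]
ELEMENT_COLUMNS = ["chrom", "start", "end", "element_class"]
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "strain", "coding"]


class ValidationError(ValueError):
    """Raised when an input structure violates a core invariant."""


def vcf_to_internal(pos: int) -> int:
    """Convert a 1-based VCF position to the internal 0-based coordinate."""
    return pos - 1


def internal_to_vcf(pos: int) -> int:
    """Convert an internal 0-based coordinate to a 1-based VCF position."""
    return pos + 1


@dataclass
class CountMatrix:
    """Integer read counts per gene per sample with a two-group design.

    Parameters
    ----------
    genes : sequence of str
        Ordered, unique gene identifiers (rows of ``counts``).
    samples : sequence of str
        Ordered, unique sample identifiers (columns of ``counts``).
    counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer counts.
    groups : dict
        Mapping sample -> group label; exactly two distinct labels.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene identifiers must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample identifiers must be unique")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        labels = sorted(set(self.groups[s] for s in self.samples))
        if len(labels) != 2:
            raise ValidationError(
                f"exactly two groups required, got {labels}"
            )
        self._labels = labels

    @property
    def group_labels(self) -> tuple[str, str]:
        """The two group labels in sorted order (group1, group2)."""
        return tuple(self._labels)

    def group_indices(self, label: str) -> np.ndarray:
        """Column indices of the samples belonging to ``label``."""
        idx = [j for j, s in enumerate(self.samples) if self.groups[s] == label]
        return np.asarray(idx, dtype=int)

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        """Return a new matrix restricted to ``genes`` (in the given order)."""
        index = {g: i for i, g in enumerate(self.genes)}
        rows = [index[g] for g in genes]
        return CountMatrix(
            genes=list(genes),
            samples=list(self.samples),
            counts=self.counts[rows, :],
            groups=dict(self.groups),
        )


@dataclass
class GeneAnnotation:
    """Gene intervals plus a classified element map.

    ``genes`` has columns gene/chrom/start/end/strand; ``elements`` has
    chrom/start/end/element_class with class in {TSS, EXN, INT, ING}.
    ``chrom_sizes`` maps chromosome name -> length in bp.
    """

    genes: pd.DataFrame
    elements: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes.reset_index(drop=True)
        if list(g.columns[:5]) != GENE_COLUMNS:
            g = g[GENE_COLUMNS]
        if g["gene"].duplicated().any():
            dups = g.loc[g["gene"].duplicated(), "gene"].tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if len(g) and not (g["start"] < g["end"]).all():
            raise ValidationError("gene intervals require start < end")
        if len(g) and not g["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        self.genes = g
        e = self.elements.reset_index(drop=True)
        if len(e):
            bad = set(e["element_class"]) - set(ELEMENT_CLASSES)
            if bad:
                raise ValidationError(f"unknown element classes: {bad}")
            if not (e["start"] < e["end"]).all():
                raise ValidationError("element intervals require start < end")
            for chrom, size in self.chrom_sizes.items():
                sub = e[e["chrom"] == chrom]
                if len(sub) and (sub["end"] > size).any():
                    raise ValidationError(
                        f"element interval beyond {chrom} length {size}"
                    )
        self.elements = e

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene"].tolist()

    def elements_of_class(self, element_class: str) -> pd.DataFrame:
        if element_class not in ELEMENT_CLASSES:
            raise ValidationError(f"unknown element class {element_class!r}")
        return self.elements[
            self.elements["element_class"] == element_class
        ].reset_index(drop=True)


@dataclass
class GeneSet:
    """A labelled signature gene set (e.g. CON, LZS, DZS, NVS, CBS)."""

    label: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.label!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.label!r} has duplicates")


@dataclass
class VariantTable:
    """Called variants; positions are 1-based as in VCF.

    ``records`` columns: chrom, pos, ref, alt, strain (str, '' = unknown),
    coding (bool).  Records are kept sorted by (chrom, pos).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.records.reset_index(drop=True)
        for col, default in (("strain", ""), ("coding", False)):
            if col not in r.columns:
                r[col] = default
        r = r[VARIANT_COLUMNS]
        if len(r):
            if (r["pos"] < 1).any():
                raise ValidationError("VCF positions must be >= 1")
            if (r["ref"].astype(str) == "").any() or (
                r["alt"].astype(str) == ""
            ).any():
                raise ValidationError("alleles must be non-empty")
            r = r.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
                drop=True
            )
        self.records = r

    def __len__(self) -> int:
        return len(self.records)

    def filter_strain(self, strain: str) -> "VariantTable":
        return VariantTable(
            self.records[self.records["strain"] == strain].reset_index(drop=True)
        )


@dataclass
class MethylProfile:
    """Per-element capture-coverage loads for one sample group.

    ``elements`` columns: chrom, start, end, element_class, load.  Loads
    are per-bp coverage mass (length-normalized) and non-negative.
    """

    elements: pd.DataFrame

    def __post_init__(self) -> None:
        e = self.elements.reset_index(drop=True)
        if len(e):
            if (e["load"] < 0).any():
                raise ValidationError("loads must be non-negative")
            for cls in e["element_class"].unique():
                sub = e[e["element_class"] == cls].sort_values(
                    ["chrom", "start"]
                )
                same = sub["chrom"].values[1:] == sub["chrom"].values[:-1]
                overlap = sub["start"].values[1:] < sub["end"].values[:-1]
                if np.any(same & overlap):
                    raise ValidationError(
                        f"overlapping {cls} element instances"
                    )
        self.elements = e

    def loads_of_class(self, element_class: str) -> np.ndarray:
        sub = self.elements[self.elements["element_class"] == element_class]
        return sub["load"].to_numpy(dtype=float)


@dataclass
class ValidationReport:
    """Outcome of cross-checking a count matrix against an annotation."""

    shared_genes: list[str]
    counts_only: list[str]
    annotation_only: list[str]

    @property
    def discrepancies(self) -> list[str]:
        out = []
        if self.counts_only:
            out.append(
                f"{len(self.counts_only)} gene(s) in counts lack coordinates"
            )
        if self.annotation_only:
            out.append(
                f"{len(self.annotation_only)} annotated gene(s) absent from counts"
            )
        return out


def validate_inputs(
    counts: CountMatrix, annotation: GeneAnnotation
) -> ValidationReport:
    """Cross-check counts against annotation.

    Returns the genes present in both (in count-matrix order) plus the
    discrepancies.  Downstream stages operate on the intersection; an
    empty intersection is fatal.
    """
    ann = set(annotation.gene_ids)
    cnt = set(counts.genes)
    shared = [g for g in counts.genes if g in ann]
    if not shared:
        raise ValidationError(
            "no genes shared between counts and annotation"
        )
    return ValidationReport(
        shared_genes=shared,
        counts_only=sorted(cnt - ann),
        annotation_only=sorted(ann - cnt),
    )
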