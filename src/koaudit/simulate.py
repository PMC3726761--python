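"""Synthetic genomes, counts, variants, and methylation coverage.

Generates inputs with the statistical structure the downstream analysis
assumes — negative-binomial counts with a common dispersion, an injected
cis-deregulated passenger region carrying clustered donor-strain SNPs
(mixed up/down effects), directional fold-change offsets for designated
signature gene sets, and null (or deliberately perturbed) methylation
coverage — together with the ground truth needed for parameter-recovery
tests.  One global seed drives independent sub-streams per data type.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .core import (
    CountMatrix,
    ELEMENT_CLASSES,
    GeneAnnotation,
    GeneSet,
    MethylProfile,
    ValidationError,
    VariantTable,
)

# sub-stream ids, so regenerating one data type never perturbs another
_STREAM_ANNOTATION = 0
_STREAM_COUNTS = 1
_STREAM_VARIANTS = 2
_STREAM_METHYLATION = 3

SIGNATURE_LABELS = ("CON", "LZS", "DZS", "NVS", "CBS")


@dataclass
class SimulationConfig:
    n_genes: int = 12_000
    n_chromosomes: int = 5
    chrom_length: int = 60_000_000
    samples_per_group: tuple[int, int] = (2, 2)
    group_labels: tuple[str, str] = ("ctrl", "ko")  # effects apply to 2nd
    mean_log_mu: float = math.log(100.0)
    sd_log_mu: float = 1.0
    dispersion: float = 0.1
    region_chrom: str = "chr1"
    region_start: int = 20_000_000
    region_end: int = 40_000_000
    n_cis_deregulated: int = 200
    cis_effect_range: tuple[float, float] = (1.0, 2.5)
    signature_shifts: dict[str, float] = field(
        default_factory=lambda: {lab: 0.0 for lab in SIGNATURE_LABELS}
    )
    signature_size: int = 100
    family_prefix: str = "Ighv"
    family_size: int = 25
    family_shift: float = 0.0
    snp_background_rate: float = 0.2  # per 50-kb window equivalent
    snp_region_rate: float = 10.0
    snp_rate_unit: int = 50_000
    strain: str = "CBA"
    meth_class_mean: dict[str, float] = field(
        default_factory=lambda: {"TSS": 0.5, "EXN": 0.4, "INT": 0.2, "ING": 0.1}
    )
    meth_dispersion: float = 0.005
    meth_element_sigma: float = 1.5
    tss_halfwidth: int = 1_000
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    libsize_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0 or self.meth_dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not (0 <= self.region_start < self.region_end <= self.chrom_length):
            raise ValidationError("passenger region must lie in its chromosome")
        if self.snp_region_rate <= self.snp_background_rate:
            raise ValidationError(
                "snp_region_rate must exceed snp_background_rate"
            )

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)
        }

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    beta: dict[str, float]  # gene -> signed log2 effect (nonzero only)
    region: tuple[str, int, int]
    signature_offsets: dict[str, float]
    signature_members: dict[str, list[str]]
    family_prefix: str
    family_shift: float
    dispersion: float
    size_factors: list[float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["region"] = tuple(d["region"])
        return cls(**d)


def scenario_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named presets: GC (2v2, LZS up / DZS down, family up), activated
    (4v4, signs reversed), naive (4v4, DZS up), and null (no effects)."""
    base: dict = {"seed": seed}
    if name == "GC":
        base.update(
            samples_per_group=(2, 2),
            signature_shifts={"CON": 0.0, "LZS": +0.5, "DZS": -0.5,
                              "NVS": 0.0, "CBS": 0.0},
            family_shift=+1.0,
        )
    elif name == "activated":
        base.update(
            samples_per_group=(4, 4),
            signature_shifts={"CON": 0.0, "LZS": -0.5, "DZS": +0.5,
                              "NVS": 0.0, "CBS": 0.0},
            family_shift=-1.0,
        )
    elif name == "naive":
        base.update(
            samples_per_group=(4, 4),
            signature_shifts={"CON": 0.0, "LZS": 0.0, "DZS": +0.5,
                              "NVS": 0.0, "CBS": 0.0},
            family_shift=0.0,
        )
    elif name == "null":
        base.update(
            samples_per_group=(4, 4),
            signature_shifts={lab: 0.0 for lab in SIGNATURE_LABELS},
            family_shift=0.0,
            n_cis_deregulated=0,
            snp_background_rate=0.2,
            snp_region_rate=0.4,  # still > background, far below any call
        )
    else:
        raise ValidationError(f"unknown scenario {name!r}")
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Place non-overlapping genes uniformly at random along chromosomes.

    Genes keep a margin of two TSS half-widths from each other and one
    from chromosome edges, so TSS windows never collide.  A fixed seed
    yields an identical annotation.
    """
    rng = config.rng(_STREAM_ANNOTATION)
    sizes = config.chrom_sizes
    chroms = list(sizes)
    n_chrom = len(chroms)
    per_chrom = [
        config.n_genes // n_chrom + (1 if i < config.n_genes % n_chrom else 0)
        for i in range(n_chrom)
    ]
    margin = config.tss_halfwidth
    min_gap = 2 * config.tss_halfwidth
    rows = []
    gene_no = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        length = sizes[chrom]
        lo, hi = config.gene_length_range
        lens = rng.integers(lo, hi + 1, size=n)
        required = int(lens.sum()) + (n - 1) * min_gap + 2 * margin
        if required > length:
            raise ValidationError(
                f"cannot pack {n} genes into {chrom} of length {length}"
            )
        slack = length - required
        gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = margin + gaps[0]
        strands = rng.choice(["+", "-"], size=n)
        for i in range(n):
            start = int(pos)
            end = start + int(lens[i])
            rows.append((f"g{gene_no:05d}", chrom, start, end, strands[i]))
            gene_no += 1
            pos = end + min_gap + gaps[i + 1]
    genes = pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "strand"]
    )
    genes = _rename_family(genes, config, rng)
    exons = _layout_exons(genes)
    elements = kio.derive_elements(
        genes, exons, sizes, tss_halfwidth=config.tss_halfwidth
    )
    return GeneAnnotation(genes=genes, elements=elements, chrom_sizes=sizes)


def _rename_family(
    genes: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Give ``family_size`` genes outside the passenger region family IDs."""
    if config.family_size == 0 or len(genes) == 0:
        return genes
    outside = genes.index[
        ~(
            (genes["chrom"] == config.region_chrom)
            & (genes["start"] < config.region_end)
            & (genes["end"] > config.region_start)
        )
    ].to_numpy()
    n = min(config.family_size, len(outside))
    chosen = rng.choice(outside, size=n, replace=False)
    genes = genes.copy()
    for i, idx in enumerate(sorted(chosen)):
        genes.loc[idx, "gene"] = f"{config.family_prefix}{i:03d}"
    return genes


def _layout_exons(genes: pd.DataFrame) -> pd.DataFrame:
    """Three exons at fixed fractions of each gene body (introns between)."""
    rows = []
    for g in genes.itertuples(index=False):
        length = g.end - g.start
        for lo, hi in ((0.0, 0.2), (0.4, 0.6), (0.8, 1.0)):
            s = g.start + int(round(lo * length))
            e = g.start + int(round(hi * length))
            if e > s:
                rows.append((g.gene, g.chrom, s, e))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# counts


def _region_mask(genes: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    return (
        (genes["chrom"] == config.region_chrom)
        & (genes["start"] < config.region_end)
        & (genes["end"] > config.region_start)
    ).to_numpy()


def simulate_counts(
    config: SimulationConfig, annotation: GeneAnnotation
) -> tuple[CountMatrix, GroundTruth]:
    """Draw NB counts mean = s_j * mu_g * 2^(x_j * beta_g), dispersion phi.

    x_j is 1 for the second group label; beta_g is nonzero for the
    configured cis-deregulated genes inside the passenger region (signs a
    symmetric +- mixture), offset by each signature set's delta for its
    members, and by the family shift for family-prefixed genes.
    GroundTruth records every nonzero beta and the set memberships.
    """
    rng = config.rng(_STREAM_COUNTS)
    genes = annotation.genes
    gene_ids = genes["gene"].to_numpy()
    n_genes = len(gene_ids)
    mu = rng.lognormal(config.mean_log_mu, config.sd_log_mu, size=n_genes)
    beta = np.zeros(n_genes)

    in_region = _region_mask(genes, config)
    region_idx = np.flatnonzero(in_region)
    if config.n_cis_deregulated > len(region_idx):
        raise ValidationError(
            f"region holds {len(region_idx)} genes; cannot deregulate "
            f"{config.n_cis_deregulated}"
        )
    cis_idx = rng.choice(
        region_idx, size=config.n_cis_deregulated, replace=False
    )
    magnitudes = rng.uniform(*config.cis_effect_range, size=len(cis_idx))
    signs = rng.choice([-1.0, 1.0], size=len(cis_idx))
    beta[cis_idx] = signs * magnitudes

    is_family = np.array(
        [g.startswith(config.family_prefix) for g in gene_ids]
    )
    # signature members: non-region, non-family genes, disjoint across sets
    pool = np.flatnonzero(~in_region & ~is_family)
    pool = rng.permutation(pool)
    members: dict[str, list[str]] = {}
    offset = 0
    for label in SIGNATURE_LABELS:
        take = pool[offset : offset + config.signature_size]
        offset += config.signature_size
        members[label] = sorted(gene_ids[take])
        delta = config.signature_shifts.get(label, 0.0)
        if delta:
            beta[take] += delta
    if config.family_shift:
        beta[is_family] += config.family_shift

    n1, n2 = config.samples_per_group
    g1, g2 = config.group_labels
    samples = [f"{g1}_{i + 1}" for i in range(n1)] + [
        f"{g2}_{i + 1}" for i in range(n2)
    ]
    groups = {s: (g1 if i < n1 else g2) for i, s in enumerate(samples)}
    x = np.array([0.0] * n1 + [1.0] * n2)
    lo, hi = config.libsize_range
    s = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n1 + n2))
    mean = s[None, :] * mu[:, None] * np.power(2.0, x[None, :] * beta[:, None])
    counts = _nb_draw(rng, mean, config.dispersion)
    cm = CountMatrix(
        genes=list(gene_ids), samples=samples, counts=counts, groups=groups
    )
    truth = GroundTruth(
        beta={gene_ids[i]: float(beta[i]) for i in np.flatnonzero(beta)},
        region=(config.region_chrom, config.region_start, config.region_end),
        signature_offsets=dict(config.signature_shifts),
        signature_members=members,
        family_prefix=config.family_prefix,
        family_shift=config.family_shift,
        dispersion=config.dispersion,
        size_factors=[float(v) for v in s],
    )
    return cm, truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, phi: float
) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def signature_gene_sets(truth: GroundTruth) -> list[GeneSet]:
    return [
        GeneSet(label=label, members=list(members))
        for label, members in truth.signature_members.items()
    ]


# ---------------------------------------------------------------------------
# variants


def simulate_variants(
    config: SimulationConfig, annotation: GeneAnnotation
) -> VariantTable:
    """Poisson-process strain-informative variants.

    Intensity is ``snp_background_rate`` per rate unit (default 50 kb)
    genome-wide and ``snp_region_rate`` inside the passenger region.  All
    variants carry the donor strain label; the coding flag marks exon hits.
    """
    rng = config.rng(_STREAM_VARIANTS)
    bases = "ACGT"
    rows = []
    for chrom, size in config.chrom_sizes.items():
        segments = [(0, size, config.snp_background_rate)]
        if chrom == config.region_chrom:
            segments = [
                (0, config.region_start, config.snp_background_rate),
                (config.region_start, config.region_end, config.snp_region_rate),
                (config.region_end, size, config.snp_background_rate),
            ]
        for seg_start, seg_end, rate in segments:
            span = seg_end - seg_start
            if span <= 0 or rate <= 0:
                continue
            lam = rate * span / config.snp_rate_unit
            n = rng.poisson(lam)
            if n == 0:
                continue
            pos0 = np.sort(rng.integers(seg_start, seg_end, size=n))
            ref_i = rng.integers(0, 4, size=n)
            alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
            for p, ri, ai in zip(pos0, ref_i, alt_i):
                rows.append(
                    (chrom, int(p) + 1, bases[ri], bases[ai], config.strain)
                )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "strain"])
    df["coding"] = _in_exon(df, annotation)
    return VariantTable(df)


def _in_exon(variants: pd.DataFrame, annotation: GeneAnnotation) -> np.ndarray:
    exons = annotation.elements_of_class("EXN")
    flags = np.zeros(len(variants), dtype=bool)
    for chrom, sub in variants.groupby("chrom", sort=False):
        exn = exons[exons["chrom"] == chrom].sort_values("start")
        if not len(exn):
            continue
        starts = exn["start"].to_numpy()
        ends = exn["end"].to_numpy()
        pos0 = sub["pos"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        flags[sub.index[inside]] = True
    return flags


# ---------------------------------------------------------------------------
# methylation


def simulate_methylation(
    config: SimulationConfig,
    annotation: GeneAnnotation,
    inject_demethylation: dict[str, float] | None = None,
) -> tuple[MethylProfile, MethylProfile]:
    """Per-element loads from shared element-class means with NB noise.

    Each element draws a latent per-element mean (log-normal around its
    class mean, spread ``meth_element_sigma``) shared between groups, then
    each group observes an NB read count at that mean times the element
    length.  ``inject_demethylation`` multiplies group B's latent means
    for the named classes by the given factors.
    """
    rng = config.rng(_STREAM_METHYLATION)
    inject = inject_demethylation or {}
    elements = annotation.elements.reset_index(drop=True)
    lengths = (elements["end"] - elements["start"]).to_numpy(dtype=float)
    class_mean = np.array(
        [config.meth_class_mean[c] for c in elements["element_class"]]
    )
    sigma = config.meth_element_sigma
    latent = class_mean * rng.lognormal(
        -0.5 * sigma**2, sigma, size=len(elements)
    )
    factor_b = np.array(
        [inject.get(c, 1.0) for c in elements["element_class"]]
    )
    loads = []
    for group_latent in (latent, latent * factor_b):
        mean_reads = group_latent * lengths
        reads = _nb_draw(rng, mean_reads, config.meth_dispersion)
        loads.append(reads / lengths)
    prof_a = elements.copy()
    prof_a["load"] = loads[0]
    prof_b = elements.copy()
    prof_b["load"] = loads[1]
    return MethylProfile(prof_a), MethylProfile(prof_b)


def profile_to_bedgraph(profile: MethylProfile) -> pd.DataFrame:
    """Flatten per-element loads to a non-overlapping coverage track.

    Where element classes overlap (e.g. a TSS window over the first exon)
    the class earlier in TSS > EXN > INT > ING wins, so TSS loads survive
    a round trip through element_loads exactly.
    """
    priority = {c: i for i, c in enumerate(ELEMENT_CLASSES)}
    frames = []
    e = profile.elements
    for chrom in e["chrom"].unique():
        sub = e[e["chrom"] == chrom]
        bounds = np.unique(
            np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()])
        )
        seg_start = bounds[:-1]
        seg_end = bounds[1:]
        seg_val = np.full(len(seg_start), np.nan)
        seg_rank = np.full(len(seg_start), len(ELEMENT_CLASSES))
        for cls in reversed(ELEMENT_CLASSES):  # lowest priority first
            c = sub[sub["element_class"] == cls].sort_values("start")
            if not len(c):
                continue
            starts = c["start"].to_numpy()
            ends = c["end"].to_numpy()
            vals = c["load"].to_numpy()
            idx = np.searchsorted(starts, seg_start, side="right") - 1
            inside = (idx >= 0) & (seg_start < ends[np.clip(idx, 0, None)])
            better = inside & (priority[cls] <= seg_rank)
            seg_val[better] = vals[idx[better]]
            seg_rank[better] = priority[cls]
        keep = ~np.isnan(seg_val)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": seg_start[keep],
                    "end": seg_end[keep],
                    "value": seg_val[keep],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# one-call emission


def simulate_all(
    config: SimulationConfig,
    outdir: str | Path,
    inject_demethylation: dict[str, float] | None = None,
) -> dict[str, str]:
    """Generate every input the pipeline consumes and write it to a dir.

    Emits counts (TSV), group map, annotation (BED/GTF-like/element BED +
    chrom sizes), variant and strain-panel VCFs, two BedGraph coverage
    tracks, signature gene-set files, and a ground-truth JSON.  Returns
    the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    counts, truth = simulate_counts(config, annotation)
    variants = simulate_variants(config, annotation)
    prof_a, prof_b = simulate_methylation(config, annotation,
                                          inject_demethylation)

    paths = kio.write_annotation(annotation, outdir / "annotation")
    paths["counts_tsv"] = str(outdir / "counts.tsv")
    kio.write_counts_tsv(counts, paths["counts_tsv"])
    paths["groups_tsv"] = str(outdir / "groups.tsv")
    kio.write_groups_tsv(counts.groups, paths["groups_tsv"])

    # called variants carry no strain label; the panel carries the labels
    unlabeled = VariantTable(
        variants.records.assign(strain="", coding=False)
    )
    paths["variants_vcf"] = str(outdir / "variants.vcf")
    kio.write_vcf(unlabeled, paths["variants_vcf"], config.chrom_sizes)
    paths["panel_vcf"] = str(outdir / "panel.vcf")
    kio.write_vcf(variants, paths["panel_vcf"], config.chrom_sizes)

    paths["coverage_a"] = str(outdir / "coverage_a.bedgraph")
    kio.write_bedgraph(profile_to_bedgraph(prof_a), paths["coverage_a"])
    paths["coverage_b"] = str(outdir / "coverage_b.bedgraph")
    kio.write_bedgraph(profile_to_bedgraph(prof_b), paths["coverage_b"])

    sets_dir = outdir / "sets"
    sets_dir.mkdir(exist_ok=True)
    for gs in signature_gene_sets(truth):
        kio.write_gene_set(gs, sets_dir / f"{gs.label}.txt")
    paths["sets_dir"] = str(sets_dir)

    paths["ground_truth"] = str(outdir / "ground_truth.json")
    Path(paths["ground_truth"]).write_text(truth.to_json() + "\n")
    return paths
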