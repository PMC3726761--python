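"""Windowed strain-SNP density scan and passenger-region calling.

Variants are binned into fixed-width windows tiling each chromosome
(default 50 kb); maximal runs of high-density windows, optionally bridged
across short cold gaps, are called as candidate donor-strain regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneAnnotation, ValidationError, VariantTable


@dataclass
class ScanConfig:
    window_size: int = 50_000
    density_threshold: int = 5
    merge_gap: int = 2
    min_region_span: int = 3

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValidationError("window size must be positive")
        if self.density_threshold < 1:
            raise ValidationError("density threshold must be >= 1")
        if self.merge_gap < 0:
            raise ValidationError("merge gap must be >= 0")


@dataclass
class WindowDensity:
    """Per-window variant counts; windows tile each chromosome."""

    windows: pd.DataFrame  # chrom, start, end, count
    window_size: int


@dataclass
class RegionCall:
    chrom: str
    start: int
    end: int
    n_windows: int
    n_variants: int
    mean_hot_density: float
    strain: str = ""


def intersect_variants_coding(
    variants: VariantTable, annotation: GeneAnnotation
) -> VariantTable:
    """Retain variants whose position falls inside an exon; set coding flag.

    A 1-based variant position p occupies internal base p-1; containment
    uses the half-open exon convention.
    """
    exons = annotation.elements_of_class("EXN")
    recs = variants.records
    keep = np.zeros(len(recs), dtype=bool)
    for chrom, sub in recs.groupby("chrom", sort=False):
        exn = exons[exons["chrom"] == chrom].sort_values("start")
        if not len(exn):
            continue
        starts = exn["start"].to_numpy()
        ends = exn["end"].to_numpy()
        pos0 = sub["pos"].to_numpy() - 1
        # exon intervals are disjoint per chromosome after sorting
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        keep[sub.index[inside]] = True
    out = recs[keep].copy()
    out["coding"] = True
    return VariantTable(out.reset_index(drop=True))


def label_strain(variants: VariantTable, panel: VariantTable) -> VariantTable:
    """Label variants by exact (chrom, pos, ref, alt) match to a strain panel.

    Unmatched variants get an empty ("unknown") strain label.
    """
    key_cols = ["chrom", "pos", "ref", "alt"]
    panel_map = {
        tuple(row): strain
        for row, strain in zip(
            panel.records[key_cols].itertuples(index=False),
            panel.records["strain"],
        )
    }
    out = variants.records.copy()
    out["strain"] = [
        panel_map.get(tuple(row), "")
        for row in out[key_cols].itertuples(index=False)
    ]
    return VariantTable(out)


def window_density(
    variants: VariantTable,
    chrom_sizes: dict[str, int],
    config: ScanConfig,
    strain: str | None = None,
) -> WindowDensity:
    """Count (optionally strain-filtered) variants per tiling window.

    A variant at 1-based position p lands in window floor((p-1)/w).  The
    last window of each chromosome is truncated at the chromosome end;
    variants beyond the end are counted in the last window with a warning.
    """
    recs = variants.records
    if strain is not None:
        recs = recs[recs["strain"] == strain]
    w = config.window_size
    frames = []
    for chrom, size in chrom_sizes.items():
        n_win = max(1, int(np.ceil(size / w)))
        starts = np.arange(n_win) * w
        ends = np.minimum(starts + w, size)
        sub = recs[recs["chrom"] == chrom]
        idx = (sub["pos"].to_numpy(dtype=np.int64) - 1) // w
        if np.any(idx >= n_win):
            warnings.warn(
                f"{int(np.sum(idx >= n_win))} variant(s) beyond {chrom} end; "
                "counted in last window"
            )
            idx = np.minimum(idx, n_win - 1)
        counts = np.bincount(idx, minlength=n_win)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "count": counts}
            )
        )
    windows = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end", "count"])
    )
    return WindowDensity(windows=windows, window_size=w)


def call_regions(
    density: WindowDensity,
    config: ScanConfig,
    variants: VariantTable | None = None,
) -> list[RegionCall]:
    """Call maximal runs of hot windows as candidate regions.

    A window is hot when count >= density_threshold; consecutive hot runs
    separated by at most ``merge_gap`` cold windows merge; calls spanning
    fewer than ``min_region_span`` windows are dropped.  Regions never
    cross chromosomes.  When ``variants`` is given, each call's strain
    label is the majority vote of member variants.
    """
    out: list[RegionCall] = []
    for chrom, sub in density.windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        counts = sub["count"].to_numpy()
        hot = np.flatnonzero(counts >= config.density_threshold)
        if hot.size == 0:
            continue
        runs: list[list[int]] = [[hot[0], hot[0]]]
        for i in hot[1:]:
            if i - runs[-1][1] - 1 <= config.merge_gap:
                runs[-1][1] = i
            else:
                runs.append([i, i])
        for first, last in runs:
            span = last - first + 1
            if span < config.min_region_span:
                continue
            start = int(sub.loc[first, "start"])
            end = int(sub.loc[last, "end"])
            member = counts[first : last + 1]
            hot_member = member[member >= config.density_threshold]
            call = RegionCall(
                chrom=str(chrom),
                start=start,
                end=end,
                n_windows=span,
                n_variants=int(member.sum()),
                mean_hot_density=float(hot_member.mean()),
            )
            if variants is not None:
                recs = variants.records
                inside = recs[
                    (recs["chrom"] == chrom)
                    & (recs["pos"] - 1 >= start)
                    & (recs["pos"] - 1 < end)
                ]
                labels = inside.loc[inside["strain"] != "", "strain"]
                if len(labels):
                    call.strain = labels.mode().iloc[0]
            out.append(call)
    return out


def regions_to_bed(regions: list[RegionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "name": r.strain or "region",
                "score": r.n_variants,
                "strand": ".",
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def windows_to_bedgraph(density: WindowDensity) -> pd.DataFrame:
    df = density.windows.rename(columns={"count": "value"})
    return df[["chrom", "start", "end", "value"]]
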