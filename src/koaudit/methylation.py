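"""Element-wise methylation-load comparison between two groups.

Capture coverage (BedGraph intervals) is reduced to per-element loads —
overlap-weighted coverage mass divided by element length — for each of
the TSS/EXN/INT/ING classes; classes are compared with a two-sided
Mann-Whitney test (t-test available behind a flag) and per-TSS loads are
correlated across groups with Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr, ttest_ind

from .core import ELEMENT_CLASSES, GeneAnnotation, MethylProfile, ValidationError


@dataclass
class ClassComparison:
    element_class: str
    mean_a: float
    mean_b: float
    pvalue: float
    n_a: int
    n_b: int
    testable: bool = True


@dataclass
class MethylComparison:
    classes: list[ClassComparison]
    pearson_r: float | None  # None when undefined (zero variance)
    n_tss: int


def element_loads(
    coverage: pd.DataFrame, annotation: GeneAnnotation
) -> MethylProfile:
    """Per-element load = overlapping coverage mass / element length.

    ``coverage`` is a BedGraph-like frame (chrom/start/end/value) with
    non-overlapping, per-chromosome-sortable intervals.
    """
    if (coverage["value"] < 0).any():
        raise ValidationError("coverage must be non-negative")
    elements = annotation.elements
    if ((elements["end"] - elements["start"]) <= 0).any():
        raise ValidationError("zero-length element")
    loads = np.zeros(len(elements))
    for chrom, cov in coverage.groupby("chrom", sort=False):
        sel = elements["chrom"] == chrom
        if not sel.any():
            continue
        cov = cov.sort_values("start")
        c_start = cov["start"].to_numpy(dtype=float)
        c_end = cov["end"].to_numpy(dtype=float)
        val = cov["value"].to_numpy(dtype=float)
        # cumulative coverage mass F(x) = integral of the step function
        cum = np.concatenate([[0.0], np.cumsum(val * (c_end - c_start))])

        def mass_upto(x: np.ndarray) -> np.ndarray:
            # F(x): mass of intervals fully left of x plus the partial
            # overlap with the first interval whose end exceeds x
            full = np.searchsorted(c_end, x, side="right")
            i = np.minimum(full, len(val) - 1)
            partial = np.where(
                full < len(val),
                val[i] * np.clip(x - c_start[i], 0.0, None),
                0.0,
            )
            return cum[full] + partial

        starts = elements.loc[sel, "start"].to_numpy(dtype=float)
        ends = elements.loc[sel, "end"].to_numpy(dtype=float)
        mass = mass_upto(ends) - mass_upto(starts)
        loads[np.flatnonzero(sel.to_numpy())] = mass
    lengths = (elements["end"] - elements["start"]).to_numpy(dtype=float)
    out = elements.copy()
    out["load"] = loads / lengths
    return MethylProfile(out)


def compare_class(
    profile_a: MethylProfile,
    profile_b: MethylProfile,
    element_class: str,
    test: str = "mannwhitney",
) -> ClassComparison:
    """Two-sided location test on the per-element loads of one class."""
    a = profile_a.loads_of_class(element_class)
    b = profile_b.loads_of_class(element_class)
    if len(a) < 2 or len(b) < 2:
        return ClassComparison(
            element_class=element_class,
            mean_a=float(np.mean(a)) if len(a) else float("nan"),
            mean_b=float(np.mean(b)) if len(b) else float("nan"),
            pvalue=float("nan"),
            n_a=len(a),
            n_b=len(b),
            testable=False,
        )
    if test == "mannwhitney":
        _, p = mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ttest":
        _, p = ttest_ind(a, b, equal_var=False)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return ClassComparison(
        element_class=element_class,
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        pvalue=float(p),
        n_a=len(a),
        n_b=len(b),
    )


def pearson_tss(
    profile_a: MethylProfile, profile_b: MethylProfile
) -> float | None:
    """Pearson r of per-TSS loads across groups (matched by interval).

    Returns None when either vector has zero variance (r undefined).
    """
    key = ["chrom", "start", "end"]
    a = profile_a.elements
    a = a[a["element_class"] == "TSS"][key + ["load"]]
    b = profile_b.elements
    b = b[b["element_class"] == "TSS"][key + ["load"]]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValidationError("need >= 3 shared TSS elements")
    x = merged["load_a"].to_numpy()
    y = merged["load_b"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r, _ = pearsonr(x, y)
    return float(r)


def compare_methylation(
    profile_a: MethylProfile,
    profile_b: MethylProfile,
    test: str = "mannwhitney",
) -> MethylComparison:
    classes = [
        compare_class(profile_a, profile_b, cls, test=test)
        for cls in ELEMENT_CLASSES
    ]
    n_tss = int(
        (profile_a.elements["element_class"] == "TSS").sum()
    )
    try:
        r = pearson_tss(profile_a, profile_b)
    except ValidationError:
        r = None
    return MethylComparison(classes=classes, pearson_r=r, n_tss=n_tss)


def comparison_to_frame(comparison: MethylComparison) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_class": c.element_class,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "pvalue": c.pvalue,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "testable": c.testable,
            }
            for c in comparison.classes
        ]
    )
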