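"""Two-group differential expression on counts.

Median-of-ratios normalization, pooled method-of-moments common-dispersion
estimation, an exact conditional negative-binomial test (two-sided by the
small-p rule, reducing to the binomial exact test in the Poisson limit),
and Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core import CountMatrix, GeneAnnotation, ValidationError

_POISSON_PHI = 1e-10  # below this, use the Poisson limit


@dataclass
class DispersionEstimate:
    phi: float
    method: str = "pooled-moments"

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValidationError("dispersion must be >= 0")


def estimate_size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the per-gene geometric mean over samples,
    restricted to genes expressed in every sample.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    if mat.shape[1] < 1:
        raise ValidationError("need at least one sample")
    if np.any(mat.sum(axis=0) == 0):
        raise ValidationError("sample with all-zero counts")
    expressed = np.all(mat > 0, axis=1)
    if not expressed.any():
        raise ValidationError(
            "no gene expressed in every sample; cannot form reference"
        )
    logs = np.log(mat[expressed, :])
    ref = logs.mean(axis=1)  # log geometric mean per gene
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def estimate_common_dispersion(
    counts: CountMatrix, factors: np.ndarray
) -> DispersionEstimate:
    """Single common NB dispersion via pooled method of moments.

    For normalized counts y = K/s the model implies
    Var(y) = mu * mean(1/s) + phi * mu^2 within a group; the estimator
    pools numerator and denominator over genes and groups, with a small
    finite-sample correction on mu^2, and clips at zero.
    """
    factors = np.asarray(factors, dtype=float)
    num = 0.0
    den = 0.0
    any_replication = False
    for label in counts.group_labels:
        idx = counts.group_indices(label)
        if len(idx) < 2:
            continue
        any_replication = True
        s = factors[idx]
        y = counts.counts[:, idx] / s
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        a = np.mean(1.0 / s)
        keep = m > 0
        n = len(idx)
        num += np.sum(v[keep] - a * m[keep])
        den += np.sum(m[keep] ** 2 - v[keep] / n)
    if not any_replication:
        raise ValidationError(
            "dispersion estimation needs replication in at least one group"
        )
    if den <= 0:
        return DispersionEstimate(phi=0.0)
    return DispersionEstimate(phi=float(max(0.0, num / den)))


def _nb_logpmf(k: np.ndarray, mean: float, r: float) -> np.ndarray:
    """NB log-pmf parameterized by mean and size r (var = mean + mean^2/r)."""
    k = np.asarray(k, dtype=float)
    logp = np.log(r / (r + mean))
    log1mp = np.log(mean / (r + mean)) if mean > 0 else -np.inf
    return (
        gammaln(k + r) - gammaln(r) - gammaln(k + 1) + r * logp + k * log1mp
    )


def _poisson_logpmf(k: np.ndarray, mean: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    if mean == 0:
        return np.where(k == 0, 0.0, -np.inf)
    return k * np.log(mean) - mean - gammaln(k + 1)


def nb_exact_test(
    count_a: int,
    count_b: int,
    n_a: float,
    n_b: float,
    phi: float,
) -> float:
    """Exact conditional two-group NB test on collapsed pseudo-counts.

    ``count_a``/``count_b`` are the per-group pseudo-counts at a common
    per-sample library size, with ``n_a``/``n_b`` samples per group; the
    group totals are then NB with mean n*mu and dispersion phi/n.
    Conditional on the two-group total, the two-sided p-value sums the
    conditional probabilities not exceeding the observed outcome's
    probability (small-p rule), so p in (0, 1].
    """
    if phi < 0:
        raise ValidationError("dispersion must be >= 0")
    if count_a < 0 or count_b < 0:
        raise ValidationError("counts must be non-negative")
    total = int(count_a) + int(count_b)
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    k = np.arange(total + 1)
    if phi < _POISSON_PHI:
        la = _poisson_logpmf(k, n_a * mu)
        lb = _poisson_logpmf(k[::-1], n_b * mu)
    else:
        la = _nb_logpmf(k, n_a * mu, n_a / phi)
        lb = _nb_logpmf(k[::-1], n_b * mu, n_b / phi)
    joint = la + lb
    joint -= logsumexp(joint)
    obs = joint[int(count_a)]
    keep = joint <= obs + 1e-9
    p = float(np.exp(logsumexp(joint[keep])))
    if p > 1.0 - 1e-10:  # modal outcome: everything included, snap to 1
        return 1.0
    return max(p, float(np.exp(obs)))


def collapse_pseudo_counts(
    counts: np.ndarray, factors: np.ndarray
) -> np.ndarray:
    """Collapse samples to per-group pseudo-counts at common library size.

    Mean scaling only (no quantile adjustment): each sample's counts are
    divided by its size factor and summed within the group, then rounded.
    Exact when all size factors are equal; an approximation otherwise.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    z = (counts / np.asarray(factors, dtype=float)).sum(axis=1)
    return np.rint(z).astype(np.int64)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_de(
    counts: CountMatrix,
    fdr_cutoff: float = 0.01,
    pseudocount: float = 0.5,
    annotation: GeneAnnotation | None = None,
    dispersion: float | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Full two-group DE analysis.

    Returns the per-gene table sorted by p-value (ties broken by gene id)
    and the list of genes with FDR below ``fdr_cutoff``.  Fold changes are
    log2 of normalized group means, group2 vs group1 (labels sorted), with
    ``pseudocount`` added to both means.
    """
    factors = estimate_size_factors(counts)
    if dispersion is None:
        phi = estimate_common_dispersion(counts, factors).phi
    else:
        phi = float(dispersion)
    g1, g2 = counts.group_labels
    idx1 = counts.group_indices(g1)
    idx2 = counts.group_indices(g2)
    z1 = collapse_pseudo_counts(counts.counts[:, idx1], factors[idx1])
    z2 = collapse_pseudo_counts(counts.counts[:, idx2], factors[idx2])
    n1, n2 = len(idx1), len(idx2)
    pvals = np.array(
        [nb_exact_test(a, b, n1, n2, phi) for a, b in zip(z1, z2)]
    )
    norm = counts.counts / factors
    mean1 = norm[:, idx1].mean(axis=1)
    mean2 = norm[:, idx2].mean(axis=1)
    log2fc = np.log2(mean2 + pseudocount) - np.log2(mean1 + pseudocount)
    table = pd.DataFrame(
        {
            "gene": counts.genes,
            "log2FC": log2fc,
            "pvalue": pvals,
            "FDR": bh_adjust(pvals),
            "mean_expr": (mean1 + mean2) / 2.0,
        }
    )
    if annotation is not None:
        coords = annotation.genes.set_index("gene")[["chrom", "start", "end"]]
        table = table.join(coords, on="gene")
        table = table[
            ["gene", "chrom", "start", "end", "log2FC", "pvalue", "FDR",
             "mean_expr"]
        ]
    table = table.sort_values(
        ["pvalue", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    significant = table.loc[table["FDR"] < fdr_cutoff, "gene"].tolist()
    return table, significant
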