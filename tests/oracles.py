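"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written by a different route than the
package implementation: exact rational arithmetic (fractions), explicit
enumeration, and per-base accumulation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def median_of_ratios_oracle(mat: np.ndarray) -> np.ndarray:
    """Hand-rolled median-of-ratios size factors (geometric mean 1)."""
    mat = np.asarray(mat, dtype=float)
    keep = [i for i in range(mat.shape[0]) if all(mat[i] > 0)]
    ref = []
    for i in keep:
        prod = 1.0
        for v in mat[i]:
            prod *= v
        ref.append(prod ** (1.0 / mat.shape[1]))
    factors = []
    for j in range(mat.shape[1]):
        ratios = sorted(mat[i, j] / ref[k] for k, i in enumerate(keep))
        n = len(ratios)
        mid = (
            ratios[n // 2]
            if n % 2
            else 0.5 * (ratios[n // 2 - 1] + ratios[n // 2])
        )
        factors.append(mid)
    geo = 1.0
    for f in factors:
        geo *= f
    geo **= 1.0 / len(factors)
    return np.array([f / geo for f in factors])


def _nb_pmf_fraction(k: int, r: int, p: Fraction) -> Fraction:
    """NB pmf with integer size r and rational success prob p (exact)."""
    return comb(k + r - 1, k) * p**r * (1 - p) ** k


def nb_exact_oracle(
    count_a: int, count_b: int, n_a: int, n_b: int, phi: Fraction
) -> float:
    """Exact conditional two-sided NB p-value by rational enumeration.

    Requires n_a/phi and n_b/phi integral (true for the phis the
    acceptance criteria use), or phi == 0 for the binomial limit.
    """
    total = count_a + count_b
    if total == 0:
        return 1.0
    mu = Fraction(total, n_a + n_b)
    probs: list[Fraction] = []
    if phi == 0:
        # Poisson limit: conditional is Binomial(total, n_a/(n_a+n_b))
        w = Fraction(n_a, n_a + n_b)
        for k in range(total + 1):
            probs.append(comb(total, k) * w**k * (1 - w) ** (total - k))
    else:
        r_a = Fraction(n_a) / phi
        r_b = Fraction(n_b) / phi
        assert r_a.denominator == 1 and r_b.denominator == 1
        p_a = r_a / (r_a + n_a * mu)
        p_b = r_b / (r_b + n_b * mu)
        for k in range(total + 1):
            probs.append(
                _nb_pmf_fraction(k, int(r_a), p_a)
                * _nb_pmf_fraction(total - k, int(r_b), p_b)
            )
    z = sum(probs)
    cond = [p / z for p in probs]
    obs = cond[count_a]
    thr = obs * (1 + Fraction(1, 10**9))
    return float(sum(p for p in cond if p <= thr))


def sign_test_oracle(k: int, n: int) -> float:
    """Two-sided sign test by exhaustive binomial enumeration (exact)."""
    half = Fraction(1, 2)
    lower = sum(comb(n, i) for i in range(0, k + 1)) * half**n
    upper = sum(comb(n, i) for i in range(k, n + 1)) * half**n
    return float(min(Fraction(1), 2 * min(lower, upper)))


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    denom = comb(n, c1)
    pmf = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    pobs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= pobs))


def call_regions_oracle(
    counts: np.ndarray, threshold: int, merge_gap: int, min_span: int
) -> list[tuple[int, int]]:
    """Run-length scan over one chromosome's window counts.

    Returns (first_window, last_window) index pairs, written as a direct
    state machine rather than the implementation's run-merging.
    """
    regions = []
    i = 0
    n = len(counts)
    while i < n:
        if counts[i] < threshold:
            i += 1
            continue
        start = i
        last_hot = i
        j = i + 1
        while j < n:
            if counts[j] >= threshold:
                last_hot = j
                j += 1
            elif j - last_hot <= merge_gap:
                j += 1
            else:
                break
        if last_hot - start + 1 >= min_span:
            regions.append((start, last_hot))
        i = last_hot + 1
    return regions


def element_loads_oracle(
    coverage_rows: list[tuple[int, int, float]],
    elements: list[tuple[int, int]],
    genome_length: int,
) -> list[float]:
    """Per-base accumulation of coverage mass over a single toy chromosome."""
    base = np.zeros(genome_length)
    for start, end, value in coverage_rows:
        base[start:end] += value
    return [base[s:e].sum() / (e - s) for s, e in elements]


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """BH step-up via statsmodels (independent of the package's own code)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]
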