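"""Directional gene-signature shift analysis on DE fold changes.

Each predefined gene set (CON, LZS, DZS, NVS, CBS, or an ad-hoc family
such as all Ighv genes) is scored by the sign of its members' log2 fold
changes and tested with the exact two-sided sign test against one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import GeneSet, ValidationError


@dataclass
class SignatureShift:
    label: str
    n_scored: int
    n_positive: int
    n_negative: int
    n_zero: int
    median_log2fc: float
    pvalue: float
    n_skipped: int = 0
    testable: bool = True

    def __post_init__(self) -> None:
        if self.testable:
            assert self.n_positive + self.n_negative + self.n_zero == self.n_scored


def sign_test(values: np.ndarray) -> float:
    """Exact two-sided sign test: doubled smaller binomial(n, 1/2) tail.

    Zeros are excluded before testing; capped at 1.  Raises if no nonzero
    value remains (an untestable set).
    """
    values = np.asarray(values, dtype=float)
    values = values[values != 0]
    n = values.size
    if n == 0:
        raise ValidationError("sign test undefined: all values are zero")
    k = int(np.sum(values > 0))
    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _shift_from_values(label: str, logfc: np.ndarray, n_skipped: int = 0) -> SignatureShift:
    logfc = np.asarray(logfc, dtype=float)
    n_pos = int(np.sum(logfc > 0))
    n_neg = int(np.sum(logfc < 0))
    n_zero = int(np.sum(logfc == 0))
    if n_pos + n_neg == 0:
        return SignatureShift(
            label=label,
            n_scored=logfc.size,
            n_positive=n_pos,
            n_negative=n_neg,
            n_zero=n_zero,
            median_log2fc=float(np.median(logfc)) if logfc.size else float("nan"),
            pvalue=float("nan"),
            n_skipped=n_skipped,
            testable=False,
        )
    return SignatureShift(
        label=label,
        n_scored=logfc.size,
        n_positive=n_pos,
        n_negative=n_neg,
        n_zero=n_zero,
        median_log2fc=float(np.median(logfc)),
        pvalue=sign_test(logfc),
        n_skipped=n_skipped,
    )


def score_signatures(
    de_table: pd.DataFrame, gene_sets: list[GeneSet]
) -> list[SignatureShift]:
    """Score every gene set against the DE table's log2 fold changes.

    Members absent from the table are counted as skipped; a set with an
    empty intersection is flagged untestable and the rest proceed.
    """
    logfc_by_gene = dict(zip(de_table["gene"], de_table["log2FC"]))
    out = []
    for gs in gene_sets:
        present = [g for g in gs.members if g in logfc_by_gene]
        skipped = len(gs.members) - len(present)
        if not present:
            out.append(
                SignatureShift(
                    label=gs.label,
                    n_scored=0,
                    n_positive=0,
                    n_negative=0,
                    n_zero=0,
                    median_log2fc=float("nan"),
                    pvalue=float("nan"),
                    n_skipped=skipped,
                    testable=False,
                )
            )
            continue
        logfc = np.array([logfc_by_gene[g] for g in present])
        out.append(_shift_from_values(gs.label, logfc, n_skipped=skipped))
    return out


def gene_family_shift(
    de_table: pd.DataFrame, family: str | list[str]
) -> SignatureShift:
    """Score an ad-hoc gene family given as an ID prefix or explicit list."""
    if isinstance(family, str):
        mask = de_table["gene"].str.startswith(family)
        members = de_table.loc[mask, "gene"].tolist()
        label = family
    else:
        members = [g for g in family if g in set(de_table["gene"])]
        label = "family"
    if not members:
        raise ValidationError(f"gene family {label!r} matches no gene")
    shifts = score_signatures(de_table, [GeneSet(label=label, members=members)])
    return shifts[0]


def shifts_to_frame(shifts: list[SignatureShift]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": s.label,
                "n_scored": s.n_scored,
                "n_positive": s.n_positive,
                "n_negative": s.n_negative,
                "n_zero": s.n_zero,
                "n_skipped": s.n_skipped,
                "median_log2FC": s.median_log2fc,
                "sign_test_p": s.pvalue,
                "testable": s.testable,
            }
            for s in shifts
        ]
    )
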