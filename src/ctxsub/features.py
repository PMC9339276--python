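"""Context composition indices, CpG contingency analysis, duplex stability.

The three hexanucleotide indices weight the flanking-pair composition by
proximity to the focal site (pair N_i sits i bases away on each side):

* ATI — A+T count per pair, weights 8/4/2 for N1/N2/N3 (range 0-28);
* RI — purine count per pair on the analyzed strand, same weights (0-28),
  used for substitutions of pyrimidines;
* RATI — per-base scores A=2, C=0, G=1, T=1 summed per pair, weights 4/2/1
  (range 0-28).

The CpG analysis contrasts transition counts at focal sites with a CpG
neighbor against all other neighbors, on each strand separately (G->A with a
5' C, and C->T with a 3' G), as cross-product odds ratios on 2x2 tables whose
second column includes all non-transition outcomes (conserved sites
included).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .contexts import BASE_INDEX, ContextKey
from .matrices import ContextCountTable

#: default proximity weights for pair N_i, i = 1, 2, 3
ATI_WEIGHTS = (8, 4, 2)
RATI_WEIGHTS = (4, 2, 1)
_RATI_SCORE = {"A": 2, "C": 0, "G": 1, "T": 1}


def _pairs(context: ContextKey):
    """(5' base, 3' base) of pair N_i for i = 1..radius."""
    if context.radius != 3:
        raise ValueError(f"indices are defined for radius 3, got {context.radius}")
    for i in range(1, 4):
        yield context.left[-i], context.right[i - 1]


def ati(context: ContextKey, weights: Sequence[int] = ATI_WEIGHTS) -> int:
    """A+T index of a hexanucleotide context (0-28)."""
    return sum(
        w * sum(1 for b in pair if b in "AT")
        for w, pair in zip(weights, _pairs(context))
    )


def ri(context: ContextKey, weights: Sequence[int] = ATI_WEIGHTS) -> int:
    """Purine index on the analyzed strand (0-28)."""
    return sum(
        w * sum(1 for b in pair if b in "AG")
        for w, pair in zip(weights, _pairs(context))
    )


def rati(context: ContextKey, weights: Sequence[int] = RATI_WEIGHTS) -> int:
    """Combined purine/A+T index with base scores A=2, C=0, G=1, T=1 (0-28)."""
    return sum(
        w * sum(_RATI_SCORE[b] for b in pair)
        for w, pair in zip(weights, _pairs(context))
    )


# ---------------------------------------------------------------------------
# CpG contingency analysis
# ---------------------------------------------------------------------------


@dataclass
class CpGTables:
    """Strand-explicit 2x2 transition tables for the CpG contrast.

    ``g_table`` rows are CG vs DG (focal G preceded by C vs not), columns
    G->A vs G->B (B = C, G or T, conserved included); ``c_table`` rows are CG
    vs CH (focal C followed by G vs not), columns C->T vs C->V.
    """

    g_table: np.ndarray
    c_table: np.ndarray


def cpg_tables(table: ContextCountTable) -> CpGTables:
    """Aggregate a raw (uncombined, strand-explicit) count table into the two
    CpG 2x2 tables."""
    if table.combined:
        raise ValueError("CpG analysis needs strand-explicit (uncombined) counts")
    if table.total() == 0:
        raise ValueError("count table is empty")
    r = table.radius
    n = table.counts.shape[0]
    idx = np.arange(n)
    left_near = (idx // 4**r) % 4  # base immediately 5' of the focal site
    right_near = (idx % 4**r) // 4 ** (r - 1)  # base immediately 3'
    A, C, G, T = (BASE_INDEX[b] for b in "ACGT")

    g_rows = table.counts[:, G, :]  # (contexts, 4 derived)
    cg = left_near == C
    g_table = np.array(
        [
            [g_rows[cg, A].sum(), g_rows[cg].sum() - g_rows[cg, A].sum()],
            [g_rows[~cg, A].sum(), g_rows[~cg].sum() - g_rows[~cg, A].sum()],
        ],
        dtype=np.int64,
    )
    c_rows = table.counts[:, C, :]
    cg2 = right_near == G
    c_table = np.array(
        [
            [c_rows[cg2, T].sum(), c_rows[cg2].sum() - c_rows[cg2, T].sum()],
            [c_rows[~cg2, T].sum(), c_rows[~cg2].sum() - c_rows[~cg2, T].sum()],
        ],
        dtype=np.int64,
    )
    return CpGTables(g_table=g_table, c_table=c_table)


def odds_ratio(table: np.ndarray) -> float:
    """Cross-product ratio (a/b)/(c/d) of a 2x2 table; NaN if any cell is 0."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    if min(a, b, c, d) <= 0:
        warnings.warn("odds ratio undefined: zero cell in 2x2 table")
        return math.nan
    return (a / b) / (c / d)


def chi2_heterogeneity(table: np.ndarray) -> tuple:
    """Pearson chi-square (df=1, no continuity correction) and its p-value."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = scipy.stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Nearest-neighbor duplex stability
# ---------------------------------------------------------------------------

#: Unified nearest-neighbor dinucleotide-step dG(37C) in kcal/mol
#: (SantaLucia 1998 unified parameter set, duplex-symmetric: a step and its
#: reverse complement share one value).  Initiation/terminal terms are
#: omitted: only relative comparisons between heptanucleotides are used.
NN_DG37 = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}


def duplex_stability(heptamer: str) -> float:
    """Stacking dG37 of a duplex: sum of the internal dinucleotide steps."""
    heptamer = heptamer.upper()
    if any(b not in "ACGT" for b in heptamer):
        raise ValueError(f"invalid symbol in {heptamer!r}")
    if len(heptamer) < 2:
        raise ValueError("need at least one dinucleotide step")
    return sum(NN_DG37[heptamer[i : i + 2]] for i in range(len(heptamer) - 1))


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need equal-length vectors with at least 2 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
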