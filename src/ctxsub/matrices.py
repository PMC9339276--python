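"""Context-dependent substitution count matrices and derived rate summaries.

Counts are stored densely: one 4x4 ancestral-by-derived integer matrix per
strand-explicit context, with conserved sites on the diagonal.  Combining
complementary contexts pools each context with the complement-transform of its
reverse-complement partner, so both strand readings contribute to one matrix;
self-complementary contexts are left as counted once.  Row-normalizing a count
matrix gives the Markov transition matrix Pi with Pi[i, j] = CM[i, j] / sum_j
CM[i, j], whose off-diagonal entries are raw substitutions/site (no multiple-
hit correction) per average ingroup branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .contexts import (
    BASES,
    BASE_INDEX,
    TRANSITION_PARTNER,
    ContextKey,
    canonical_index_mask,
    context_to_index,
    index_to_context,
    n_contexts,
    rc_permutation,
    self_complementary_mask,
)

ContextLike = Union[ContextKey, str, tuple]


def _as_index(context: ContextLike, radius: int) -> int:
    if isinstance(context, ContextKey):
        key = context
    elif isinstance(context, str):
        key = ContextKey.from_string(context)
    else:
        key = ContextKey(*context)
    if key.radius != radius:
        raise ValueError(f"context radius {key.radius} != table radius {radius}")
    return context_to_index(key)


class ContextCountTable:
    """Dense mapping from strand-explicit context to its 4x4 count matrix.

    Indexable by :class:`ContextKey`, ``"LEFT|RIGHT"`` strings, or
    ``(left, right)`` tuples; values are 4x4 integer arrays in A,C,G,T order
    (rows ancestral, columns derived).
    """

    def __init__(self, radius: int, counts: Optional[np.ndarray] = None, combined: bool = False):
        if radius < 1:
            raise ValueError("radius must be >= 1")
        self.radius = radius
        shape = (n_contexts(radius), 4, 4)
        if counts is None:
            counts = np.zeros(shape, dtype=np.int64)
        else:
            counts = np.asarray(counts, dtype=np.int64)
            if counts.shape != shape:
                raise ValueError(f"counts shape {counts.shape}, expected {shape}")
        self.counts = counts
        self.combined = combined

    # -- mapping-style access -------------------------------------------------
    def __getitem__(self, context: ContextLike) -> np.ndarray:
        return self.counts[_as_index(context, self.radius)]

    def __iter__(self) -> Iterator[ContextKey]:
        for i in np.nonzero(self.counts.sum(axis=(1, 2)))[0]:
            yield index_to_context(int(i), self.radius)

    def context_total(self, context: ContextLike) -> int:
        return int(self[context].sum())

    def total(self) -> int:
        return int(self.counts.sum())

    def n_substitutions(self) -> int:
        off = self.counts.sum(axis=(1, 2)) - np.trace(self.counts, axis1=1, axis2=2)
        return int(off.sum())

    @property
    def canonical_indices(self) -> np.ndarray:
        return np.nonzero(canonical_index_mask(self.radius))[0]

    def canonical_counts(self) -> np.ndarray:
        """Counts restricted to canonical contexts (rows for others untouched)."""
        return self.counts[canonical_index_mask(self.radius)]

    # -- construction ---------------------------------------------------------
    def add(self, context: ContextLike, ancestral: str, derived: str, n: int = 1) -> None:
        self.counts[_as_index(context, self.radius), BASE_INDEX[ancestral], BASE_INDEX[derived]] += n

    def combine_complements(self) -> "ContextCountTable":
        """Pool each context with the complement-transform of its partner.

        ``combined[c][i, j] = raw[c][i, j] + raw[rc(c)][comp(i), comp(j)]`` for
        contexts with ``rc(c) != c``; self-complementary contexts keep their
        raw counts.  Complementary pairs become identical, so restricting to
        canonical contexts afterwards conserves the total count exactly.
        """
        if self.combined:
            raise ValueError("table is already combined")
        perm = rc_permutation(self.radius)
        transformed = self.counts[perm][:, ::-1, ::-1]
        out = self.counts + transformed
        self_mask = self_complementary_mask(self.radius)
        out[self_mask] = self.counts[self_mask]
        return ContextCountTable(self.radius, out, combined=True)

    # -- serialization --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        idx, i, j = np.nonzero(self.counts)
        mask = canonical_index_mask(self.radius)
        rows = {
            "context_left": [index_to_context(int(k), self.radius).left for k in idx],
            "context_right": [index_to_context(int(k), self.radius).right for k in idx],
            "ancestral": [BASES[a] for a in i],
            "derived": [BASES[d] for d in j],
            "count": self.counts[idx, i, j],
            "canonical": mask[idx],
        }
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, radius: Optional[int] = None, combined: bool = False) -> "ContextCountTable":
        if len(frame) == 0:
            if radius is None:
                raise ValueError("radius required for an empty table")
            return cls(radius, combined=combined)
        r = len(frame["context_left"].iloc[0])
        if radius is not None and radius != r:
            raise ValueError(f"radius {radius} != frame radius {r}")
        table = cls(r, combined=combined)
        cols = (frame[c] for c in ("context_left", "context_right", "ancestral", "derived", "count"))
        for left, right, anc, der, cnt in zip(*cols):
            table.add((left, right), anc, der, int(cnt))
        return table

    @classmethod
    def from_tsv(cls, path, combined: bool = False) -> "ContextCountTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"context_left": str, "context_right": str}), combined=combined)


def accumulate_counts(records: Iterable, radius: int) -> ContextCountTable:
    """Accumulate substitution records into a strand-explicit count table.

    Each record needs ``context`` (a :class:`ContextKey` of the given radius),
    ``ancestral`` and ``derived`` attributes; mixed radii raise.
    """
    table = ContextCountTable(radius)
    for rec in records:
        if rec.context.radius != radius:
            raise ValueError(
                f"record radius {rec.context.radius} != requested radius {radius}"
            )
        table.add(rec.context, rec.ancestral, rec.derived)
    return table


@dataclass
class TransitionMatrix:
    """Row-normalized count matrix for one context.

    ``probs`` rows are probability vectors except where ``empty_rows`` flags a
    zero-count ancestral base; ``row_n`` holds the row sample sizes and
    ``counts`` the source count matrix.
    """

    context: ContextKey
    probs: np.ndarray
    row_n: np.ndarray
    counts: Optional[np.ndarray] = None

    @property
    def empty_rows(self) -> np.ndarray:
        return self.row_n == 0


def to_transition_matrix(counts: np.ndarray, context: ContextKey) -> TransitionMatrix:
    counts = np.asarray(counts)
    row_n = counts.sum(axis=1)
    probs = np.zeros((4, 4), dtype=float)
    nz = row_n > 0
    probs[nz] = counts[nz] / row_n[nz, None]
    return TransitionMatrix(context=context, probs=probs, row_n=row_n, counts=counts)


def rate_ci(p: float, n: int) -> tuple:
    """Wald 95% interval p +/- 1.96 sqrt(p(1-p)/n), clipped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    half = 1.96 * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


@dataclass
class RateSummary:
    """Per-context transition/transversion rates for one ancestral base."""

    context: ContextKey
    from_base: str
    ts_rate: float
    tv_rate: float
    total_rate: float
    ts_tv: Optional[float]  # None when n_tv == 0
    n_ts: int
    n_tv: int
    n_row: int


def rate_summary(tm: TransitionMatrix, from_base: str) -> RateSummary:
    """Ts/Tv rates from one matrix row.

    Restricted to pyrimidine rows: after complement combining the A and G rows
    mirror the T and C rows, so only C and T carry independent information.
    """
    if from_base not in ("C", "T"):
        raise ValueError("from_base must be 'C' or 'T' (A/G rows are redundant)")
    i = BASE_INDEX[from_base]
    if tm.row_n[i] == 0:
        raise ValueError(f"empty {from_base} row in context {tm.context}")
    partner = BASE_INDEX[TRANSITION_PARTNER[from_base]]
    tv_targets = [j for j in range(4) if j not in (i, partner)]
    ts_rate = float(tm.probs[i, partner])
    tv_rate = float(tm.probs[i, tv_targets].sum())
    counts = tm.counts if tm.counts is not None else np.round(tm.probs * tm.row_n[:, None]).astype(np.int64)
    n_ts = int(counts[i, partner])
    n_tv = int(counts[i, tv_targets].sum())
    ts_tv = ts_rate / tv_rate if n_tv > 0 else None
    return RateSummary(
        context=tm.context,
        from_base=from_base,
        ts_rate=ts_rate,
        tv_rate=tv_rate,
        total_rate=ts_rate + tv_rate,
        ts_tv=ts_tv,
        n_ts=n_ts,
        n_tv=n_tv,
        n_row=int(tm.row_n[i]),
    )


def rate_summaries(table: ContextCountTable, canonical_only: bool = True) -> list:
    """RateSummary for the C and T rows of every (canonical) context."""
    out = []
    mask = canonical_index_mask(table.radius)
    totals = table.counts.sum(axis=(1, 2))
    for idx in np.nonzero(totals)[0]:
        if canonical_only and not mask[idx]:
            continue
        key = index_to_context(int(idx), table.radius)
        tm = to_transition_matrix(table.counts[idx], key)
        for base in ("T", "C"):
            if tm.row_n[BASE_INDEX[base]] > 0:
                out.append(rate_summary(tm, base))
    return out


_FOLD_STATS = ("ts_rate", "tv_rate", "total_rate", "ts_tv")


def _passes(s: RateSummary, mode: str, min_ts: int, min_tv: int, min_row: int) -> bool:
    if mode == "ts50tv50":
        return s.n_ts >= min_ts and s.n_tv >= min_tv
    if mode == "row100":
        return s.n_ts + s.n_tv >= min_row
    raise ValueError(f"unknown mode {mode!r}")


def fold_variation_table(
    summaries: Sequence[RateSummary],
    mode: str = "ts50tv50",
    min_ts: int = 50,
    min_tv: int = 50,
    min_row: int = 100,
) -> pd.DataFrame:
    """Max/min fold-variation across contexts passing a count threshold.

    ``mode='ts50tv50'`` requires at least ``min_ts`` transitions and ``min_tv``
    transversions in the row; ``mode='row100'`` requires ``min_row``
    substitutions in the row.  Rows cover each statistic for substitutions from
    T, from C, and from either ('T+C' takes extremes over the union).  Ts:Tv
    values undefined by a zero transversion count are excluded from the Ts:Tv
    line.
    """
    passing = [s for s in summaries if _passes(s, mode, min_ts, min_tv, min_row)]
    if not passing:
        raise ValueError("no context passes the threshold")
    rows = []
    for stat in _FOLD_STATS:
        for scope in ("T", "C", "T+C"):
            pool = [
                s for s in passing
                if scope == "T+C" or s.from_base == scope
            ]
            vals = [(getattr(s, stat), s) for s in pool if getattr(s, stat) is not None]
            if not vals:
                continue
            hi_v, hi_s = max(vals, key=lambda t: t[0])
            lo_v, lo_s = min(vals, key=lambda t: t[0])
            fold = hi_v / lo_v if lo_v > 0 else math.inf
            rows.append(
                {
                    "statistic": stat,
                    "from": scope,
                    "fold": fold,
                    "max_value": hi_v,
                    "max_context": str(hi_s.context),
                    "max_from": hi_s.from_base,
                    "min_value": lo_v,
                    "min_context": str(lo_s.context),
                    "min_from": lo_s.from_base,
                    "n_contexts": len(vals),
                }
            )
    return pd.DataFrame(rows)


def slice_by_outer_pair(
    table: ContextCountTable,
    internal_context: ContextKey,
) -> Mapping[tuple, np.ndarray]:
    """The 16 radius-r matrices surrounding a fixed radius-(r-1) context.

    For each outer pair (x, y) the returned matrix is the count matrix of the
    context ``(x + internal_left, internal_right + y)``, controlling exactly
    for the internal context; summing the 16 matrices gives the marginal
    matrix of the internal context.
    """
    if internal_context.radius != table.radius - 1:
        raise ValueError(
            f"internal radius {internal_context.radius} must be table radius - 1 "
            f"({table.radius - 1})"
        )
    out = {}
    for x in BASES:
        for y in BASES:
            key = ContextKey(x + internal_context.left, internal_context.right + y)
            out[(x, y)] = table[key]
    return out
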