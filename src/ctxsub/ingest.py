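"""Triplet alignment parsing and per-site substitution record extraction.

Each region is an alignment of two closely related ingroup sequences plus an
outgroup whose base is taken as the ancestral state.  A column contributes two
records (one per ingroup, conserved sites included) when it passes the
eligibility filters:

* window: of the 10 surrounding alignment columns (5 per side) at least 8 are
  non-gap bases in both ingroups, and at least 7 of the 10 are identical
  non-gap matches between the ingroups (>= 70% similarity; any gap counts as a
  mismatch);
* context: the r nearest columns on each side are gap-free and identical in
  all three sequences, so the flanking context is conserved and alignment
  neighbors equal physical neighbors;
* focal: the focal column is a plain base (A/C/G/T) in all three sequences
  and lies at least max(5, r) columns from either end.

Ambiguity codes and any non-ACGT symbol are treated as gaps for eligibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional

import numpy as np
from Bio import SeqIO

from .contexts import BASES, ContextKey
from .matrices import ContextCountTable

logger = logging.getLogger(__name__)

MIN_REGION_COLUMNS = 70
WINDOW = 5  # columns examined on each side of the focal site
MIN_WINDOW_PAIRS = 8  # non-gap in both ingroups, out of 10
MIN_WINDOW_MATCHES = 7  # identical ingroup bases, out of 10 (>=70%)

_CODE = np.full(256, 4, dtype=np.int8)  # 4 = gap/ambiguous/other
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

ROLES = ("ingroup1", "ingroup2", "outgroup")


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class TripletAlignment:
    """Equal-length gapped sequences for one noncoding region."""

    region_id: str
    ingroup1: str
    ingroup2: str
    outgroup: str

    def __post_init__(self) -> None:
        lengths = {len(self.ingroup1), len(self.ingroup2), len(self.outgroup)}
        if len(lengths) != 1:
            raise ValueError(
                f"region {self.region_id!r}: sequences have unequal lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.outgroup)

    def codes(self) -> tuple:
        return _encode(self.outgroup), _encode(self.ingroup1), _encode(self.ingroup2)


@dataclass
class SubstitutionRecord:
    region_id: str
    column: int
    context: ContextKey
    ancestral: str
    derived: str
    ingroup_index: int


@dataclass
class FilterTally:
    """Accounting of why alignment columns were kept or excluded.

    Exclusions are attributed to the first failing filter in the order edge,
    focal gap, window gaps, window similarity, context conservation, so
    ``columns_scanned = eligible + sum(excluded_*)`` holds exactly.
    """

    regions_read: int = 0
    regions_too_short: int = 0
    columns_scanned: int = 0
    excluded_edge: int = 0
    excluded_focal_gap: int = 0
    excluded_window_gaps: int = 0
    excluded_window_similarity: int = 0
    excluded_context: int = 0
    eligible: int = 0

    def add(self, other: "FilterTally") -> None:
        for name in self.__dataclass_fields__:
            setattr(self, name, getattr(self, name) + getattr(other, name))

    @property
    def excluded_total(self) -> int:
        return (
            self.excluded_edge
            + self.excluded_focal_gap
            + self.excluded_window_gaps
            + self.excluded_window_similarity
            + self.excluded_context
        )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.__dataclass_fields__}


def read_triplet_alignments(
    path,
    min_columns: int = MIN_REGION_COLUMNS,
    tally: Optional[FilterTally] = None,
) -> List[TripletAlignment]:
    """Read role-tagged FASTA alignments from a file or directory.

    Record ids must end in ``|ingroup1``, ``|ingroup2`` or ``|outgroup``; the
    prefix names the region.  Regions with ``min_columns`` or fewer alignment
    columns are skipped and tallied.
    """
    path = Path(path)
    files = sorted(path.glob("*.fa*")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no FASTA files under {path}")
    triplets: List[TripletAlignment] = []
    for fname in files:
        regions: dict = {}
        order: list = []
        for rec in SeqIO.parse(str(fname), "fasta"):
            name, sep, role = rec.id.rpartition("|")
            if not sep or role not in ROLES:
                raise ValueError(
                    f"{fname}: record id {rec.id!r} lacks a |ingroup1/|ingroup2/|outgroup tag"
                )
            if name not in regions:
                regions[name] = {}
                order.append(name)
            regions[name][role] = str(rec.seq).upper()
        for name in order:
            seqs = regions[name]
            missing = [r for r in ROLES if r not in seqs]
            if missing:
                raise ValueError(f"{fname}: region {name!r} missing role(s) {missing}")
            trip = TripletAlignment(name, seqs["ingroup1"], seqs["ingroup2"], seqs["outgroup"])
            if trip.length <= min_columns:
                if tally is not None:
                    tally.regions_too_short += 1
                logger.info("skipping region %s: %d columns (<= %d)", name, trip.length, min_columns)
                continue
            if tally is not None:
                tally.regions_read += 1
            triplets.append(trip)
    return triplets


def site_eligible(triplet: TripletAlignment, column: int, radius: int) -> bool:
    """Scalar eligibility check for one alignment column (reference semantics)."""
    og, a, b = triplet.codes()
    L = triplet.length
    if not 0 <= column < L:
        raise IndexError(f"column {column} out of range [0, {L})")
    lo = max(WINDOW, radius)
    if column < lo or column > L - 1 - lo:
        return False
    if og[column] >= 4 or a[column] >= 4 or b[column] >= 4:
        return False
    win = [column + d for d in range(-WINDOW, WINDOW + 1) if d != 0]
    pairs = sum(1 for c in win if a[c] < 4 and b[c] < 4)
    if pairs < MIN_WINDOW_PAIRS:
        return False
    matches = sum(1 for c in win if a[c] < 4 and a[c] == b[c])
    if matches < MIN_WINDOW_MATCHES:
        return False
    for d in range(1, radius + 1):
        for c in (column - d, column + d):
            if og[c] >= 4 or og[c] != a[c] or a[c] != b[c]:
                return False
    return True


def _eligibility(
    triplet: TripletAlignment, radius: int, tally: Optional[FilterTally] = None
):
    """Vectorized eligibility mask plus context index per column.

    Returns (eligible mask, context index array, outgroup/ingroup code arrays).
    Context indices are big-endian base-4 over the concatenated left+right
    flanking bases and are only meaningful where the mask is True.
    """
    og, a, b = triplet.codes()
    L = triplet.length
    lo = max(WINDOW, radius)
    pos = np.arange(L)
    interior = (pos >= lo) & (pos <= L - 1 - lo)

    focal_ok = (og < 4) & (a < 4) & (b < 4)

    pair = ((a < 4) & (b < 4)).astype(np.int32)
    match = ((a < 4) & (a == b)).astype(np.int32)
    kernel = np.ones(2 * WINDOW + 1, dtype=np.int32)
    win_pairs = np.convolve(pair, kernel, mode="same") - pair
    win_match = np.convolve(match, kernel, mode="same") - match

    cons = (og < 4) & (og == a) & (a == b)
    ctx_ok = np.ones(L, dtype=bool)
    ctx_idx = np.zeros(L, dtype=np.int64)
    for d in range(1, radius + 1):
        for shifted in (np.roll(cons, d), np.roll(cons, -d)):
            ctx_ok &= shifted
    # big-endian digits: left bases (far to near), then right bases (near to far)
    weight = 2 * radius - 1
    for d in range(radius, 0, -1):
        ctx_idx += np.roll(og, d).astype(np.int64) * 4**weight
        weight -= 1
    for d in range(1, radius + 1):
        ctx_idx += np.roll(og, -d).astype(np.int64) * 4**weight
        weight -= 1

    pairs_ok = win_pairs >= MIN_WINDOW_PAIRS
    match_ok = win_match >= MIN_WINDOW_MATCHES
    eligible = interior & focal_ok & pairs_ok & match_ok & ctx_ok

    if tally is not None:
        tally.columns_scanned += L
        fail_edge = ~interior
        fail_focal = interior & ~focal_ok
        fail_pairs = interior & focal_ok & ~pairs_ok
        fail_match = interior & focal_ok & pairs_ok & ~match_ok
        fail_ctx = interior & focal_ok & pairs_ok & match_ok & ~ctx_ok
        tally.excluded_edge += int(fail_edge.sum())
        tally.excluded_focal_gap += int(fail_focal.sum())
        tally.excluded_window_gaps += int(fail_pairs.sum())
        tally.excluded_window_similarity += int(fail_match.sum())
        tally.excluded_context += int(fail_ctx.sum())
        tally.eligible += int(eligible.sum())
    return eligible, ctx_idx, og, a, b


def extract_site_records(
    triplet: TripletAlignment, radius: int, tally: Optional[FilterTally] = None
) -> Iterator[SubstitutionRecord]:
    """Yield two records (one per ingroup) for every eligible column.

    The outgroup base is the ancestral state; both ingroup bases are derived
    states, so a column where both ingroups differ from the outgroup counts as
    two substitutions and conserved columns populate matrix diagonals.
    """
    eligible, ctx_idx, og, a, b = _eligibility(triplet, radius, tally)
    for col in np.nonzero(eligible)[0]:
        col = int(col)
        left = "".join(BASES[c] for c in og[col - radius : col])
        right = "".join(BASES[c] for c in og[col + 1 : col + 1 + radius])
        key = ContextKey(left, right)
        anc = BASES[og[col]]
        yield SubstitutionRecord(triplet.region_id, col, key, anc, BASES[a[col]], 1)
        yield SubstitutionRecord(triplet.region_id, col, key, anc, BASES[b[col]], 2)


def count_table_from_alignments(
    triplets: Iterable[TripletAlignment],
    radius: int,
    tally: Optional[FilterTally] = None,
) -> ContextCountTable:
    """Accumulate eligible columns of many regions into a count table.

    Vectorized equivalent of running :func:`extract_site_records` through
    :func:`ctxsub.matrices.accumulate_counts`.
    """
    table = ContextCountTable(radius)
    flat = table.counts.reshape(-1, 4)  # (contexts*4, 4): row = ctx*4 + ancestral
    for trip in triplets:
        eligible, ctx_idx, og, a, b = _eligibility(trip, radius, tally)
        cols = np.nonzero(eligible)[0]
        if len(cols) == 0:
            continue
        rows = ctx_idx[cols] * 4 + og[cols]
        np.add.at(flat, (rows, a[cols]), 1)
        np.add.at(flat, (rows, b[cols]), 1)
    return table
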