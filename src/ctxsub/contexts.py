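"""Strand-explicit flanking contexts and reverse-complement canonicalization.

A *context* is the pair of r-mers flanking a focal site: ``left`` runs 5'->3'
and ends immediately 5' of the site, ``right`` runs 5'->3' starting
immediately 3' of it.  Reading the opposite strand maps a context onto its
reverse complement, ``rc(left, right) = (revcomp(right), revcomp(left))``,
which is an involution; picking the lexicographically smaller concatenated
string of each pair yields the canonical representative.  For radius r there
are ``4**(2r)`` strand-explicit contexts and ``(4**(2r) - 4**r)/2 + 4**r``
canonical ones (2,080 hexanucleotide classes at r = 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: complement of base code i is 3 - i under the A,C,G,T ordering
_RC_TABLE = str.maketrans("ACGT", "TGCA")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
#: transition partner of each base (A<->G, C<->T)
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over ACGT."""
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True, order=True)
class ContextKey:
    """Flanking context (left r-mer, right r-mer) around a focal site."""

    left: str
    right: str

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError(
                f"left/right lengths differ: {self.left!r} vs {self.right!r}"
            )
        if not self.left:
            raise ValueError("context r-mers must be non-empty")
        for mer in (self.left, self.right):
            if any(b not in BASE_INDEX for b in mer):
                raise ValueError(f"context {mer!r} contains non-ACGT symbols")

    @property
    def radius(self) -> int:
        return len(self.left)

    def reverse_complement(self) -> "ContextKey":
        return ContextKey(revcomp(self.right), revcomp(self.left))

    def canonical(self) -> "ContextKey":
        rc = self.reverse_complement()
        return self if self.left + self.right <= rc.left + rc.right else rc

    @property
    def is_canonical(self) -> bool:
        return self == self.canonical()

    @property
    def is_self_complementary(self) -> bool:
        return self == self.reverse_complement()

    def __str__(self) -> str:
        return f"{self.left}|{self.right}"

    @classmethod
    def from_string(cls, text: str) -> "ContextKey":
        left, sep, right = text.partition("|")
        if not sep:
            raise ValueError(f"expected 'LEFT|RIGHT', got {text!r}")
        return cls(left, right)


def n_contexts(radius: int) -> int:
    """Number of strand-explicit contexts at a given radius."""
    return 4 ** (2 * radius)


def n_canonical_contexts(radius: int) -> int:
    """Number of reverse-complement equivalence classes at a given radius."""
    total = n_contexts(radius)
    self_comp = 4**radius  # right == revcomp(left)
    return (total - self_comp) // 2 + self_comp


def kmer_to_index(kmer: str) -> int:
    """Big-endian base-4 index of a k-mer (A=0, C=1, G=2, T=3)."""
    idx = 0
    for b in kmer:
        idx = idx * 4 + BASE_INDEX[b]
    return idx


def index_to_kmer(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


def context_to_index(key: ContextKey) -> int:
    """Index of a context = big-endian index of left+right concatenated."""
    return kmer_to_index(key.left + key.right)


def index_to_context(index: int, radius: int) -> ContextKey:
    s = index_to_kmer(index, 2 * radius)
    return ContextKey(s[:radius], s[radius:])


@lru_cache(maxsize=None)
def rc_permutation(radius: int) -> np.ndarray:
    """Permutation p with p[i] = index of the reverse-complement context.

    Because rc(left, right) concatenates to revcomp(left + right), this is the
    reverse-complement permutation on 2r-mers.
    """
    k = 2 * radius
    idx = np.arange(4**k, dtype=np.int64)
    out = np.zeros_like(idx)
    for j in range(k):  # digit j has weight 4**(k-1-j)
        digit = (idx // 4 ** (k - 1 - j)) % 4
        out += (3 - digit) * 4**j
    out.setflags(write=False)
    return out


@lru_cache(maxsize=None)
def canonical_index_mask(radius: int) -> np.ndarray:
    """Boolean mask of canonical context indices (i <= rc(i))."""
    perm = rc_permutation(radius)
    mask = np.arange(len(perm)) <= perm
    mask.setflags(write=False)
    return mask


@lru_cache(maxsize=None)
def self_complementary_mask(radius: int) -> np.ndarray:
    perm = rc_permutation(radius)
    mask = np.arange(len(perm)) == perm
    mask.setflags(write=False)
    return mask


def enumerate_contexts(radius: int, canonical_only: bool = False) -> Iterator[ContextKey]:
    mask = canonical_index_mask(radius) if canonical_only else None
    for i in range(n_contexts(radius)):
        if mask is None or mask[i]:
            yield index_to_context(i, radius)
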