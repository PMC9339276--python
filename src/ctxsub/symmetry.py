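"""Strand-orientation from gene annotations and complementary-context tests.

Chloroplast genomes are deposited with an arbitrary annotated strand.  A
reference gene set (rps12 and psbA on one strand; psbK, psbD and psbC on the
other) fixes a common orientation: genomes with that arrangement are kept and
relabeled so the rps12/psbA strand is "A".  Genes annotated in at least 90%
of the oriented genomes and on a consistent strand in at least 80% of them
form the symmetry gene list; regions between two such genes can then be
extracted from the same physical strand in every genome, giving
strand-explicit matrices whose complementary contexts carry independent
estimates of the two strands' dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .contexts import canonical_index_mask, index_to_context, rc_permutation, self_complementary_mask
from .equilibrium import composition_stats, stationary_vector
from .features import pearson_r2
from .matrices import ContextCountTable, to_transition_matrix

logger = logging.getLogger(__name__)

#: reference genes: first group on one strand, second group on the other
REFERENCE_GENES = (("rps12", "psba"), ("psbk", "psbd", "psbc"))


@dataclass
class GenomeAnnotation:
    """Gene -> strand (+/-) for one genome, names case-normalized."""

    genome_id: str
    gene_strands: Dict[str, str]

    def __post_init__(self) -> None:
        norm = {}
        for gene, strand in self.gene_strands.items():
            if strand not in "+-":
                raise ValueError(f"{self.genome_id}: bad strand {strand!r} for {gene}")
            norm[gene.strip().lower()] = strand
        self.gene_strands = norm


@dataclass
class OrientedGenome:
    """Annotation relabeled to strands A/C; ``flipped`` if A was the - strand."""

    genome_id: str
    flipped: bool
    gene_strands: Dict[str, str]  # gene -> "A" or "C"


def read_annotations(path) -> List[GenomeAnnotation]:
    """Annotation TSV with columns genome_id, gene, strand."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for gid, sub in frame.groupby("genome_id", sort=True):
        out.append(GenomeAnnotation(gid, dict(zip(sub["gene"], sub["strand"]))))
    return out


def find_symmetry_genomes(
    annotations: Iterable[GenomeAnnotation],
    reference: Tuple[Sequence[str], Sequence[str]] = REFERENCE_GENES,
) -> List[OrientedGenome]:
    """Keep genomes whose reference genes split across the two strands as
    expected and relabel strands so the rps12/psbA strand is A."""
    group_a, group_c = ([g.lower() for g in grp] for grp in reference)
    oriented = []
    for ann in annotations:
        strands = ann.gene_strands
        missing = [g for g in (*group_a, *group_c) if g not in strands]
        if missing:
            logger.info("%s: missing reference gene(s) %s", ann.genome_id, missing)
            continue
        sa = {strands[g] for g in group_a}
        sc = {strands[g] for g in group_c}
        if len(sa) != 1 or len(sc) != 1 or sa == sc:
            logger.info("%s: reference genes not in the expected arrangement", ann.genome_id)
            continue
        a_strand = sa.pop()
        relabeled = {
            gene: ("A" if strand == a_strand else "C")
            for gene, strand in strands.items()
        }
        oriented.append(OrientedGenome(ann.genome_id, flipped=a_strand == "-", gene_strands=relabeled))
    return oriented


def find_symmetry_genes(
    oriented: Sequence[OrientedGenome],
    presence_min: float = 0.90,
    consistency_min: float = 0.80,
) -> List[str]:
    """Genes present in >= presence_min of genomes with a consistent strand.

    Consistent means on strand A in at least ``consistency_min`` of the
    genomes annotating the gene, or in at most ``1 - consistency_min`` of
    them.  Output is sorted, hence independent of genome order.
    """
    if not oriented:
        raise ValueError("no oriented genomes")
    n = len(oriented)
    presence: Dict[str, int] = {}
    on_a: Dict[str, int] = {}
    for genome in oriented:
        for gene, strand in genome.gene_strands.items():
            presence[gene] = presence.get(gene, 0) + 1
            if strand == "A":
                on_a[gene] = on_a.get(gene, 0) + 1
    out = []
    for gene, count in presence.items():
        if count / n < presence_min:
            continue
        frac_a = on_a.get(gene, 0) / count
        if frac_a >= consistency_min or frac_a <= 1.0 - consistency_min:
            out.append(gene)
    return sorted(out)


def complementary_context_correlation(
    table: ContextCountTable, min_subs: int = 50
) -> dict:
    """Agreement of equilibrium composition between complementary contexts.

    For every complementary pair (c, rc(c)) of a strand-explicit table where
    both members have at least ``min_subs`` substitutions and non-degenerate
    stationary vectors, the stationary statistics of rc(c) are mapped back
    through complementation and correlated against those of c.  Returns the
    squared Pearson correlations for equilibrium A+T% and A-T skew plus the
    number of pairs used.  Under a strand-symmetric process both r2 approach 1
    as sample size grows.
    """
    if table.combined:
        raise ValueError("strand-symmetry test needs uncombined matrices")
    perm = rc_permutation(table.radius)
    self_mask = self_complementary_mask(table.radius)
    at_pairs: List[Tuple[float, float]] = []
    skew_pairs: List[Tuple[float, float]] = []
    n_pairs = 0
    for idx in range(table.counts.shape[0]):
        j = int(perm[idx])
        if idx >= j or self_mask[idx]:
            continue
        cm_a, cm_b = table.counts[idx], table.counts[j]
        subs_a = int(cm_a.sum() - np.trace(cm_a))
        subs_b = int(cm_b.sum() - np.trace(cm_b))
        if subs_a < min_subs or subs_b < min_subs:
            continue
        sv_a = stationary_vector(to_transition_matrix(cm_a, index_to_context(idx, table.radius)))
        sv_b = stationary_vector(to_transition_matrix(cm_b, index_to_context(j, table.radius)))
        if sv_a.degenerate or sv_b.degenerate:
            continue
        stats_a = composition_stats(sv_a.freqs)
        stats_b = composition_stats(sv_b.freqs[::-1])  # complement-mapped (A<->T, C<->G)
        n_pairs += 1
        at_pairs.append((stats_a.at_percent, stats_b.at_percent))
        if stats_a.at_skew is not None and stats_b.at_skew is not None:
            skew_pairs.append((stats_a.at_skew, stats_b.at_skew))
    if n_pairs < 2:
        raise ValueError("fewer than 2 qualifying complementary pairs")
    result = {"n_pairs": n_pairs}
    for name, pairs in (("r2_at_percent", at_pairs), ("r2_at_skew", skew_pairs)):
        if len(pairs) >= 2:
            x, y = zip(*pairs)
            try:
                result[name] = pearson_r2(x, y)
            except ValueError:
                result[name] = None
        else:
            result[name] = None
    return result
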