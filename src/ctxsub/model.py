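"""Model/Results interface tying the estimation pipeline together.

:class:`ContextSubstitutionModel` holds the aligned triplets and the
estimation settings; :meth:`fit` runs ingest -> count accumulation ->
complement combining and returns a :class:`ContextSubstitutionResults`
carrying the matrices and the derived summaries (rates and their Wald
intervals, fold variation, stationary compositions, CpG contingency,
context indices), statsmodels-style.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from . import equilibrium as eq
from . import features as ft
from .contexts import BASE_INDEX, ContextKey, index_to_context, n_canonical_contexts
from .ingest import FilterTally, TripletAlignment, count_table_from_alignments, read_triplet_alignments
from .matrices import (
    ContextCountTable,
    RateSummary,
    TransitionMatrix,
    fold_variation_table,
    rate_ci,
    rate_summaries,
    to_transition_matrix,
)
from .symmetry import complementary_context_correlation


class ContextSubstitutionModel:
    """Context-dependent substitution matrix estimator for triplet alignments.

    Parameters
    ----------
    alignments:
        Validated :class:`~ctxsub.ingest.TripletAlignment` regions.
    radius:
        Flanking bases counted on each side of a focal site (3 gives the
        hexanucleotide context).
    """

    def __init__(self, alignments: Sequence[TripletAlignment], radius: int = 3):
        if radius not in (1, 2, 3, 4):
            raise ValueError("radius must be in 1..4")
        self.alignments = list(alignments)
        self.radius = radius

    @classmethod
    def from_fasta(cls, path, radius: int = 3, min_columns: int = 70) -> "ContextSubstitutionModel":
        tally = FilterTally()
        alignments = read_triplet_alignments(path, min_columns=min_columns, tally=tally)
        model = cls(alignments, radius=radius)
        model._read_tally = tally
        return model

    def fit(self) -> "ContextSubstitutionResults":
        tally = getattr(self, "_read_tally", FilterTally())
        raw = count_table_from_alignments(self.alignments, self.radius, tally=tally)
        combined = raw.combine_complements()
        return ContextSubstitutionResults(self, raw, combined, tally)


@dataclass
class ContextSubstitutionResults:
    """Estimated context-dependent matrices and their summaries."""

    model: ContextSubstitutionModel
    raw_counts: ContextCountTable
    counts: ContextCountTable  # complement-combined
    tally: FilterTally

    @property
    def radius(self) -> int:
        return self.model.radius

    @property
    def n_records(self) -> int:
        return self.raw_counts.total()

    @property
    def n_substitutions(self) -> int:
        return self.raw_counts.n_substitutions()

    # -- matrices -------------------------------------------------------------
    def transition_matrix(self, context, combined: bool = True) -> TransitionMatrix:
        table = self.counts if combined else self.raw_counts
        key = context if isinstance(context, ContextKey) else ContextKey.from_string(str(context))
        return to_transition_matrix(table[key], key)

    # -- rates ----------------------------------------------------------------
    def rate_summaries(self) -> List[RateSummary]:
        return rate_summaries(self.counts, canonical_only=True)

    def rates_frame(self) -> pd.DataFrame:
        """Per-context pyrimidine-row rates with Wald intervals and indices."""
        rows = []
        with_indices = self.radius == 3
        for s in self.rate_summaries():
            lo, hi = rate_ci(s.total_rate, s.n_row) if s.n_row else (np.nan, np.nan)
            row = {
                "context": str(s.context),
                "from_base": s.from_base,
                "ts_rate": s.ts_rate,
                "tv_rate": s.tv_rate,
                "total_rate": s.total_rate,
                "total_rate_ci_low": lo,
                "total_rate_ci_high": hi,
                "ts_tv": np.nan if s.ts_tv is None else s.ts_tv,
                "n_ts": s.n_ts,
                "n_tv": s.n_tv,
                "n_row": s.n_row,
            }
            if with_indices:
                row["ati"] = ft.ati(s.context)
                row["ri"] = ft.ri(s.context)
                row["rati"] = ft.rati(s.context)
            rows.append(row)
        return pd.DataFrame(rows)

    def fold_variation(self, mode: str = "ts50tv50", **kwargs) -> pd.DataFrame:
        return fold_variation_table(self.rate_summaries(), mode=mode, **kwargs)

    # -- equilibrium ----------------------------------------------------------
    def equilibrium_frame(self, min_subs: int = 50):
        """Predicted-vs-observed composition table and per-statistic r2."""
        return eq.predicted_vs_observed(self.counts, min_subs=min_subs)

    # -- CpG ------------------------------------------------------------------
    def cpg(self) -> dict:
        """CpG 2x2 tables with odds ratios and heterogeneity chi-square."""
        tables = ft.cpg_tables(self.raw_counts)
        out = {}
        for label, t in (("g_to_a", tables.g_table), ("c_to_t", tables.c_table)):
            stat, p = ft.chi2_heterogeneity(t)
            out[label] = {
                "table": t,
                "odds_ratio": ft.odds_ratio(t),
                "chi2": stat,
                "p": p,
            }
        return out

    # -- strand symmetry ------------------------------------------------------
    def strand_symmetry(self, min_subs: int = 50) -> dict:
        return complementary_context_correlation(self.raw_counts, min_subs=min_subs)

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Context-dependent substitution analysis",
            "=" * 42,
            f"radius:                {self.radius} "
            f"({n_canonical_contexts(self.radius)} canonical contexts)",
            f"regions:               {len(self.model.alignments)}",
            f"columns scanned:       {self.tally.columns_scanned}",
            f"eligible sites:        {self.tally.eligible}",
            f"records (2/site):      {self.n_records}",
            f"substitutions:         {self.n_substitutions}",
        ]
        if self.tally.eligible:
            rate = self.n_substitutions / self.n_records
            lines.append(f"substitutions/record:  {rate:.4f}")
        try:
            cpg = self.cpg()
            lines.append(
                "CpG odds ratios:       "
                f"G>A {cpg['g_to_a']['odds_ratio']:.2f}, "
                f"C>T {cpg['c_to_t']['odds_ratio']:.2f}"
            )
        except ValueError:
            pass
        return "\n".join(lines)
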