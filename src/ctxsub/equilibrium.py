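"""Stationary composition of context transition matrices.

For each context's Markov matrix Pi the stationary vector phi solves
phi = phi Pi; it is the base composition a site evolving under those dynamics
approaches, and comparing it with the observed composition in the same
context tests whether extant sequences sit near their context-specific
equilibria.  Matrices with an empty row, a non-unique eigenvalue-1 eigenspace
or a zero equilibrium frequency (typical of sparse counts) are flagged
degenerate rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .contexts import ContextKey, canonical_index_mask, index_to_context
from .matrices import ContextCountTable, TransitionMatrix, to_transition_matrix

RESIDUAL_TOL = 1e-10


@dataclass
class StationaryVector:
    context: Optional[ContextKey]
    freqs: np.ndarray  # A,C,G,T; nonnegative, sums to 1 unless degenerate-empty
    degenerate: bool
    note: str = ""


@dataclass
class CompositionStats:
    """A+T percentage and signed skews of a composition, on the percent scale.

    ``gc_skew = 100*(G-C)/(G+C)`` and ``at_skew = 100*(A-T)/(A+T)``; a skew is
    None when its denominator is zero.
    """

    at_percent: float
    gc_skew: Optional[float]
    at_skew: Optional[float]


def _power_iteration(P: np.ndarray, tol: float = RESIDUAL_TOL, max_iter: int = 100000) -> np.ndarray:
    phi = np.full(4, 0.25)
    for _ in range(max_iter):
        nxt = phi @ P
        s = nxt.sum()
        if s <= 0:
            break
        nxt = nxt / s
        if np.abs(nxt - phi).max() < tol / 10:
            phi = nxt
            break
        phi = nxt
    return phi


def stationary_vector(tm: TransitionMatrix) -> StationaryVector:
    """Left eigenvector of Pi for eigenvalue 1, normalized to sum to 1.

    Eigen-decomposition with a power-iteration fallback; entries in
    (-1e-12, 0) are clipped to zero.  Degenerate outputs (empty rows,
    non-unique solutions, zero frequencies) are flagged, not dropped.
    """
    if tm.empty_rows.any():
        return StationaryVector(tm.context, np.zeros(4), True, "empty row")
    P = tm.probs
    note = ""
    vals, vecs = scipy.linalg.eig(P.T)
    order = np.argsort(np.abs(vals - 1.0))
    near_one = np.abs(vals - 1.0) < 1e-9
    if near_one.sum() > 1:
        note = "non-unique stationary solution"
    v = np.real(vecs[:, order[0]])
    s = v.sum()
    phi = v / s if abs(s) > 1e-300 else np.full(4, 0.25)
    phi = np.where((phi > -1e-12) & (phi < 0), 0.0, phi)
    residual = np.abs(phi @ P - phi).max()
    if residual > RESIDUAL_TOL or (phi < 0).any():
        phi = _power_iteration(P)
        phi = np.clip(phi, 0.0, None)
        phi = phi / phi.sum()
        residual = np.abs(phi @ P - phi).max()
        if residual > RESIDUAL_TOL:
            note = note or f"residual {residual:.2e} above tolerance"
    degenerate = bool(note) or bool(np.any(phi <= 0.0))
    if not note and np.any(phi <= 0.0):
        note = "zero equilibrium frequency"
    return StationaryVector(tm.context, phi, degenerate, note)


def composition_stats(freqs: Sequence[float]) -> CompositionStats:
    a, c, g, t = (float(x) for x in freqs)
    at = a + t
    gc = g + c
    return CompositionStats(
        at_percent=100.0 * at,
        gc_skew=100.0 * (g - c) / gc if gc > 0 else None,
        at_skew=100.0 * (a - t) / at if at > 0 else None,
    )


def observed_composition(counts: np.ndarray) -> Optional[np.ndarray]:
    """Observed focal-base frequencies from a (combined) count matrix.

    Uses the derived (ingroup) bases — the column sums — so every eligible
    site contributes its two ingroup readings, complement-folded exactly like
    the matrix itself.  Returns None for an empty matrix.
    """
    col = np.asarray(counts).sum(axis=0).astype(float)
    total = col.sum()
    if total == 0:
        return None
    return col / total


def predicted_vs_observed(
    table: ContextCountTable, min_subs: int = 50, canonical_only: bool = True
) -> tuple:
    """Per-context predicted (stationary) vs observed composition.

    Rows are (canonical) contexts with at least ``min_subs`` substitutions;
    returns ``(frame, r2)`` where ``r2`` maps each statistic (at_percent,
    gc_skew, at_skew) to the squared Pearson correlation between predicted and
    observed across non-degenerate contexts.
    """
    from .features import pearson_r2

    mask = canonical_index_mask(table.radius)
    rows = []
    for idx in range(table.counts.shape[0]):
        if canonical_only and not mask[idx]:
            continue
        cm = table.counts[idx]
        n_subs = int(cm.sum() - np.trace(cm))
        if n_subs < min_subs:
            continue
        key = index_to_context(idx, table.radius)
        sv = stationary_vector(to_transition_matrix(cm, key))
        obs = observed_composition(cm)
        pred_stats = composition_stats(sv.freqs) if sv.freqs.sum() > 0 else None
        obs_stats = composition_stats(obs) if obs is not None else None
        rows.append(
            {
                "context": str(key),
                "n_subs": n_subs,
                "n_sites": int(cm.sum()),
                "degenerate": sv.degenerate,
                "pred_A": sv.freqs[0], "pred_C": sv.freqs[1],
                "pred_G": sv.freqs[2], "pred_T": sv.freqs[3],
                "obs_A": obs[0] if obs is not None else np.nan,
                "obs_C": obs[1] if obs is not None else np.nan,
                "obs_G": obs[2] if obs is not None else np.nan,
                "obs_T": obs[3] if obs is not None else np.nan,
                "pred_at_percent": pred_stats.at_percent if pred_stats else np.nan,
                "pred_gc_skew": _opt(pred_stats.gc_skew) if pred_stats else np.nan,
                "pred_at_skew": _opt(pred_stats.at_skew) if pred_stats else np.nan,
                "obs_at_percent": obs_stats.at_percent if obs_stats else np.nan,
                "obs_gc_skew": _opt(obs_stats.gc_skew) if obs_stats else np.nan,
                "obs_at_skew": _opt(obs_stats.at_skew) if obs_stats else np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame) < 2:
        raise ValueError("fewer than 2 contexts pass min_subs")
    r2 = {}
    ok = ~frame["degenerate"]
    for stat in ("at_percent", "gc_skew", "at_skew"):
        x = frame.loc[ok, f"pred_{stat}"].to_numpy(dtype=float)
        y = frame.loc[ok, f"obs_{stat}"].to_numpy(dtype=float)
        good = np.isfinite(x) & np.isfinite(y)
        if good.sum() >= 2 and np.std(x[good]) > 0 and np.std(y[good]) > 0:
            r2[stat] = pearson_r2(x[good], y[good])
        else:
            r2[stat] = None
    return frame, r2


def _opt(v):
    return np.nan if v is None else v
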