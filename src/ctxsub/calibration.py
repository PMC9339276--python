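"""Simulation-based calibration studies: does the estimator recover truth?

Each study simulates a triplet corpus under a known context-dependent model
with the outgroup branch set to zero (so ancestral inference is exact), runs
the full ingest/counting pipeline on it, and compares the estimate with the
generating model's analytic expectation.  Problem sizes are desk-scale: large
enough that the binomial error bands are a few percent, small enough that the
whole battery runs in a few minutes on one CPU.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .contexts import BASE_INDEX
from .equilibrium import predicted_vs_observed
from .ingest import count_table_from_alignments
from .matrices import fold_variation_table, rate_summaries
from .simulate import (
    SimulationParams,
    at_bias_model,
    cpg_model,
    f81_model,
    generate_triplet_dataset,
    uniform_model,
)


def _child_seeds(seed: int, n: int) -> list:
    """Deterministic child seeds below 2**31 derived from one master seed."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def cpg_recovery_study(
    seed: int,
    n_regions: int = 100,
    region_length: int = 5000,
    k: float = 1.4,
    ingroup_branch: float = 0.05,
) -> dict:
    """Recover the CpG transition multiplier from a simulated corpus.

    Simulates under the cpg preset and estimates the ratio of the C->T rate
    in CG dinucleotides to the C->T rate elsewhere from the raw radius-1
    count table; the delta-method standard error treats the two rate
    estimates as independent binomials.
    """
    params = SimulationParams(
        n_regions=n_regions,
        region_length=region_length,
        ingroup_branch=ingroup_branch,
        outgroup_branch=0.0,
        gc_content=0.5,
        indel_rate=0.0,
        seed=seed,
    )
    aligns, _ = generate_triplet_dataset(params, cpg_model(k=k))
    raw = count_table_from_alignments(aligns, 1)
    C, T, G = BASE_INDEX["C"], BASE_INDEX["T"], BASE_INDEX["G"]
    cg = (np.arange(16) % 4) == G  # radius-1 context index = left*4 + right
    c_rows = raw.counts[:, C, :]
    n_cg, k_cg = int(c_rows[cg].sum()), int(c_rows[cg, T].sum())
    n_other, k_other = int(c_rows[~cg].sum()), int(c_rows[~cg, T].sum())
    p_cg, p_other = k_cg / n_cg, k_other / n_other
    ratio = p_cg / p_other
    se = ratio * math.sqrt((1 - p_cg) / k_cg + (1 - p_other) / k_other)
    return {
        "true_k": k,
        "ratio": ratio,
        "se": se,
        "z": (ratio - k) / se,
        "n_records": raw.total(),
        "n_cg_transitions": k_cg,
        "n_other_transitions": k_other,
    }


def _uniform_folds(seed: int, n_regions: int, region_length: int, branch: float) -> dict:
    params = SimulationParams(
        n_regions=n_regions,
        region_length=region_length,
        ingroup_branch=branch,
        outgroup_branch=0.0,
        gc_content=0.5,
        indel_rate=0.0,
        seed=seed,
    )
    aligns, _ = generate_triplet_dataset(params, uniform_model())
    table = count_table_from_alignments(aligns, 1).combine_complements()
    summaries = rate_summaries(table)
    folds = fold_variation_table(summaries, mode="ts50tv50")
    pick = lambda stat: float(
        folds[(folds.statistic == stat) & (folds["from"] == "T+C")].fold.iloc[0]
    )
    return {
        "summaries": summaries,
        "fold_total_rate": pick("total_rate"),
        "fold_ts_tv": pick("ts_tv"),
        "n_records": table.canonical_counts().sum(),
    }


def uniform_rate_study(
    seed: int,
    n_regions: int = 100,
    region_length: int = 5000,
    branch: float = 0.10,
    n_replicates: int = 20,
) -> dict:
    """Ts:Tv and fold-variation of a context-free process, with a sampling
    envelope.

    Under the uniform preset every context shares one rate matrix with one
    transition and two transversions per base, so the pooled Ts:Tv is 0.5 at
    any divergence and any apparent fold-variation across contexts is
    sampling noise.  The study runs one primary simulation plus
    ``n_replicates`` at identical parameters; the replicate folds form the
    envelope the primary fold is judged against.
    """
    seeds = _child_seeds(seed, n_replicates + 1)
    main = _uniform_folds(seeds[0], n_regions, region_length, branch)
    n_ts = sum(s.n_ts for s in main["summaries"])
    n_tv = sum(s.n_tv for s in main["summaries"])
    ratio = n_ts / n_tv
    se = ratio * math.sqrt(1 / n_ts + 1 / n_tv)
    env_total, env_tstv = [], []
    for rs in seeds[1:]:
        rep = _uniform_folds(rs, n_regions, region_length, branch)
        env_total.append(rep["fold_total_rate"])
        env_tstv.append(rep["fold_ts_tv"])
    return {
        "ts_tv": ratio,
        "ts_tv_se": se,
        "ts_tv_z": (ratio - 0.5) / se,
        "n_ts": n_ts,
        "n_tv": n_tv,
        "fold_total_rate": main["fold_total_rate"],
        "fold_ts_tv": main["fold_ts_tv"],
        "envelope_total_rate": (min(env_total), max(env_total)),
        "envelope_ts_tv": (min(env_tstv), max(env_tstv)),
        "n_replicates": n_replicates,
        "n_records": int(main["n_records"]),
    }


def stationary_composition_study(
    seed: int,
    n_regions: int = 30,
    region_length: int = 2000,
    branch: float = 0.10,
    base_freqs=(0.40, 0.20, 0.10, 0.30),
) -> dict:
    """Observed per-context composition against a known analytic equilibrium.

    Simulates a context-independent F81 process from an i.i.d. stationary
    start, then compares the observed focal-base frequencies in every
    radius-1 context with the analytic stationary distribution, as z-scores
    with binomial standard errors on the site count (the two ingroup records
    per site are correlated, so records/2 is the effective sample size).
    """
    pi = np.asarray(base_freqs, dtype=float)
    params = SimulationParams(
        n_regions=n_regions,
        region_length=region_length,
        ingroup_branch=branch,
        outgroup_branch=0.0,
        gc_content=0.5,
        indel_rate=0.0,
        seed=seed,
    )
    aligns, _ = generate_triplet_dataset(params, f81_model(base_freqs=tuple(pi)))
    raw = count_table_from_alignments(aligns, 1)
    zs = []
    for i in range(raw.counts.shape[0]):
        cm = raw.counts[i]
        n_rec = cm.sum()
        if n_rec == 0:
            continue
        obs = cm.sum(axis=0) / n_rec
        n_sites = n_rec / 2
        for b in range(4):
            se = math.sqrt(pi[b] * (1 - pi[b]) / n_sites)
            zs.append((obs[b] - pi[b]) / se)
    zs = np.abs(np.asarray(zs))
    return {
        "n_cells": len(zs),
        "max_abs_z": float(zs.max()),
        "frac_beyond_3se": float(np.mean(zs > 3.0)),
        "n_records": raw.total(),
    }


def equilibrium_agreement_study(
    seed: int,
    n_regions: int = 30,
    region_length: int = 2000,
    branch: float = 0.15,
    s: float = 3.0,
    burn_in: float = 6.0,
    min_subs: int = 50,
) -> dict:
    """Predicted-vs-observed equilibrium under context-dependent dynamics.

    The at_bias preset makes equilibrium A+T content rise with flanking A+T.
    A burn-in branch brings the root sequences near their context-specific
    equilibria before the triplet is simulated, emulating sequences that have
    long evolved under their own dynamics; the squared correlation between
    the stationary predictions of the estimated matrices and the observed
    compositions then measures how well the equilibrium machinery works at
    this sample size.
    """
    params = SimulationParams(
        n_regions=n_regions,
        region_length=region_length,
        ingroup_branch=branch,
        outgroup_branch=0.0,
        gc_content=0.5,
        indel_rate=0.0,
        seed=seed,
        burn_in=burn_in,
    )
    aligns, _ = generate_triplet_dataset(params, at_bias_model(radius=1, s=s))
    table = count_table_from_alignments(aligns, 1).combine_complements()
    frame, r2 = predicted_vs_observed(table, min_subs=min_subs)
    return {
        "n_contexts": len(frame),
        "r2_at_percent": r2["at_percent"],
        "predicted_at_range": (
            float(frame.pred_at_percent.min()),
            float(frame.pred_at_percent.max()),
        ),
        "observed_at_range": (
            float(frame.obs_at_percent.min()),
            float(frame.obs_at_percent.max()),
        ),
        "n_records": int(table.canonical_counts().sum()),
    }
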