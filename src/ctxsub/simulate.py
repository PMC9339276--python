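"""Synthetic triplet alignments from context-dependent sequence evolution.

Sequences evolve under a continuous-time Markov process whose per-site
substitution rates may depend on the flanking bases, simulated exactly with
the Gillespie algorithm: after every event the contexts (and hence rates) of
the neighbors within the model radius are refreshed.  Sites within one radius
of either sequence end have undefined context and never mutate.  Branch
lengths are in expected substitutions/site under the uniform reference rate
(total per-site rate 1), so small branches give approximately that many
substitutions per site.

A dataset of independent noncoding regions is produced on a 3-taxon tree:
ancestor -> outgroup, and ancestor -> two independent ingroup branches
(star-like ingroup), with optional geometric-length indels on the ingroups;
the emitted alignment is the true one, known by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .contexts import BASES, ContextKey, index_to_context, n_contexts
from .ingest import TripletAlignment

RateFn = Callable[[str, str, str, str], float]


@dataclass
class ContextRateModel:
    """Ground-truth mapping from flanking context to a 4x4 rate matrix.

    ``rate_fn(left, right, current, target)`` returns the nonnegative rate of
    ``current -> target`` in the given context, per unit branch time; the
    diagonal is implied and never queried.
    """

    radius: int
    rate_fn: RateFn
    name: str = "custom"

    def __post_init__(self) -> None:
        if not 1 <= self.radius <= 4:
            raise ValueError("radius must be in 1..4")
        self._lut: Optional[np.ndarray] = None

    def rate_lut(self) -> np.ndarray:
        """Dense (4^(2r), 4, 4) rate table with zero diagonal (cached)."""
        if self._lut is None:
            nc = n_contexts(self.radius)
            lut = np.zeros((nc, 4, 4))
            for idx in range(nc):
                key = index_to_context(idx, self.radius)
                for i, cur in enumerate(BASES):
                    for j, tgt in enumerate(BASES):
                        if i != j:
                            rate = float(self.rate_fn(key.left, key.right, cur, tgt))
                            if rate < 0:
                                raise ValueError(
                                    f"negative rate for {cur}->{tgt} in {key}"
                                )
                            lut[idx, i, j] = rate
            self._lut = lut
        return self._lut

    def stationary_lut(self) -> np.ndarray:
        """Analytic per-context stationary distribution of the rate matrices.

        Treats each context as fixed (valid exactly for context-independent
        models; an approximation otherwise).
        """
        from .equilibrium import stationary_vector
        from .matrices import TransitionMatrix

        lut = self.rate_lut()
        out = np.zeros((lut.shape[0], 4))
        for idx in range(lut.shape[0]):
            q = lut[idx].copy()
            np.fill_diagonal(q, 0.0)
            scale = q.sum(axis=1).max()
            p = q / (2.0 * scale)  # uniformized chain shares the stationary vector
            np.fill_diagonal(p, 1.0 - p.sum(axis=1))
            tm = TransitionMatrix(
                context=index_to_context(idx, self.radius),
                probs=p,
                row_n=np.full(4, 1, dtype=np.int64),
            )
            out[idx] = stationary_vector(tm).freqs
        return out


@dataclass
class SimulationParams:
    """Study conditions for a synthetic triplet dataset.

    Defaults emulate the corpus the estimator targets: many independent
    intergenic alignments comfortably over 70 nt, ~0.066 substitutions/site
    between the two ingroups (0.033 per ingroup branch), a more diverged
    outgroup, A+T-rich composition, and occasional short indels.
    """

    n_regions: int = 280
    region_length: int = 300
    ingroup_branch: float = 0.033
    outgroup_branch: float = 0.05
    gc_content: float = 0.35
    indel_rate: float = 0.002
    seed: int = 0
    #: extra branch applied to the ancestor before the triplet, to bring the
    #: root sequence near the model's own stationary composition
    burn_in: float = 0.0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.region_length < 1:
            raise ValueError("n_regions and region_length must be positive")
        if self.ingroup_branch < 0 or self.outgroup_branch < 0 or self.burn_in < 0:
            raise ValueError("branch lengths must be nonnegative")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be nonnegative")


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _uniform_fn(mu: float) -> RateFn:
    rate = mu / 3.0

    def fn(left: str, right: str, cur: str, tgt: str) -> float:
        return rate

    return fn


def uniform_model(radius: int = 1, mu: float = 1.0) -> ContextRateModel:
    """All 12 changes at equal rate mu/3 in every context (total rate mu/site)."""
    return ContextRateModel(radius, _uniform_fn(mu), name="uniform")


def cpg_model(radius: int = 1, k: float = 1.4, mu: float = 1.0) -> ContextRateModel:
    """CpG-elevated transitions: C->T with a 3' G, and G->A with a 5' C, x k."""

    base = mu / 3.0

    def fn(left: str, right: str, cur: str, tgt: str) -> float:
        if tgt == _TS_PARTNER[cur]:
            if (cur == "C" and tgt == "T" and right[0] == "G") or (
                cur == "G" and tgt == "A" and left[-1] == "C"
            ):
                return base * k
        return base

    return ContextRateModel(radius, fn, name="cpg")


def ati_tv_model(slope: float = 0.05, mu: float = 1.0) -> ContextRateModel:
    """Transversion rate scaled linearly in the ATI of the flanking context.

    The multiplier is ``1 + slope * ATI``, so the Tv rate in an ATI = 28
    context is ``(1 + 28 * slope)`` times that in an ATI = 0 context; the
    transition rate is context independent.  Radius is fixed at 3 (the ATI is
    a hexanucleotide statistic).
    """
    from .features import ati

    base = mu / 3.0

    def fn(left: str, right: str, cur: str, tgt: str) -> float:
        if tgt == _TS_PARTNER[cur]:
            return base
        return base * (1.0 + slope * ati(ContextKey(left, right)))

    return ContextRateModel(3, fn, name="ati_tv")


def at_bias_model(radius: int = 2, s: float = 3.0, mu: float = 1.0) -> ContextRateModel:
    """Transitions toward A/T scaled by flanking A+T fraction.

    C->T and G->A run at ``(1 + s*w)`` times the base transition rate, where w
    is the A+T fraction of the 2r flanking bases, so equilibrium A+T content
    rises smoothly with flanking A+T — a minimal generator of the
    context-dependent equilibrium heterogeneity the estimator measures.
    """
    base = mu / 3.0

    def fn(left: str, right: str, cur: str, tgt: str) -> float:
        if (cur, tgt) in (("C", "T"), ("G", "A")):
            ctx = left + right
            w = sum(1 for b in ctx if b in "AT") / len(ctx)
            return base * (1.0 + s * w)
        return base

    return ContextRateModel(radius, fn, name="at_bias")


def f81_model(
    base_freqs: Sequence[float] = (0.35, 0.15, 0.15, 0.35), radius: int = 1, mu: float = 1.0
) -> ContextRateModel:
    """Context-independent F81 process: rate(i->j) proportional to pi_j.

    Its stationary distribution is ``base_freqs`` (A,C,G,T order) for every
    context, and an i.i.d. draw from ``base_freqs`` is a stationary start.
    """
    pi = np.asarray(base_freqs, dtype=float)
    if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0) or (pi <= 0).any():
        raise ValueError("base_freqs must be 4 positive values summing to 1")
    # scale so the mean total leave rate under pi is mu
    scale = mu / float(sum(pi[i] * (1.0 - pi[i]) for i in range(4)))

    def fn(left: str, right: str, cur: str, tgt: str) -> float:
        return scale * pi["ACGT".index(tgt)]

    model = ContextRateModel(radius, fn, name="f81")
    model.base_freqs = pi  # type: ignore[attr-defined]
    return model


_BUILTINS: Dict[str, Callable[..., ContextRateModel]] = {
    "uniform": uniform_model,
    "cpg": cpg_model,
    "ati_tv": ati_tv_model,
    "at_bias": at_bias_model,
    "f81": f81_model,
}


def builtin_models() -> Dict[str, Callable[..., ContextRateModel]]:
    """Named preset factories ('uniform', 'cpg', 'ati_tv', 'at_bias', 'f81')."""
    return dict(_BUILTINS)


def get_model(name: str, **kwargs) -> ContextRateModel:
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise ValueError(f"unknown model preset {name!r}; choose from {sorted(_BUILTINS)}")
    return factory(**kwargs)


# ---------------------------------------------------------------------------
# Sequence generation and evolution
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_ancestor(
    length: int,
    gc_content: float = 0.5,
    seed=0,
    base_freqs: Optional[Sequence[float]] = None,
) -> str:
    """I.i.d. random sequence with the given G+C fraction (or explicit freqs)."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = _as_rng(seed)
    if base_freqs is None:
        at = (1.0 - gc_content) / 2.0
        gc = gc_content / 2.0
        base_freqs = (at, gc, gc, at)
    p = np.asarray(base_freqs, dtype=float)
    codes = rng.choice(4, size=length, p=p / p.sum())
    return "".join(BASES[c] for c in codes)


def _context_indices(codes: np.ndarray, radius: int) -> np.ndarray:
    """Context index for every active site (radius .. L-radius-1)."""
    L = len(codes)
    active = L - 2 * radius
    idx = np.zeros(active, dtype=np.int64)
    weight = 2 * radius - 1
    for d in range(radius, 0, -1):  # left bases, far to near
        idx += codes[radius - d : radius - d + active].astype(np.int64) * 4**weight
        weight -= 1
    for d in range(1, radius + 1):  # right bases, near to far
        idx += codes[radius + d : radius + d + active].astype(np.int64) * 4**weight
        weight -= 1
    return idx


def evolve_sequence(seq: str, model: ContextRateModel, branch: float, seed=0) -> str:
    """Evolve a sequence for one branch; returns the descendant sequence."""
    if branch < 0:
        raise ValueError("branch must be nonnegative")
    r = model.radius
    if len(seq) <= 2 * r:
        raise ValueError(f"sequence length {len(seq)} must exceed 2*radius ({2 * r})")
    codes = np.array([BASES.index(b) for b in seq], dtype=np.int8)
    _evolve_codes(codes, model, branch, _as_rng(seed))
    return "".join(BASES[c] for c in codes)


def _evolve_codes(
    codes: np.ndarray, model: ContextRateModel, branch: float, rng: np.random.Generator
) -> int:
    """In-place Gillespie evolution; returns the number of substitutions."""
    if branch == 0:
        return 0
    r = model.radius
    lut = model.rate_lut()
    row_rate = lut.sum(axis=2)  # (contexts, 4): total leave rate per current base
    L = len(codes)
    active = L - 2 * r  # sites with a complete context
    if active <= 0:
        return 0
    ctx = _context_indices(codes, r)
    cur = codes[r : L - r].astype(np.int64)
    site_rate = row_rate[ctx, cur]
    n_events = 0
    t = 0.0
    while True:
        total = site_rate.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > branch:
            break
        cum = np.cumsum(site_rate)
        j = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        j = min(j, active - 1)
        rates = lut[ctx[j], codes[r + j]]
        target = int(rng.choice(4, p=rates / rates.sum()))
        codes[r + j] = target
        n_events += 1
        # refresh context and rate of the neighbors within radius
        lo = max(0, j - r)
        hi = min(active - 1, j + r)
        for i in range(lo, hi + 1):
            pos = r + i
            left = codes[pos - r : pos].astype(np.int64)
            right = codes[pos + 1 : pos + 1 + r].astype(np.int64)
            idx = 0
            for v in left:
                idx = idx * 4 + int(v)
            for v in right:
                idx = idx * 4 + int(v)
            ctx[i] = idx
            site_rate[i] = row_rate[idx, codes[pos]]
    return n_events


# ---------------------------------------------------------------------------
# Indels and triplet assembly
# ---------------------------------------------------------------------------


def _draw_indels(length: int, rate: float, rng: np.random.Generator) -> list:
    """Indel events as (position, kind, payload); geometric lengths, mean 2."""
    events = []
    n = rng.poisson(rate * length) if rate > 0 else 0
    for _ in range(n):
        pos = int(rng.integers(0, length))
        size = int(rng.geometric(0.5))
        if rng.random() < 0.5:
            events.append((pos, "del", size))
        else:
            bases = "".join(BASES[c] for c in rng.integers(0, 4, size=size))
            events.append((pos, "ins", bases))
    return events


def _apply_indels_aligned(
    outgroup: str, in1: str, in2: str, events1: list, events2: list
) -> tuple:
    """Build gapped alignment rows from per-ingroup indel event lists."""
    L = len(outgroup)
    rows = {"out": list(outgroup), "in1": list(in1), "in2": list(in2)}
    inserts: Dict[int, Dict[str, str]] = {}
    for name, events in (("in1", events1), ("in2", events2)):
        for pos, kind, payload in events:
            if kind == "del":
                for p in range(pos, min(L, pos + payload)):
                    rows[name][p] = "-"
            else:
                inserts.setdefault(pos, {}).setdefault(name, "")
                inserts[pos][name] += payload
    out_parts, in1_parts, in2_parts = [], [], []
    for p in range(L):
        out_parts.append(rows["out"][p])
        in1_parts.append(rows["in1"][p])
        in2_parts.append(rows["in2"][p])
        if p in inserts:
            for name, bases in sorted(inserts[p].items()):
                gap = "-" * len(bases)
                out_parts.append(gap)
                in1_parts.append(bases if name == "in1" else gap)
                in2_parts.append(bases if name == "in2" else gap)
    return "".join(out_parts), "".join(in1_parts), "".join(in2_parts)


def generate_triplet_dataset(
    params: SimulationParams, model: ContextRateModel
) -> tuple:
    """Simulate a dataset of triplet alignments with known ground truth.

    Returns ``(alignments, truth)`` where ``truth`` records the model name,
    parameters and per-region substitution/indel event counts.  Per-region
    random streams are spawned deterministically from the master seed, so
    identical parameters give identical datasets.
    """
    master = np.random.SeedSequence(params.seed)
    streams = master.spawn(params.n_regions)
    alignments: List[TripletAlignment] = []
    truth = {
        "model": model.name,
        "radius": model.radius,
        "params": asdict(params),
        "regions": [],
    }
    base_freqs = getattr(model, "base_freqs", None)
    for k in range(params.n_regions):
        rng = np.random.default_rng(streams[k])
        ancestor = generate_ancestor(
            params.region_length, params.gc_content, rng, base_freqs=base_freqs
        )
        anc_codes = np.array([BASES.index(b) for b in ancestor], dtype=np.int8)
        if params.burn_in > 0:
            _evolve_codes(anc_codes, model, params.burn_in, rng)
        out_codes = anc_codes.copy()
        n_out = _evolve_codes(out_codes, model, params.outgroup_branch, rng)
        in1_codes = anc_codes.copy()
        n_in1 = _evolve_codes(in1_codes, model, params.ingroup_branch, rng)
        in2_codes = anc_codes.copy()
        n_in2 = _evolve_codes(in2_codes, model, params.ingroup_branch, rng)
        out_s = "".join(BASES[c] for c in out_codes)
        in1_s = "".join(BASES[c] for c in in1_codes)
        in2_s = "".join(BASES[c] for c in in2_codes)
        ev1 = _draw_indels(len(in1_s), params.indel_rate, rng)
        ev2 = _draw_indels(len(in2_s), params.indel_rate, rng)
        out_s, in1_s, in2_s = _apply_indels_aligned(out_s, in1_s, in2_s, ev1, ev2)
        region_id = f"region{k}"
        alignments.append(TripletAlignment(region_id, in1_s, in2_s, out_s))
        truth["regions"].append(
            {
                "region_id": region_id,
                "substitutions": {"outgroup": n_out, "ingroup1": n_in1, "ingroup2": n_in2},
                "indels": {"ingroup1": len(ev1), "ingroup2": len(ev2)},
            }
        )
    return alignments, truth


def write_dataset(alignments: Sequence[TripletAlignment], truth: dict, out_dir) -> None:
    """One multi-FASTA per region plus a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for trip in alignments:
        with open(out / f"{trip.region_id}.fasta", "w") as fh:
            for role, seq in (
                ("ingroup1", trip.ingroup1),
                ("ingroup2", trip.ingroup2),
                ("outgroup", trip.outgroup),
            ):
                fh.write(f">{trip.region_id}|{role}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
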