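"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pytest

from ctxsub.ingest import TripletAlignment
from ctxsub.simulate import SimulationParams, generate_triplet_dataset, get_model


def make_triplet(outgroup, ingroup1, ingroup2, region_id="r0"):
    return TripletAlignment(region_id, ingroup1, ingroup2, outgroup)


@pytest.fixture
def identical_triplet():
    """Gap-free identical triplet: every interior column is eligible."""
    seq = "ACGTACGTACGTACGTACGTACGT"  # 24 columns
    return make_triplet(seq, seq, seq)


@pytest.fixture(scope="session")
def uniform_dataset():
    """Moderate uniform-model simulation with exact ancestral inference."""
    params = SimulationParams(
        n_regions=30,
        region_length=1000,
        ingroup_branch=0.05,
        outgroup_branch=0.0,
        gc_content=0.5,
        indel_rate=0.0,
        seed=11,
    )
    return generate_triplet_dataset(params, get_model("uniform"))


@pytest.fixture(scope="session")
def gappy_dataset():
    """Simulation with indels, exercising the gap filters."""
    params = SimulationParams(
        n_regions=10,
        region_length=400,
        ingroup_branch=0.05,
        outgroup_branch=0.05,
        gc_content=0.4,
        indel_rate=0.01,
        seed=5,
    )
    return generate_triplet_dataset(params, get_model("uniform"))


@pytest.fixture
def random_gappy_triplets():
    """Small random alignments with gaps for oracle comparisons."""
    rng = np.random.default_rng(42)
    alphabet = np.array(list("ACGT-N"))
    probs = [0.22, 0.22, 0.22, 0.22, 0.08, 0.04]
    out = []
    for k in range(8):
        L = int(rng.integers(75, 120))
        base = rng.choice(alphabet, size=L, p=probs)
        seqs = []
        for _ in range(3):
            seq = base.copy()
            flip = rng.random(L) < 0.1
            seq[flip] = rng.choice(alphabet, size=int(flip.sum()), p=probs)
            seqs.append("".join(seq))
        out.append(TripletAlignment(f"rand{k}", seqs[0], seqs[1], seqs[2]))
    return out
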