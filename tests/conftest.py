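from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dmrkit import Methylome, SimParams, generate_genome, generate_methylome_pair
from dmrkit.simulate import sample_truth_regions


def build_methylome(rows, sample_id="sample", chrom_lengths=None) -> Methylome:
    """Methylome from (chrom, pos, strand, context, n_meth, n_unmeth) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )
    return Methylome(sample_id=sample_id, sites=df,
                     chrom_lengths=dict(chrom_lengths or {}))


@pytest.fixture
def make_methylome():
    return build_methylome


def uniform_cg_pair(level_a=0.05, level_b_inside=0.9, region=(200, 400),
                    length=1000, spacing=25, coverage=20):
    """Deterministic toy pair: CG sites every ``spacing`` bp at fixed counts;
    sample B's level switches to ``level_b_inside`` within ``region``."""
    rows_a, rows_b = [], []
    for pos0 in range(0, length, spacing):
        ma = round(level_a * coverage)
        rows_a.append(("Chr1", pos0 + 1, "+", "CG", ma, coverage - ma))
        inside = region[0] <= pos0 < region[1]
        mb = round((level_b_inside if inside else level_a) * coverage)
        rows_b.append(("Chr1", pos0 + 1, "+", "CG", mb, coverage - mb))
    lengths = {"Chr1": length}
    return (build_methylome(rows_a, "wt", lengths),
            build_methylome(rows_b, "mut", lengths))


@pytest.fixture
def toy_pair():
    return uniform_cg_pair()


@pytest.fixture(scope="session")
def small_simulation():
    """A seeded 200 kb two-genotype simulation with four strong hyper
    implants, shared across tests that need realistic data."""
    params = SimParams(chrom_lengths={"Chr1": 200_000}, n_genes=30, n_tes=30,
                       seed=11)
    rng = np.random.default_rng(11)
    sequences, features = generate_genome(params, rng)
    truth = sample_truth_regions(sequences, n=4, length=400, level_b=0.9,
                                 level_a=0.05, min_cg_sites=10, rng=rng)
    meth_a, meth_b, truth = generate_methylome_pair(
        sequences, features, params, truth, rng
    )
    return {
        "params": params, "sequences": sequences, "features": features,
        "truth": truth, "meth_a": meth_a, "meth_b": meth_b,
    }
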