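"""Seeded end-to-end experiments: simulate a methylome pair, call DMRs,
score recovery against the implanted truth.

These wrappers fix the study conditions used throughout the package's
validation: a 1 Mb chromosome at 20× mean coverage with 400 bp implanted
regions shifting methylation from 0.05 to 0.9 across all contexts, called
with the default parameters.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .caller import CallResult, DmrCallParams, call_dmrs_full
from .simulate import (RecoveryReport, SimParams, evaluate_recovery,
                       generate_genome, generate_methylome_pair,
                       sample_truth_regions)


def recovery_experiment(seed: int,
                        chrom_length: int = 1_000_000,
                        mean_coverage: float = 20.0,
                        n_regions: int = 10,
                        region_length: int = 400,
                        level_a: float | None = 0.05,
                        level_b: float = 0.9,
                        direction: str = "hyper",
                        min_cg_sites: int = 10,
                        call_params: DmrCallParams | None = None,
                        sim_params: SimParams | None = None,
                        ) -> tuple[RecoveryReport, CallResult, list]:
    """One full simulate → call → score run under a single seed.

    With ``n_regions=0`` this is a null run (both genotypes drawn from the
    same model); any called DMR is then a false positive.
    """
    params = sim_params or SimParams(chrom_lengths={"Chr1": chrom_length},
                                     mean_coverage=mean_coverage, seed=seed)
    if sim_params is not None:
        params = replace(params, seed=seed)
    rng = np.random.default_rng(seed)
    sequences, features = generate_genome(params, rng)
    truth = []
    if n_regions:
        truth = sample_truth_regions(
            sequences, n=n_regions, length=region_length, level_b=level_b,
            level_a=level_a, direction=direction,
            min_cg_sites=min_cg_sites, rng=rng,
        )
    meth_a, meth_b, truth = generate_methylome_pair(
        sequences, features, params, truth, rng
    )
    result = call_dmrs_full(meth_a, meth_b, call_params)
    report = evaluate_recovery(result.dmrs, truth)
    return report, result, truth
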