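"""Synthetic two-genotype methylomes with implanted DMRs and truth records.

The generator emulates the structure of a plant (Arabidopsis-like) methylome
at desk scale: a random genome with gene and TE annotations, cytosine
contexts derived from the sequence, feature-class-dependent base methylation
(dense CG/CHG/CHH methylation on TEs, CG-only gene-body methylation, low
intergenic methylation), beta-distributed site-level methylation around the
class base (overdispersion), Poisson read coverage and binomial methylated
counts. Differential regions are implanted by overriding the latent
methylation level of sample B (and optionally sample A) inside requested
truth regions, which are returned as the reference for recovery scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import CONTEXTS, FeatureSet, Methylome, assign_contexts

DEFAULT_BASE_LEVELS = {
    ("TE", "CG"): 0.85,
    ("TE", "CHG"): 0.60,
    ("TE", "CHH"): 0.15,
    ("gene_body", "CG"): 0.30,
    ("gene_body", "CHG"): 0.02,
    ("gene_body", "CHH"): 0.02,
    ("intergenic", "CG"): 0.10,
    ("intergenic", "CHG"): 0.02,
    ("intergenic", "CHH"): 0.02,
}


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the simulator.

    ``dispersion_k`` is the beta precision: site latent levels are drawn
    from Beta(p·k, (1−p)·k) around the class base level p, so smaller k
    means noisier sites. ``base_levels`` maps (feature class, context) to p.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"Chr1": 1_000_000}
    )
    gc_fraction: float = 0.36
    n_genes: int = 150
    gene_length_range: tuple = (1000, 3000)
    n_tes: int = 150
    te_length_range: tuple = (200, 2000)
    te_in_gene_fraction: float = 0.1
    mean_coverage: float = 20.0
    dispersion_k: float = 50.0
    base_levels: Mapping = field(default_factory=lambda: dict(DEFAULT_BASE_LEVELS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.dispersion_k <= 0:
            raise ValueError("dispersion_k must be positive")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be non-negative")
        if any(not 0 <= p <= 1 for p in self.base_levels.values()):
            raise ValueError("base levels are probabilities")
        if not 0 <= self.te_in_gene_fraction <= 1:
            raise ValueError("te_in_gene_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TruthRegion:
    """An implanted differential region (the simulator's ground truth).

    ``level_b`` replaces the latent methylation base inside the region in
    sample B for the affected contexts; ``level_a``, when given, pins sample
    A's level there too (otherwise A keeps its feature-class base and the
    realized class-average is recorded on output).
    """

    chrom: str
    start: int
    end: int
    direction: str
    level_b: float
    level_a: float | None = None
    contexts: tuple = CONTEXTS

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError("need 0 <= start < end")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be hyper or hypo")
        if not 0 <= self.level_b <= 1:
            raise ValueError("level_b must lie in [0, 1]")


@dataclass
class RecoveryReport:
    """Scores called DMRs against implanted truth regions."""

    n_truth: int
    n_called: int
    n_truth_matched: int
    n_called_matched: int
    rule: str

    @property
    def recall(self) -> float:
        return self.n_truth_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return (self.n_called_matched / self.n_called
                if self.n_called else float("nan"))

    @property
    def precision_defined(self) -> bool:
        return self.n_called > 0

    @property
    def f1(self) -> float:
        p = self.precision if self.precision_defined else 0.0
        r = self.recall
        if math.isnan(r) or p + r == 0:
            return 0.0
        return 2 * p * r / (p + r)


# -- genome and annotation generation ---------------------------------------


def _place_nonoverlapping(rng: np.random.Generator, occupied: dict,
                          chrom_lengths: Mapping[str, int], length: int,
                          max_tries: int = 2000) -> tuple[str, int]:
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        limit = chrom_lengths[chrom] - length
        if limit < 0:
            continue
        start = int(rng.integers(0, limit + 1))
        if not occupied[chrom].overlap(start, start + length):
            return chrom, start
    raise ValueError(
        "could not place a feature without overlap; genome too crowded"
    )


def generate_genome(params: SimParams,
                    rng: np.random.Generator | None = None
                    ) -> tuple[dict, FeatureSet]:
    """Random genome at the requested GC fraction with non-overlapping gene
    and TE annotations; a configurable fraction of TEs is nested in genes."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    at = (1 - params.gc_fraction) / 2
    gc = params.gc_fraction / 2
    sequences = {}
    for chrom in sorted(params.chrom_lengths):
        length = params.chrom_lengths[chrom]
        bases = rng.choice(
            np.frombuffer(b"ACGT", dtype=np.uint8), size=length,
            p=[at, gc, gc, at],
        )
        sequences[chrom] = bases.tobytes().decode("ascii")

    occupied = {c: IntervalTree() for c in params.chrom_lengths}
    genes = []
    for i in range(params.n_genes):
        glen = int(rng.integers(*params.gene_length_range))
        chrom, start = _place_nonoverlapping(rng, occupied,
                                             params.chrom_lengths, glen)
        occupied[chrom].addi(start, start + glen)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((chrom, start, start + glen, strand, f"gene_{i:04d}"))

    te_occupied = {c: IntervalTree() for c in params.chrom_lengths}
    tes = []
    for i in range(params.n_tes):
        tlen = int(rng.integers(*params.te_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        if genes and rng.random() < params.te_in_gene_fraction:
            # nest inside a random gene wide enough to hold it
            order = rng.permutation(len(genes))
            placed = False
            for gi in order:
                gchrom, gstart, gend = genes[gi][0], genes[gi][1], genes[gi][2]
                if gend - gstart <= tlen:
                    continue
                start = int(rng.integers(gstart, gend - tlen + 1))
                if not te_occupied[gchrom].overlap(start, start + tlen):
                    te_occupied[gchrom].addi(start, start + tlen)
                    tes.append((gchrom, start, start + tlen, strand,
                                f"te_{i:04d}"))
                    placed = True
                    break
            if placed:
                continue
        both = {
            c: occupied[c] | te_occupied[c] for c in params.chrom_lengths
        }
        chrom, start = _place_nonoverlapping(rng, both,
                                             params.chrom_lengths, tlen)
        te_occupied[chrom].addi(start, start + tlen)
        tes.append((chrom, start, start + tlen, strand, f"te_{i:04d}"))

    cols = ["chrom", "start", "end", "strand", "id"]
    features = FeatureSet(
        genes=pd.DataFrame(genes, columns=cols) if genes else None,
        tes=pd.DataFrame(tes, columns=cols) if tes else None,
    )
    return sequences, features


# -- methylome generation ---------------------------------------------------


def _feature_class_masks(features: FeatureSet,
                         chrom_lengths: Mapping[str, int]) -> dict:
    """Per chromosome, an int8 array: 2 = TE, 1 = gene body, 0 = intergenic
    (TE wins where a TE is nested in a gene)."""
    masks = {c: np.zeros(length, dtype=np.int8)
             for c, length in chrom_lengths.items()}
    for r in features.genes.itertuples(index=False):
        if r.chrom in masks:
            masks[r.chrom][r.start:r.end] = np.maximum(
                masks[r.chrom][r.start:r.end], 1
            )
    for r in features.tes.itertuples(index=False):
        if r.chrom in masks:
            masks[r.chrom][r.start:r.end] = 2
    return masks


_CLASS_NAMES = {0: "intergenic", 1: "gene_body", 2: "TE"}


def _latent_levels(rng: np.random.Generator, p: np.ndarray,
                   k: float) -> np.ndarray:
    """Beta(p·k, (1−p)·k) draws; degenerate p of 0 or 1 stays deterministic."""
    latent = np.empty_like(p)
    mid = (p > 0) & (p < 1)
    latent[p <= 0] = 0.0
    latent[p >= 1] = 1.0
    if mid.any():
        latent[mid] = rng.beta(p[mid] * k, (1 - p[mid]) * k)
    return latent


def generate_methylome_pair(sequences: Mapping[str, str],
                            features: FeatureSet,
                            params: SimParams,
                            truth_spec: Sequence[TruthRegion] = (),
                            rng: np.random.Generator | None = None,
                            ) -> tuple[Methylome, Methylome, list[TruthRegion]]:
    """Draw a pair of per-cytosine count tables over one genome.

    Sample A is the wild-type-like baseline; truth regions override sample
    B's latent level (and A's, when ``level_a`` is given). Both samples
    share site positions; per-site coverage is Poisson around
    ``mean_coverage`` independently per sample.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    chrom_lengths = {c: len(sequences[c]) for c in sorted(sequences)}
    for t in truth_spec:
        if t.chrom not in chrom_lengths or t.end > chrom_lengths[t.chrom]:
            raise ValueError(f"truth region outside genome: {t}")
    for i, t1 in enumerate(truth_spec):
        for t2 in truth_spec[i + 1:]:
            if (t1.chrom == t2.chrom and t1.start < t2.end
                    and t2.start < t1.end):
                raise ValueError("truth regions must not overlap")

    contexts = assign_contexts(sequences)
    masks = _feature_class_masks(features, chrom_lengths)

    pos0 = contexts["pos"].to_numpy() - 1
    klass = np.concatenate([
        masks[c][contexts.loc[contexts["chrom"] == c, "pos"].to_numpy() - 1]
        for c in sorted(chrom_lengths)
    ]) if len(contexts) else np.zeros(0, dtype=np.int8)

    base = np.zeros(len(contexts), dtype=np.float64)
    ctx = contexts["context"].to_numpy()
    for kcode, kname in _CLASS_NAMES.items():
        for context in CONTEXTS:
            sel = (klass == kcode) & (ctx == context)
            base[sel] = params.base_levels[(kname, context)]

    p_a = base.copy()
    p_b = base.copy()
    chrom_arr = contexts["chrom"].to_numpy()
    realized_truth = []
    for t in truth_spec:
        inside = (chrom_arr == t.chrom) & (pos0 >= t.start) & (pos0 < t.end)
        inside &= np.isin(ctx, t.contexts)
        p_b[inside] = t.level_b
        if t.level_a is not None:
            p_a[inside] = t.level_a
            la = t.level_a
        else:
            la = float(base[inside].mean()) if inside.any() else float("nan")
        realized_truth.append(replace(t, level_a=la))

    k = params.dispersion_k
    latent_a = _latent_levels(rng, p_a, k)
    latent_b = _latent_levels(rng, p_b, k)
    cov_a = rng.poisson(params.mean_coverage, size=len(contexts))
    cov_b = rng.poisson(params.mean_coverage, size=len(contexts))
    meth_a = rng.binomial(cov_a, latent_a)
    meth_b = rng.binomial(cov_b, latent_b)

    def _build(sample_id, cov, meth):
        df = contexts.copy()
        df["n_meth"] = meth
        df["n_unmeth"] = cov - meth
        return Methylome(sample_id=sample_id, sites=df,
                         chrom_lengths=dict(chrom_lengths))

    return (_build("sample_a", cov_a, meth_a),
            _build("sample_b", cov_b, meth_b),
            realized_truth)


def sample_truth_regions(sequences: Mapping[str, str], n: int, length: int,
                         level_b: float, direction: str = "hyper",
                         level_a: float | None = None,
                         contexts: Sequence[str] = CONTEXTS,
                         min_cg_sites: int = 0,
                         rng: np.random.Generator | None = None,
                         contexts_table: pd.DataFrame | None = None,
                         max_tries: int = 5000) -> list[TruthRegion]:
    """Draw non-overlapping truth-region requests uniformly over the genome,
    optionally requiring a minimum number of CG cytosines per region."""
    rng = rng if rng is not None else np.random.default_rng(0)
    if contexts_table is None and min_cg_sites > 0:
        contexts_table = assign_contexts(sequences)
    chrom_lengths = {c: len(sequences[c]) for c in sorted(sequences)}
    cg_pos = {}
    if min_cg_sites > 0:
        cg = contexts_table[contexts_table["context"] == "CG"]
        for c, grp in cg.groupby("chrom", sort=True):
            cg_pos[c] = grp["pos"].to_numpy() - 1
    occupied = {c: IntervalTree() for c in chrom_lengths}
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place the requested truth regions")
        try:
            chrom, start = _place_nonoverlapping(rng, occupied, chrom_lengths,
                                                 length, max_tries=1)
        except ValueError:
            continue
        if min_cg_sites > 0:
            pos = cg_pos.get(chrom, np.empty(0))
            n_cg = int(np.searchsorted(pos, start + length)
                       - np.searchsorted(pos, start))
            if n_cg < min_cg_sites:
                continue
        occupied[chrom].addi(start, start + length)
        out.append(TruthRegion(chrom=chrom, start=start, end=start + length,
                               direction=direction, level_b=level_b,
                               level_a=level_a, contexts=tuple(contexts)))
    out.sort(key=lambda t: (t.chrom, t.start))
    return out


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def evaluate_recovery(called: Sequence, truth: Sequence[TruthRegion],
                      min_overlap_fraction: float | None = None
                      ) -> RecoveryReport:
    """Match called DMRs against truth regions (same direction required).

    By default any 1 bp overlap matches; with ``min_overlap_fraction`` f,
    a match needs overlap ≥ f · truth-region length. Recall counts matched
    truth regions; precision counts called regions matching any truth.
    """
    if min_overlap_fraction is not None and not 0 < min_overlap_fraction <= 1:
        raise ValueError("min_overlap_fraction must lie in (0, 1]")
    rule = (">=1bp same-direction overlap" if min_overlap_fraction is None
            else f"overlap >= {min_overlap_fraction} of truth length, "
                 "same direction")
    truth_matched = [False] * len(truth)
    called_matched = [False] * len(called)
    for ti, t in enumerate(truth):
        need = 1 if min_overlap_fraction is None else max(
            1, math.ceil(min_overlap_fraction * (t.end - t.start))
        )
        for ci, d in enumerate(called):
            if d.chrom != t.chrom or d.direction != t.direction:
                continue
            if _overlap(d.start, d.end, t.start, t.end) >= need:
                truth_matched[ti] = True
                called_matched[ci] = True
    return RecoveryReport(
        n_truth=len(truth), n_called=len(called),
        n_truth_matched=sum(truth_matched),
        n_called_matched=sum(called_matched),
        rule=rule,
    )


def write_truth_bed(truth: Sequence[TruthRegion], path) -> None:
    with open(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\tname\tlevel_a\tlevel_b\tcontexts\n")
        for t in sorted(truth, key=lambda t: (t.chrom, t.start)):
            la = "NA" if t.level_a is None else f"{t.level_a:.4f}"
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.direction}\t{la}\t"
                f"{t.level_b:.4f}\t{','.join(t.contexts)}\n"
            )
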