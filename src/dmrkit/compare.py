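"""Downstream DMR analytics.

Multi-set overlap (Venn) classification across genotypes, methylation-level
summaries of DMR subgroups re-measured in arbitrary samples, genomic-feature
classification (gene body / intergenic / TE in or out of genes), chromosome
distribution, and TE-length-stratified methylation levels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import FeatureSet, Methylome

FEATURE_CLASSES = (
    "te_overlapping_gene",
    "te_outside_gene",
    "gene_body",
    "intergenic",
)


@dataclass
class DmrSet:
    """A labelled collection of DMRs from one genotype/contrast."""

    label: str
    dmrs: list

    def __len__(self) -> int:
        return len(self.dmrs)


@dataclass
class VennReport:
    """Membership of each reference DMR across the other sets.

    ``memberships`` holds, per reference region, the sorted tuple of other
    set labels containing a same-direction overlapping region;
    ``pattern_counts`` aggregates those tuples. Counts sum to the size of
    the reference set.
    """

    reference_label: str
    other_labels: tuple
    memberships: list = field(default_factory=list)
    pattern_counts: Counter = field(default_factory=Counter)
    set_totals: dict = field(default_factory=dict)

    @property
    def n_reference(self) -> int:
        return len(self.memberships)

    def shared_with_all_fraction(self) -> float:
        """Fraction of reference regions present in every other set."""
        if not self.memberships:
            return float("nan")
        full = tuple(sorted(self.other_labels))
        return self.pattern_counts.get(full, 0) / len(self.memberships)


def _direction_trees(dmrs: Iterable) -> dict:
    trees: dict[tuple, IntervalTree] = {}
    for d in dmrs:
        trees.setdefault((d.chrom, d.direction), IntervalTree()).addi(
            d.start, d.end, d
        )
    return trees


def venn_classify(reference: DmrSet, others: Sequence[DmrSet],
                  min_overlap_bp: int = 1) -> VennReport:
    """Label each reference DMR with the other sets that contain a
    same-direction region overlapping it by at least ``min_overlap_bp``."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    other_trees = {o.label: _direction_trees(o.dmrs) for o in others}
    report = VennReport(
        reference_label=reference.label,
        other_labels=tuple(o.label for o in others),
        set_totals={reference.label: len(reference.dmrs),
                    **{o.label: len(o.dmrs) for o in others}},
    )
    for d in reference.dmrs:
        hits = []
        for label, trees in other_trees.items():
            tree = trees.get((d.chrom, d.direction))
            if tree is None:
                continue
            for iv in tree.overlap(d.start, d.end):
                if min(iv.end, d.end) - max(iv.begin, d.start) >= min_overlap_bp:
                    hits.append(label)
                    break
        pattern = tuple(sorted(hits))
        report.memberships.append(pattern)
        report.pattern_counts[pattern] += 1
    return report


# -- methylation levels over region subgroups -------------------------------


def _pooled_levels_per_region(regions: Sequence, methylome: Methylome,
                              min_cov: int) -> pd.DataFrame:
    """Per region and context, pooled level over sites covered >= min_cov.

    Regions without qualifying sites for a context are omitted from that
    context's rows.
    """
    sites = methylome.sites
    cov = (sites["n_meth"] + sites["n_unmeth"]).to_numpy()
    keep = cov >= min_cov
    by_chrom = {
        c: g.reset_index(drop=True)
        for c, g in sites.loc[keep].groupby("chrom", sort=False)
    }
    rows = []
    for i, r in enumerate(regions):
        grp = by_chrom.get(r.chrom)
        if grp is None:
            continue
        pos0 = grp["pos"].to_numpy() - 1
        lo = int(np.searchsorted(pos0, r.start, side="left"))
        hi = int(np.searchsorted(pos0, r.end, side="left"))
        span = grp.iloc[lo:hi]
        for context, cgrp in span.groupby("context", sort=True):
            m = int(cgrp["n_meth"].sum())
            u = int(cgrp["n_unmeth"].sum())
            if m + u == 0:
                continue
            rows.append((i, r.chrom, r.start, r.end, context, m / (m + u)))
    return pd.DataFrame(
        rows, columns=["region_index", "chrom", "start", "end",
                       "context", "level"]
    )


def subgroup_levels(subgroups: Mapping[str, Sequence],
                    methylomes: Mapping[str, Methylome],
                    min_cov: int = 4) -> pd.DataFrame:
    """Per-region pooled methylation levels for every subgroup × genotype ×
    context, with five-number summaries.

    ``subgroups`` partitions regions (objects with chrom/start/end) into
    named groups, e.g. Venn classes; ``methylomes`` maps genotype label to
    sample. Returns a tidy summary frame with columns subgroup, genotype,
    context, n_regions, min, q1, median, q3, max, mean. Per-region values
    are attached as ``summary.attrs["levels"]``.
    """
    level_frames = []
    for name, regions in subgroups.items():
        for genotype, methylome in methylomes.items():
            lv = _pooled_levels_per_region(list(regions), methylome, min_cov)
            if len(lv) == 0:
                continue
            lv.insert(0, "subgroup", name)
            lv.insert(1, "genotype", genotype)
            level_frames.append(lv)
    if level_frames:
        levels = pd.concat(level_frames, ignore_index=True)
    else:
        levels = pd.DataFrame(
            columns=["subgroup", "genotype", "region_index", "chrom",
                     "start", "end", "context", "level"]
        )
    rows = []
    for (name, genotype, context), grp in levels.groupby(
            ["subgroup", "genotype", "context"], sort=True):
        v = grp["level"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append((name, genotype, context, len(v),
                     v.min(), q1, med, q3, v.max(), v.mean()))
    summary = pd.DataFrame(
        rows, columns=["subgroup", "genotype", "context", "n_regions",
                       "min", "q1", "median", "q3", "max", "mean"]
    )
    summary.attrs["levels"] = levels
    return summary


# -- genomic feature classification ----------------------------------------


def _tree_from_frame(df: pd.DataFrame) -> dict:
    trees: dict[str, IntervalTree] = {}
    for r in df.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.id)
    return trees


@dataclass
class FeatureClassCounts:
    """DMR counts over the four mutually exclusive location classes."""

    counts: dict
    labels: list

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict:
        t = self.total
        return {k: (v / t if t else float("nan")) for k, v in self.counts.items()}


def classify_by_features(dmrs: DmrSet | Sequence,
                         features: FeatureSet) -> FeatureClassCounts:
    """Assign each DMR exactly one location class.

    Precedence (1 bp overlap suffices at every step): TE that itself
    overlaps a gene > TE outside genes > gene body > intergenic.
    """
    regions = dmrs.dmrs if isinstance(dmrs, DmrSet) else list(dmrs)
    gene_trees = _tree_from_frame(features.genes)
    te_trees = _tree_from_frame(features.tes)
    # precompute, per TE, whether it overlaps any gene
    te_in_gene: dict[tuple, bool] = {}
    for r in features.tes.itertuples(index=False):
        gtree = gene_trees.get(r.chrom)
        te_in_gene[(r.chrom, r.start, r.end)] = bool(
            gtree and gtree.overlap(r.start, r.end)
        )
    labels = []
    counts = Counter({c: 0 for c in FEATURE_CLASSES})
    for d in regions:
        ttree = te_trees.get(d.chrom)
        te_hits = list(ttree.overlap(d.start, d.end)) if ttree else []
        if te_hits:
            if any(te_in_gene[(d.chrom, iv.begin, iv.end)] for iv in te_hits):
                label = "te_overlapping_gene"
            else:
                label = "te_outside_gene"
        else:
            gtree = gene_trees.get(d.chrom)
            if gtree and gtree.overlap(d.start, d.end):
                label = "gene_body"
            else:
                label = "intergenic"
        labels.append(label)
        counts[label] += 1
    return FeatureClassCounts(counts=dict(counts), labels=labels)


def chromosome_distribution(dmrs: DmrSet | Sequence,
                            chrom_lengths: Mapping[str, int],
                            bin_bp: int = 100_000) -> pd.DataFrame:
    """Count DMR midpoints per fixed-width bin per chromosome.

    Returns one row per bin (zeros included) with columns chrom, bin_start,
    bin_end, count; the last bin of each chromosome is clipped.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    regions = dmrs.dmrs if isinstance(dmrs, DmrSet) else list(dmrs)
    rows = []
    mids: dict[str, list] = {}
    for d in regions:
        mids.setdefault(d.chrom, []).append((d.start + d.end) // 2)
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_bins = (length - 1) // bin_bp + 1
        counts = np.zeros(n_bins, dtype=np.int64)
        for mid in mids.get(chrom, ()):
            counts[min(mid // bin_bp, n_bins - 1)] += 1
        for i in range(n_bins):
            rows.append((chrom, i * bin_bp, min((i + 1) * bin_bp, length),
                         int(counts[i])))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "count"])


def te_length_strata(tes: FeatureSet | pd.DataFrame,
                     methylomes: Mapping[str, Methylome],
                     bins: Sequence[int] = (500, 4000),
                     min_cov: int = 4) -> pd.DataFrame:
    """Pooled CHH methylation level per TE-length stratum per genotype.

    ``bins`` are strictly increasing length boundaries; the default
    (500, 4000) gives short (< 500 bp), medium and long (>= 4000 bp)
    strata. Strata without TEs are emitted with n_tes = 0 and NaN level.
    """
    bins = list(bins)
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])) or not bins:
        raise ValueError("bins must be strictly increasing and non-empty")
    te_df = tes.tes if isinstance(tes, FeatureSet) else tes
    edges = [0, *bins, np.inf]
    names = []
    for lo, hi in zip(edges, edges[1:]):
        names.append(f"[{lo},{hi})" if np.isfinite(hi) else f">={lo}")
    lengths = (te_df["end"] - te_df["start"]).to_numpy()
    stratum_of = np.digitize(lengths, bins)
    rows = []
    for s, name in enumerate(names):
        members = te_df.loc[stratum_of == s]
        for genotype, methylome in methylomes.items():
            if len(members) == 0:
                rows.append((name, genotype, 0, float("nan")))
                continue
            sites = methylome.sites
            chh = sites[(sites["context"] == "CHH")
                        & (sites["n_meth"] + sites["n_unmeth"] >= min_cov)]
            m = u = 0
            for c, grp in chh.groupby("chrom", sort=False):
                sel = members[members["chrom"] == c]
                if len(sel) == 0:
                    continue
                pos0 = grp["pos"].to_numpy() - 1
                inside = np.zeros(len(grp), dtype=bool)
                for r in sel.itertuples(index=False):
                    lo_i = np.searchsorted(pos0, r.start, side="left")
                    hi_i = np.searchsorted(pos0, r.end, side="left")
                    inside[lo_i:hi_i] = True
                m += int(grp.loc[inside, "n_meth"].sum())
                u += int(grp.loc[inside, "n_unmeth"].sum())
            level = m / (m + u) if m + u else float("nan")
            rows.append((name, genotype, len(members), level))
    return pd.DataFrame(rows, columns=["stratum", "genotype", "n_tes",
                                       "chh_level"])
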