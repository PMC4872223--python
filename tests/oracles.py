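"""Independent reference implementations used only to check dmrkit.

Everything here is deliberately written the slow, obvious way — exact
rational arithmetic, plain Python loops, scipy's own Fisher test — and
shares no code with the package internals it validates.
"""

from __future__ import annotations

import math
from fractions import Fraction

from scipy.stats import fisher_exact as scipy_fisher


def fisher_two_sided_exact_fraction(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p for [[a, b], [c, d]] by exhaustive enumeration of
    all tables with the observed margins, in exact rational arithmetic.
    Tables whose probability equals the observed one count as ties."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for k in range(lo, hi + 1):
        num = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num <= obs:
            total += num
    return Fraction(total, math.comb(n, c1))


def bh_step_up(p_values):
    """Benjamini–Hochberg adjusted p-values by the literal step-up formula."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    q = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * n / rank)
        q[i] = running_min
    return q


# -- 3-mer context lookup ---------------------------------------------------

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def _context_of_trimer(tri: str) -> str | None:
    """Context of a cytosine from the 3 bases starting at it (5'→3' on its
    strand); None when undeterminable. Shorter strings handle chromosome
    ends: one following base suffices when it is a G."""
    if len(tri) < 2 or tri[0] != "C" or tri[1] == "N":
        return None
    if tri[1] == "G":
        return "CG"
    if len(tri) < 3 or tri[2] == "N":
        return None
    return "CHG" if tri[2] == "G" else "CHH"


def contexts_by_lookup(seq: str):
    """All (pos 1-based, strand, context) for a sequence, via trimer lookup."""
    seq = seq.upper()
    out = []
    for i, base in enumerate(seq):
        if base == "C":
            ctx = _context_of_trimer(seq[i : i + 3])
            if ctx:
                out.append((i + 1, "+", ctx))
        elif base == "G":
            ctx = _context_of_trimer(_revcomp(seq[max(0, i - 2) : i + 1]))
            if ctx:
                out.append((i + 1, "-", ctx))
    return out


# -- straight-line DMR caller -----------------------------------------------


def brute_force_dmrs(meth_a, meth_b, window_bp=200, step_bp=50, min_cov=4,
                     window_q_max=0.01, min_fold=2.0, dmc_p_max=0.01,
                     min_dmcs=7, merge_gap_bp=100, context_mode="ALL"):
    """The published procedure transcribed line by line with plain loops.

    Returns ``[(chrom, start, end, direction, n_dmcs), ...]`` sorted by
    position, for comparison against ``dmrkit.caller.call_dmrs``.
    """
    # pair sites present in both samples, keep those well covered in both
    b_index = {}
    for row in meth_b.sites.itertuples(index=False):
        b_index[(row.chrom, row.pos, row.strand)] = row
    sites = []
    for ra in meth_a.sites.itertuples(index=False):
        rb = b_index.get((ra.chrom, ra.pos, ra.strand))
        if rb is None or rb.context != ra.context:
            continue
        if context_mode != "ALL" and ra.context != context_mode:
            continue
        if ra.n_meth + ra.n_unmeth < min_cov or rb.n_meth + rb.n_unmeth < min_cov:
            continue
        sites.append((ra.chrom, ra.pos - 1, ra.n_meth, ra.n_unmeth,
                      rb.n_meth, rb.n_unmeth))

    chroms = sorted(set(meth_a.chrom_lengths) & set(meth_b.chrom_lengths))
    lengths = {c: max(meth_a.chrom_lengths[c], meth_b.chrom_lengths[c])
               for c in chroms}

    # windowed Fisher tests
    windows = []
    for chrom in chroms:
        for start in range(0, lengths[chrom], step_bp):
            end = min(start + window_bp, lengths[chrom])
            inside = [s for s in sites if s[0] == chrom and start <= s[1] < end]
            if not inside:
                continue
            ma = sum(s[2] for s in inside)
            ua = sum(s[3] for s in inside)
            mb = sum(s[4] for s in inside)
            ub = sum(s[5] for s in inside)
            if ma + ua == 0 or mb + ub == 0:
                continue
            p = scipy_fisher([[ma, ua], [mb, ub]]).pvalue
            windows.append([chrom, start, end, ma / (ma + ua), mb / (mb + ub), p])

    qs = bh_step_up([w[5] for w in windows])
    retained = []
    for w, q in zip(windows, qs):
        la, lb = w[3], w[4]
        hi, lo = max(la, lb), min(la, lb)
        if lo == 0 and hi > 0:
            fold = math.inf
        elif lo == 0:
            fold = math.nan
        else:
            fold = hi / lo
        direction = "hyper" if lb > la else ("hypo" if lb < la else "none")
        if q < window_q_max and fold > min_fold and direction != "none":
            retained.append((w[0], w[1], w[2], direction, q))

    # union overlapping/book-ended retained windows per direction
    regions = []
    for direction in ("hyper", "hypo"):
        sel = sorted([r for r in retained if r[3] == direction])
        current = None
        for chrom, start, end, _, q in sel:
            if current and current[0] == chrom and start <= current[2]:
                current[2] = max(current[2], end)
                current[4] = min(current[4], q)
            else:
                current = [chrom, start, end, direction, q]
                regions.append(current)

    # per-cytosine tests inside candidate regions
    with_dmcs = []
    for chrom, start, end, direction, q in regions:
        dmcs = []
        for s in sites:
            if s[0] != chrom or not start <= s[1] < end:
                continue
            la = s[2] / (s[2] + s[3])
            lb = s[4] / (s[4] + s[5])
            sdir = "hyper" if lb > la else ("hypo" if lb < la else "none")
            if sdir != direction:
                continue
            p = scipy_fisher([[s[2], s[3]], [s[4], s[5]]]).pvalue
            if p < dmc_p_max:
                dmcs.append(s[1])
        if len(dmcs) >= min_dmcs:
            with_dmcs.append([chrom, start, end, direction, sorted(dmcs)])

    # merge neighbours with gap < merge_gap_bp, same direction
    merged = []
    for direction in ("hyper", "hypo"):
        sel = sorted([r for r in with_dmcs if r[3] == direction])
        current = None
        for chrom, start, end, _, dmcs in sel:
            if (current and current[0] == chrom
                    and start - current[2] < merge_gap_bp):
                current[2] = max(current[2], end)
                current[4] = sorted(current[4] + dmcs)
            else:
                current = [chrom, start, end, direction, list(dmcs)]
                merged.append(current)

    # trim to first/last DMC
    out = [(chrom, dmcs[0], dmcs[-1] + 1, direction, len(dmcs))
           for chrom, start, end, direction, dmcs in merged]
    return sorted(out)


# -- interval classification ------------------------------------------------


def brute_force_venn(reference, others, min_overlap_bp=1):
    """Membership pattern of each reference DMR, by exhaustive pair checks.
    ``others`` is a list of (label, dmrs) pairs."""
    patterns = []
    for d in reference:
        hits = []
        for label, dmrs in others:
            for o in dmrs:
                if (o.chrom == d.chrom and o.direction == d.direction
                        and min(o.end, d.end) - max(o.start, d.start)
                        >= min_overlap_bp):
                    hits.append(label)
                    break
        patterns.append(tuple(sorted(hits)))
    return patterns


def brute_force_feature_class(dmr, genes, tes):
    """Location class of one region against plain (chrom, start, end) lists."""

    def overlaps(a, b):
        return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]

    region = (dmr.chrom, dmr.start, dmr.end)
    hit_tes = [t for t in tes if overlaps(region, t)]
    if hit_tes:
        for t in hit_tes:
            if any(overlaps(t, g) for g in genes):
                return "te_overlapping_gene"
        return "te_outside_gene"
    if any(overlaps(region, g) for g in genes):
        return "gene_body"
    return "intergenic"
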