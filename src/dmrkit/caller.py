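"""Windowed Fisher-exact DMR calling with DMC-based region refinement.

The algorithm compares two single-library methylomes pairwise:

1. keep cytosines covered by at least ``min_cov`` reads in both libraries;
2. pool methylated/unmethylated counts in 200 bp windows sliding by 50 bp
   and test each window with a two-sided Fisher exact test;
3. adjust window p-values genome-wide (Benjamini–Hochberg) and retain
   windows with q < 0.01 and an over 2-fold methylation-level change;
4. union overlapping retained windows of one direction into candidate
   regions and re-test every cytosine inside them: a site with raw Fisher
   p < 0.01 changing in the region's direction is a differentially
   methylated cytosine (DMC);
5. keep regions with at least 7 DMCs, merge same-direction neighbours whose
   gap is under 100 bp, and trim each region to its first and last DMC.

Direction is reported for sample B relative to sample A ("hyper" = more
methylated in B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .io import CONTEXTS, InputError, Methylome
from .stats import bh_adjust, fisher_exact_many, fisher_exact_two_sided

CONTEXT_MODES = CONTEXTS + ("ALL",)


@dataclass(frozen=True)
class DmrCallParams:
    """Tuning knobs of the caller; defaults are the published procedure."""

    window_bp: int = 200
    step_bp: int = 50
    min_cov: int = 4
    window_q_max: float = 0.01
    min_fold: float = 2.0
    dmc_p_max: float = 0.01
    min_dmcs: int = 7
    merge_gap_bp: int = 100  # gaps strictly below this merge
    context_mode: str = "ALL"

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0 < self.step_bp <= self.window_bp:
            raise ValueError("need 0 < step_bp <= window_bp")
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not 0 < self.window_q_max < 1 or not 0 < self.dmc_p_max < 1:
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")
        if self.min_dmcs < 1:
            raise ValueError("min_dmcs must be >= 1")
        if self.merge_gap_bp < 0:
            raise ValueError("merge_gap_bp must be non-negative")
        if self.context_mode not in CONTEXT_MODES:
            raise ValueError(f"context_mode must be one of {CONTEXT_MODES}")


@dataclass
class Window:
    """One tested window: pooled counts over qualifying sites of both samples."""

    chrom: str
    start: int
    end: int
    meth_a: int = 0
    unmeth_a: int = 0
    meth_b: int = 0
    unmeth_b: int = 0
    n_sites: int = 0
    p_raw: float = float("nan")
    q: float = float("nan")
    direction: str = "none"

    @property
    def testable(self) -> bool:
        return self.n_sites > 0 and self.meth_a + self.unmeth_a > 0 \
            and self.meth_b + self.unmeth_b > 0

    @property
    def level_a(self) -> float:
        cov = self.meth_a + self.unmeth_a
        return self.meth_a / cov if cov else float("nan")

    @property
    def level_b(self) -> float:
        cov = self.meth_b + self.unmeth_b
        return self.meth_b / cov if cov else float("nan")


@dataclass(frozen=True)
class Dmc:
    """A differentially methylated cytosine (raw Fisher p below threshold)."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    p_raw: float
    direction: str


@dataclass(frozen=True)
class Dmr:
    """A called differentially methylated region, trimmed to its DMC span.

    ``start``/``end`` are 0-based half-open; ``dmc_positions`` holds the
    member DMCs' 0-based positions; levels and fold change are pooled over
    qualifying sites of the trimmed span.
    """

    chrom: str
    start: int
    end: int
    direction: str
    context_mode: str
    n_dmcs: int
    best_q: float
    fold_change: float
    level_a: float
    level_b: float
    dmc_positions: tuple = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class _Region:
    """Internal candidate region: a union of retained windows."""

    chrom: str
    start: int
    end: int
    direction: str
    best_q: float
    dmcs: list = field(default_factory=list)


@dataclass
class CallResult:
    """Full output of one caller run: DMRs, the window table, stage counts."""

    dmrs: list
    windows: pd.DataFrame
    funnel: dict


# -- window construction ----------------------------------------------------


def enumerate_windows(chrom_lengths: dict[str, int],
                      params: DmrCallParams) -> Iterator[tuple[str, int, int]]:
    """Yield sliding-window frames (chrom, start, end), 0-based half-open.

    Starts run 0, step, 2·step, … while start < chromosome length; the last
    frame is clipped at the chromosome end.
    """
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        for start in range(0, length, params.step_bp):
            yield chrom, start, min(start + params.window_bp, length)


def _paired_sites(meth_a: Methylome, meth_b: Methylome) -> pd.DataFrame:
    shared = set(meth_a.chrom_lengths) & set(meth_b.chrom_lengths)
    if not shared:
        raise InputError("methylomes share no chromosomes")
    df = pd.merge(
        meth_a.sites, meth_b.sites,
        on=["chrom", "pos", "strand", "context"],
        suffixes=("_a", "_b"), how="inner", sort=False,
    )
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return df.reset_index(drop=True)


def _qualifying(paired: pd.DataFrame, params: DmrCallParams) -> pd.DataFrame:
    cov_a = paired["n_meth_a"] + paired["n_unmeth_a"]
    cov_b = paired["n_meth_b"] + paired["n_unmeth_b"]
    keep = (cov_a >= params.min_cov) & (cov_b >= params.min_cov)
    if params.context_mode != "ALL":
        keep &= paired["context"] == params.context_mode
    return paired.loc[keep].reset_index(drop=True)


def _window_table(qualifying: pd.DataFrame, chrom_lengths: dict[str, int],
                  params: DmrCallParams) -> pd.DataFrame:
    """Pool counts of qualifying sites into sliding windows.

    Only frames containing at least one qualifying site are materialized
    (empty frames are untestable and never reach the test stage).
    """
    win, step = params.window_bp, params.step_bp
    n_offsets = -(-win // step)  # a site falls in at most ceil(win/step) frames
    chunks = []
    for chrom, grp in qualifying.groupby("chrom", sort=True):
        length = chrom_lengths[chrom]
        n_frames = (length - 1) // step + 1
        pos0 = grp["pos"].to_numpy() - 1
        counts = grp[["n_meth_a", "n_unmeth_a", "n_meth_b", "n_unmeth_b"]].to_numpy()
        acc = np.zeros((n_frames, 4), dtype=np.int64)
        n_sites = np.zeros(n_frames, dtype=np.int64)
        base = pos0 // step
        for k in range(n_offsets):
            w = base - k
            ok = (w >= 0) & (pos0 < w * step + win)
            if not ok.any():
                continue
            widx = w[ok]
            np.add.at(acc, widx, counts[ok])
            np.add.at(n_sites, widx, 1)
        hit = np.flatnonzero(n_sites > 0)
        starts = hit * step
        chunks.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + win, length),
                    "meth_a": acc[hit, 0],
                    "unmeth_a": acc[hit, 1],
                    "meth_b": acc[hit, 2],
                    "unmeth_b": acc[hit, 3],
                    "n_sites": n_sites[hit],
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "meth_a", "unmeth_a",
                     "meth_b", "unmeth_b", "n_sites"]
        )
    return pd.concat(chunks, ignore_index=True)


def pool_window_counts(meth_a: Methylome, meth_b: Methylome,
                       frame: tuple[str, int, int],
                       params: DmrCallParams) -> Window:
    """Pool one frame's counts over sites qualifying in both samples."""
    chrom, start, end = frame
    paired = _qualifying(_paired_sites(meth_a, meth_b), params)
    grp = paired[(paired["chrom"] == chrom)
                 & (paired["pos"] - 1 >= start) & (paired["pos"] - 1 < end)]
    w = Window(
        chrom=chrom, start=start, end=end,
        meth_a=int(grp["n_meth_a"].sum()), unmeth_a=int(grp["n_unmeth_a"].sum()),
        meth_b=int(grp["n_meth_b"].sum()), unmeth_b=int(grp["n_unmeth_b"].sum()),
        n_sites=len(grp),
    )
    if w.testable:
        if w.level_b > w.level_a:
            w.direction = "hyper"
        elif w.level_b < w.level_a:
            w.direction = "hypo"
    return w


# -- window testing ---------------------------------------------------------


def _fold_change(level_a: np.ndarray, level_b: np.ndarray) -> np.ndarray:
    hi = np.maximum(level_a, level_b)
    lo = np.minimum(level_a, level_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where((lo == 0) & (hi > 0), np.inf, hi / lo)
    return fold


def _test_window_table(windows: pd.DataFrame,
                       params: DmrCallParams) -> pd.DataFrame:
    """Attach p, q, levels, direction, fold and the retained flag.

    BH adjustment spans all testable windows of the run (one context mode,
    genome-wide).
    """
    df = windows.copy()
    cov_a = df["meth_a"] + df["unmeth_a"]
    cov_b = df["meth_b"] + df["unmeth_b"]
    testable = (df["n_sites"] > 0) & (cov_a > 0) & (cov_b > 0)
    df = df.loc[testable].reset_index(drop=True)
    if len(df) == 0:
        for col in ("level_a", "level_b", "p_raw", "q", "fold_change"):
            df[col] = pd.Series(dtype=np.float64)
        df["direction"] = pd.Series(dtype=str)
        df["retained"] = pd.Series(dtype=bool)
        return df
    cov_a = (df["meth_a"] + df["unmeth_a"]).to_numpy(dtype=np.float64)
    cov_b = (df["meth_b"] + df["unmeth_b"]).to_numpy(dtype=np.float64)
    level_a = df["meth_a"].to_numpy() / cov_a
    level_b = df["meth_b"].to_numpy() / cov_b
    tables = df[["meth_a", "unmeth_a", "meth_b", "unmeth_b"]].to_numpy()
    p = fisher_exact_many(tables)
    q = bh_adjust(p)
    fold = _fold_change(level_a, level_b)
    direction = np.where(level_b > level_a, "hyper",
                         np.where(level_b < level_a, "hypo", "none"))
    df["level_a"] = level_a
    df["level_b"] = level_b
    df["p_raw"] = p
    df["q"] = q
    df["fold_change"] = fold
    df["direction"] = direction
    df["retained"] = (
        (q < params.window_q_max)
        & (fold > params.min_fold)
        & (direction != "none")
    )
    return df


def test_windows(windows: Sequence[Window],
                 params: DmrCallParams) -> list[Window]:
    """Test a collection of pooled windows; return the significant ones.

    Untestable windows are dropped; BH is applied across the remaining
    family; retention requires q < ``window_q_max`` and fold change above
    ``min_fold`` (fold = larger level / smaller level; infinite when the
    smaller level is zero and the larger is not).
    """
    testable = [w for w in windows if w.testable]
    if not testable:
        return []
    p = fisher_exact_many(
        np.array([[w.meth_a, w.unmeth_a, w.meth_b, w.unmeth_b]
                  for w in testable])
    )
    q = bh_adjust(p)
    out = []
    for w, pi, qi in zip(testable, p, q):
        w.p_raw = float(pi)
        w.q = float(qi)
        hi, lo = max(w.level_a, w.level_b), min(w.level_a, w.level_b)
        fold = math.inf if (lo == 0 and hi > 0) else (hi / lo if lo else math.nan)
        if w.q < params.window_q_max and fold > params.min_fold \
                and w.direction != "none":
            out.append(w)
    return out


# -- region assembly --------------------------------------------------------


def build_regions(significant: pd.DataFrame | Sequence[Window]) -> list[_Region]:
    """Union overlapping or book-ended same-direction retained windows into
    maximal candidate regions. Opposite directions never union."""
    if isinstance(significant, pd.DataFrame):
        rows = list(significant[["chrom", "start", "end", "direction", "q"]]
                    .itertuples(index=False))
    else:
        rows = [(w.chrom, w.start, w.end, w.direction, w.q) for w in significant]
    regions: list[_Region] = []
    for direction in ("hyper", "hypo"):
        sel = sorted((r for r in rows if r[3] == direction),
                     key=lambda r: (r[0], r[1], r[2]))
        current = None
        for chrom, start, end, _, q in sel:
            if (current is not None and current.chrom == chrom
                    and start <= current.end):
                current.end = max(current.end, end)
                current.best_q = min(current.best_q, q)
            else:
                current = _Region(chrom, start, end, direction, q)
                regions.append(current)
    regions.sort(key=lambda r: (r.chrom, r.start, r.direction))
    return regions


def call_dmcs(meth_a: Methylome, meth_b: Methylome,
              region: tuple[str, int, int], direction: str,
              params: DmrCallParams) -> list[Dmc]:
    """Per-cytosine Fisher tests inside a candidate region.

    Returns the sites with raw p below ``dmc_p_max`` whose own direction of
    change matches the region's.
    """
    paired = _qualifying(_paired_sites(meth_a, meth_b), params)
    chrom, start, end = region
    grp = paired[(paired["chrom"] == chrom)
                 & (paired["pos"] - 1 >= start) & (paired["pos"] - 1 < end)]
    return _dmcs_from_rows(grp, direction, params)


def _dmcs_from_rows(rows: pd.DataFrame, direction: str,
                    params: DmrCallParams) -> list[Dmc]:
    out = []
    for r in rows.itertuples(index=False):
        la = r.n_meth_a / (r.n_meth_a + r.n_unmeth_a)
        lb = r.n_meth_b / (r.n_meth_b + r.n_unmeth_b)
        site_dir = "hyper" if lb > la else ("hypo" if lb < la else "none")
        if site_dir != direction:
            continue
        p = fisher_exact_two_sided(r.n_meth_a, r.n_unmeth_a,
                                   r.n_meth_b, r.n_unmeth_b)
        if p < params.dmc_p_max:
            out.append(Dmc(r.chrom, int(r.pos), r.strand, r.context,
                           p, site_dir))
    return out


def retain_and_merge(regions: Iterable[_Region],
                     params: DmrCallParams) -> list[_Region]:
    """Drop regions with fewer than ``min_dmcs`` DMCs, then merge surviving
    same-direction neighbours whose gap is strictly below ``merge_gap_bp``.

    Gaps are measured in half-open coordinates (next start − previous end);
    merging runs left to right to a fixed point and is order-independent.
    """
    survivors = [r for r in regions if len(r.dmcs) >= params.min_dmcs]
    merged: list[_Region] = []
    for direction in ("hyper", "hypo"):
        sel = sorted((r for r in survivors if r.direction == direction),
                     key=lambda r: (r.chrom, r.start, r.end))
        current = None
        for r in sel:
            if (current is not None and current.chrom == r.chrom
                    and r.start - current.end < params.merge_gap_bp):
                current.end = max(current.end, r.end)
                current.best_q = min(current.best_q, r.best_q)
                current.dmcs.extend(r.dmcs)
            else:
                current = _Region(r.chrom, r.start, r.end, direction,
                                  r.best_q, list(r.dmcs))
                merged.append(current)
    merged.sort(key=lambda r: (r.chrom, r.start, r.direction))
    return merged


def trim_to_dmcs(region: _Region, qualifying: pd.DataFrame,
                 params: DmrCallParams) -> Dmr:
    """Trim a region to its first and last DMC and recompute statistics
    (pooled levels and fold change) over the trimmed span."""
    if not region.dmcs:
        raise RuntimeError("cannot trim a region with no DMCs")
    dmc_pos0 = sorted(d.pos - 1 for d in region.dmcs)
    start, end = dmc_pos0[0], dmc_pos0[-1] + 1
    grp = qualifying[(qualifying["chrom"] == region.chrom)
                     & (qualifying["pos"] - 1 >= start)
                     & (qualifying["pos"] - 1 < end)]
    ma, ua = int(grp["n_meth_a"].sum()), int(grp["n_unmeth_a"].sum())
    mb, ub = int(grp["n_meth_b"].sum()), int(grp["n_unmeth_b"].sum())
    level_a = ma / (ma + ua) if ma + ua else float("nan")
    level_b = mb / (mb + ub) if mb + ub else float("nan")
    hi, lo = max(level_a, level_b), min(level_a, level_b)
    fold = math.inf if (lo == 0 and hi > 0) else (hi / lo if lo else math.nan)
    return Dmr(
        chrom=region.chrom, start=start, end=end, direction=region.direction,
        context_mode=params.context_mode, n_dmcs=len(region.dmcs),
        best_q=region.best_q, fold_change=fold,
        level_a=level_a, level_b=level_b,
        dmc_positions=tuple(dmc_pos0),
    )


# -- full pipeline ----------------------------------------------------------


def call_dmrs_full(meth_a: Methylome, meth_b: Methylome,
                   params: DmrCallParams | None = None) -> CallResult:
    """Run the whole caller and keep the window table and stage counts."""
    params = params or DmrCallParams()
    shared = sorted(set(meth_a.chrom_lengths) & set(meth_b.chrom_lengths))
    if not shared:
        raise InputError("methylomes share no chromosomes")
    chrom_lengths = {
        c: max(meth_a.chrom_lengths[c], meth_b.chrom_lengths[c]) for c in shared
    }
    paired = _paired_sites(meth_a, meth_b)
    qualifying = _qualifying(paired, params)
    windows = _window_table(qualifying, chrom_lengths, params)
    tested = _test_window_table(windows, params)
    retained = tested.loc[tested["retained"]]
    regions = build_regions(retained)
    # index qualifying sites per chromosome once; regions query by position
    by_chrom = {c: g.reset_index(drop=True)
                for c, g in qualifying.groupby("chrom", sort=False)}
    n_candidates = len(regions)
    for region in regions:
        grp = by_chrom.get(region.chrom)
        if grp is None:
            continue
        pos0 = grp["pos"].to_numpy() - 1
        lo = int(np.searchsorted(pos0, region.start, side="left"))
        hi = int(np.searchsorted(pos0, region.end, side="left"))
        region.dmcs = _dmcs_from_rows(grp.iloc[lo:hi], region.direction, params)
    kept = [r for r in regions if len(r.dmcs) >= params.min_dmcs]
    merged = retain_and_merge(regions, params)
    dmrs = [trim_to_dmcs(r, by_chrom[r.chrom], params) for r in merged]
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.direction))
    funnel = {
        "sites_paired": len(paired),
        "sites_qualifying": len(qualifying),
        "windows_tested": len(tested),
        "windows_retained": int(tested["retained"].sum()) if len(tested) else 0,
        "regions_candidate": n_candidates,
        "regions_min_dmcs": len(kept),
        "dmrs": len(dmrs),
    }
    return CallResult(dmrs=dmrs, windows=tested, funnel=funnel)


def call_dmrs(meth_a: Methylome, meth_b: Methylome,
              params: DmrCallParams | None = None) -> list[Dmr]:
    """Call DMRs between two methylomes; see the module docstring for the
    procedure. Returns hyper- and hypo-DMRs together, sorted by position."""
    return call_dmrs_full(meth_a, meth_b, params).dmrs
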