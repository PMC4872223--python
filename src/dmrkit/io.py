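"""Reading and writing the formats the pipeline touches.

Per-cytosine methylation reports (TSV, optionally gzipped), genome FASTA,
gene/TE annotations (BED or GFF3), and BED6+ DMR output. Coordinates are
1-based in cytosine reports and GFF3, 0-based half-open everywhere internally
and in BED, matching each format's convention.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class InputError(ValueError):
    """Inputs are individually well-formed but mutually inconsistent."""


@dataclass(frozen=True)
class CytosineSite:
    """One strand-specific cytosine in one sample.

    ``pos`` is the 1-based position of the cytosine on the forward reference
    coordinate (for a − strand cytosine this is the position of the G on the
    + strand). Counts are reads supporting methylation / non-methylation.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")
        if self.context not in CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.pos <= 0:
            raise ValueError("pos is 1-based and must be positive")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass
class Methylome:
    """One sample's per-cytosine calls plus chromosome lengths.

    ``sites`` is a DataFrame with columns chrom, pos (1-based), strand,
    context, n_meth, n_unmeth, sorted by (chrom, pos, strand) with no
    duplicate site.
    """

    sample_id: str
    sites: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sites missing columns: {missing}")
        df = df[SITE_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["n_meth"] = df["n_meth"].astype(np.int64)
        df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
        if len(df):
            if (df["pos"] <= 0).any():
                raise ValueError("positions are 1-based and must be positive")
            if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
                raise ValueError("read counts must be non-negative")
            bad = ~df["context"].isin(CONTEXTS)
            if bad.any():
                raise ValueError(
                    f"invalid context value {df.loc[bad, 'context'].iloc[0]!r}"
                )
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        df = df.reset_index(drop=True)
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) site")
        if not self.chrom_lengths:
            self.chrom_lengths = (
                df.groupby("chrom", sort=True)["pos"].max().astype(int).to_dict()
            )
        else:
            for chrom, grp in df.groupby("chrom", sort=False):
                length = self.chrom_lengths.get(chrom)
                if length is not None and int(grp["pos"].max()) > length:
                    raise ValueError(
                        f"site beyond end of {chrom} (length {length})"
                    )
        self.sites = df

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class FeatureSet:
    """Gene and TE intervals, 0-based half-open.

    Both tables have columns chrom, start, end, strand, id.
    """

    genes: pd.DataFrame = None
    tes: pd.DataFrame = None

    def __post_init__(self) -> None:
        for attr in ("genes", "tes"):
            df = getattr(self, attr)
            if df is None:
                df = _empty_features()
            df = df[FEATURE_COLUMNS].copy()
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            if len(df) and (df["start"] >= df["end"]).any():
                raise FormatError(f"{attr}: interval with start >= end")
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
            setattr(self, attr, df.reset_index(drop=True))


FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "id"]


def _empty_features() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "id": pd.Series(dtype=str),
        }
    )


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_cytosine_report(path, sample_id: str | None = None,
                         chrom_lengths: dict[str, int] | None = None) -> Methylome:
    """Read a six-column per-cytosine report into a :class:`Methylome`.

    Expected tab-separated columns: chrom, pos (1-based), strand (+/−),
    context (CG/CHG/CHH), methylated count, unmethylated count. Lines
    starting with ``#`` are ignored. Gzip-compressed input is handled by
    file extension.
    """
    path = Path(path)
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, strand, context, m_s, u_s = fields
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(m_s), int(u_s)
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: non-integer position or count"
                ) from None
            if pos <= 0:
                raise FormatError(f"{path.name}:{lineno}: position must be >= 1")
            if n_meth < 0 or n_unmeth < 0:
                raise FormatError(f"{path.name}:{lineno}: negative count")
            if context not in CONTEXTS:
                raise FormatError(
                    f"{path.name}:{lineno}: invalid context {context!r}"
                )
            if strand not in ("+", "-"):
                raise FormatError(f"{path.name}:{lineno}: invalid strand {strand!r}")
            rows.append((chrom, pos, strand, context, n_meth, n_unmeth))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS) if rows else pd.DataFrame(
        {c: [] for c in SITE_COLUMNS}
    )
    if not rows:
        df = df.astype({"pos": np.int64, "n_meth": np.int64, "n_unmeth": np.int64})
    return Methylome(
        sample_id=sample_id or path.stem.removesuffix(".tsv"),
        sites=df,
        chrom_lengths=dict(chrom_lengths or {}),
    )


def write_cytosine_report(methylome: Methylome, path) -> None:
    """Write a Methylome back to the six-column report format (round-trips)."""
    with _open_text(path, "wt") as fh:
        df = methylome.sites
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.context}\t"
                f"{row.n_meth}\t{row.n_unmeth}\n"
            )


# -- cytosine context assignment -------------------------------------------

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")


def assign_contexts(genome: Mapping[str, str]) -> pd.DataFrame:
    """Assign CG/CHG/CHH context to every cytosine on both strands.

    ``genome`` maps chromosome name to sequence (any object whose ``str()``
    yields the sequence works, so ``pyfaidx.Fasta`` records are accepted).
    Contexts follow the plant convention: reading 5'→3' on the cytosine's own
    strand, CG if the next base is G, else CHG if the base after that is G,
    else CHH (H = A, T or C). Cytosines whose required context bases fall off
    the chromosome end or are N are skipped.

    Returns a DataFrame with columns chrom, pos (1-based, forward
    coordinate), strand, context, sorted by (chrom, pos, strand).
    """
    frames = []
    for chrom in sorted(genome.keys()):
        seq = str(genome[chrom]).upper()
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = arr.size
        if n == 0:
            continue
        # b1/b2: following bases on + strand, sentinel N past the end
        b1 = np.full(n, _N, dtype=np.uint8)
        b2 = np.full(n, _N, dtype=np.uint8)
        b1[:-1] = arr[1:]
        if n >= 2:
            b2[:-2] = arr[2:]
        h1 = (b1 == _A) | (b1 == _C) | (b1 == _T)
        h2 = (b2 == _A) | (b2 == _C) | (b2 == _T)
        is_c = arr == _C
        plus_cg = is_c & (b1 == _G)
        plus_chg = is_c & h1 & (b2 == _G)
        plus_chh = is_c & h1 & h2
        # − strand: a G on the forward strand; its 3' neighbours read on the
        # reverse complement are the complements of the preceding forward bases
        p1 = np.full(n, _N, dtype=np.uint8)
        p2 = np.full(n, _N, dtype=np.uint8)
        p1[1:] = arr[:-1]
        if n >= 2:
            p2[2:] = arr[:-2]
        # complement of {A,C,T} is {T,G,A}: H on the − strand
        h1m = (p1 == _A) | (p1 == _G) | (p1 == _T)
        h2m = (p2 == _A) | (p2 == _G) | (p2 == _T)
        is_g = arr == _G
        minus_cg = is_g & (p1 == _C)
        minus_chg = is_g & h1m & (p2 == _C)
        minus_chh = is_g & h1m & h2m
        for strand, cg, chg, chh in (
            ("+", plus_cg, plus_chg, plus_chh),
            ("-", minus_cg, minus_chg, minus_chh),
        ):
            for context, mask in (("CG", cg), ("CHG", chg), ("CHH", chh)):
                pos = np.flatnonzero(mask) + 1
                if pos.size:
                    frames.append(
                        pd.DataFrame(
                            {
                                "chrom": chrom,
                                "pos": pos,
                                "strand": strand,
                                "context": context,
                            }
                        )
                    )
    if not frames:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "context": pd.Series(dtype=str),
            }
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return out.reset_index(drop=True)


# -- feature annotations ----------------------------------------------------


def read_features(path, kind: str = "gene") -> FeatureSet:
    """Read gene or TE intervals from BED (0-based half-open) or GFF3.

    GFF3 coordinates (1-based closed) are converted on read. ``kind`` selects
    which slot of the returned :class:`FeatureSet` is populated.
    """
    if kind not in ("gene", "te"):
        raise ValueError("kind must be 'gene' or 'te'")
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3", ".gtf"):
        df = _read_gff3(path)
    else:
        df = _read_bed_intervals(path)
    if kind == "gene":
        return FeatureSet(genes=df, tes=None)
    return FeatureSet(genes=None, tes=df)


def _read_bed_intervals(path) -> pd.DataFrame:
    path = Path(path)
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path.name}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from None
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path.name}:{lineno}: invalid interval [{start},{end})"
                )
            name = f[3] if len(f) > 3 and f[3] else f"feature_{lineno}"
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            rows.append((f[0], start, end, strand, name))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS) if rows else _empty_features()


def _read_gff3(path) -> pd.DataFrame:
    path = Path(path)
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path.name}:{lineno}: GFF3 needs 9 columns")
            try:
                start1, end1 = int(f[3]), int(f[4])
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from None
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path.name}:{lineno}: invalid interval [{start},{end})"
                )
            fid = f"feature_{lineno}"
            for token in f[8].split(";"):
                if token.startswith("ID="):
                    fid = token[3:]
                    break
                if token.startswith("Name="):
                    fid = token[5:]
            strand = f[6] if f[6] in ("+", "-") else "."
            rows.append((f[0], start, end, strand, fid))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS) if rows else _empty_features()


# -- DMR BED output ---------------------------------------------------------

DMR_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\t"
    "n_dmcs\tfold_change\tlevel_a\tlevel_b\tq_value"
)


def _fmt_fold(fold: float) -> str:
    if math.isinf(fold):
        return "inf"
    return f"{fold:.4f}"


def write_dmr_bed(dmrs: Iterable, path) -> None:
    """Write called DMRs as deterministic BED6+ sorted by (chrom, start).

    The name column is ``direction:context``; the score is the conventional
    min(−10·log10(q), 1000), rounded.
    """
    dmrs = sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end, d.direction))
    with open(path, "wt") as fh:
        fh.write(DMR_BED_HEADER + "\n")
        for d in dmrs:
            score = int(round(min(-10.0 * math.log10(max(d.best_q, 1e-300)), 1000.0)))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}:{d.context_mode}\t"
                f"{score}\t.\t{d.n_dmcs}\t{_fmt_fold(d.fold_change)}\t"
                f"{d.level_a:.4f}\t{d.level_b:.4f}\t{d.best_q:.6g}\n"
            )


def read_dmr_bed(path) -> list:
    """Read DMRs written by :func:`write_dmr_bed` (or any BED4+ with a
    ``direction:context`` name column) back into :class:`~dmrkit.caller.Dmr`
    records. Missing statistics columns are filled with neutral values."""
    from .caller import Dmr

    path = Path(path)
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path.name}:{lineno}: DMR BED needs >= 4 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from None
            direction, _, context = f[3].partition(":")
            if direction not in ("hyper", "hypo"):
                raise FormatError(
                    f"{path.name}:{lineno}: name must be direction:context, "
                    f"got {f[3]!r}"
                )
            n_dmcs = int(f[6]) if len(f) > 6 else 0
            fold = float(f[7]) if len(f) > 7 else float("nan")
            level_a = float(f[8]) if len(f) > 8 else float("nan")
            level_b = float(f[9]) if len(f) > 9 else float("nan")
            q = float(f[10]) if len(f) > 10 else float("nan")
            out.append(
                Dmr(
                    chrom=f[0], start=start, end=end, direction=direction,
                    context_mode=context or "ALL", n_dmcs=n_dmcs, best_q=q,
                    fold_change=fold, level_a=level_a, level_b=level_b,
                    dmc_positions=(),
                )
            )
    return out


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file as a chromosome → sequence dict (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name in sequences:
            seq = str(sequences[name])
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
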