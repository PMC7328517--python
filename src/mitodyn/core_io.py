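"""Genomic interval data model, standard-format I/O and meta-profiles.

Coordinates are 0-based half-open throughout (BED convention). 1-based
inputs are never auto-detected: silent convention guessing causes
off-by-one corruption, so callers must convert explicitly. Strand is
ignored for peaks and honored only for TSS placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "CTCF")
PHASES = ("interphase", "prometaphase", "ana_telo")

BED_COLUMNS = ["chrom", "start", "end", "name", "signal", "strand"]


class ParseError(ValueError):
    """Malformed record in a text input file (carries the line number)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, . : {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp (half-open; strand ignored)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _as_frame(intervals: pd.DataFrame | Iterable) -> pd.DataFrame:
    """Coerce a peak table or iterable of intervals to a sorted frame."""
    if isinstance(intervals, pd.DataFrame):
        df = intervals
    else:
        rows = []
        for item in intervals:
            if isinstance(item, GenomicInterval):
                rows.append((item.chrom, item.start, item.end, ".", np.nan,
                             item.strand))
            else:  # (interval, signal) pair
                iv, sig = item
                rows.append((iv.chrom, iv.start, iv.end, ".", float(sig),
                             iv.strand))
        df = pd.DataFrame(rows, columns=BED_COLUMNS)
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    return df.reset_index(drop=True)


class PeakSet:
    """A named set of peaks for one (mark, phase).

    Peaks are kept in a sorted, deduplicated table with columns
    ``chrom, start, end, name, signal, strand``; ``signal`` is a
    nonnegative normalized read density (NaN when unknown).
    """

    def __init__(self, intervals, mark: str | None = None,
                 phase: str | None = None):
        if mark is not None and mark not in MARKS:
            raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
        if phase is not None and phase not in PHASES:
            raise ValueError(
                f"unknown phase {phase!r}; expected one of {PHASES}")
        df = _as_frame(intervals)
        df = df.drop_duplicates(subset=["chrom", "start", "end"])
        df = df.reset_index(drop=True)
        if len(df):
            sig = df["signal"].to_numpy(dtype=float)
            if np.any(sig[~np.isnan(sig)] < 0):
                raise ValueError("peak signal must be nonnegative")
        self.df = df
        self.mark = mark
        self.phase = phase

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  row.strand)

    def intervals(self) -> list[GenomicInterval]:
        return list(self)

    def centers(self) -> pd.DataFrame:
        """Peak centers as a frame of (chrom, pos)."""
        df = self.df
        pos = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        return pd.DataFrame({"chrom": df["chrom"].to_numpy(), "pos": pos})

    def clipped_to(self, chrom_lengths: Mapping[str, int]) -> "PeakSet":
        """Clip peaks straddling chromosome ends (logged); drop unknown chroms."""
        df = self.df.copy()
        keep = df["chrom"].isin(chrom_lengths)
        if (~keep).any():
            logger.warning("dropping %d peaks on unknown chromosomes",
                           int((~keep).sum()))
            df = df[keep]
        lengths = df["chrom"].map(chrom_lengths).to_numpy(dtype=np.int64)
        clipped = df["end"].to_numpy() > lengths
        if clipped.any():
            logger.warning("clipping %d peaks at chromosome ends",
                           int(clipped.sum()))
            df = df.copy()
            df.loc[clipped, "end"] = lengths[clipped]
            df = df[df["end"] > df["start"]]
        return PeakSet(df, mark=self.mark, phase=self.phase)


def overlap_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean vector: does each query interval overlap >= 1 subject interval.

    Both frames need ``chrom, start, end`` columns. >= 1 bp half-open
    overlap. O((n+m) log m) via a sorted sweep with a running maximum of
    subject ends per chromosome.
    """
    out = np.zeros(len(query), dtype=bool)
    if not len(query) or not len(subject):
        return out
    by_chrom = {}
    sub = subject.sort_values(["chrom", "start"], kind="mergesort")
    for chrom, grp in sub.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        run_max_end = np.maximum.accumulate(grp["end"].to_numpy(np.int64))
        by_chrom[chrom] = (starts, run_max_end)
    qc = query["chrom"].to_numpy()
    qs = query["start"].to_numpy(dtype=np.int64)
    qe = query["end"].to_numpy(dtype=np.int64)
    for chrom, (starts, run_max_end) in by_chrom.items():
        idx = np.flatnonzero(qc == chrom)
        if not idx.size:
            continue
        hi = np.searchsorted(starts, qe[idx], side="left")
        has = hi > 0
        hit = np.zeros(idx.size, dtype=bool)
        hit[has] = run_max_end[hi[has] - 1] > qs[idx[has]]
        out[idx] = hit
    return out


def first_overlap_index(query: pd.DataFrame, subject: pd.DataFrame,
                        max_backscan: int = 64) -> np.ndarray:
    """Index into ``subject`` of one interval overlapping each query (-1 if
    none). Exact when subject intervals are (near-)non-overlapping, as peak
    sets are; deeply nested subjects beyond the backscan bound may be
    missed."""
    out = np.full(len(query), -1, dtype=np.int64)
    if not len(query) or not len(subject):
        return out
    sub = subject.sort_values(["chrom", "start"], kind="mergesort")
    qc = query["chrom"].to_numpy()
    qs = query["start"].to_numpy(dtype=np.int64)
    qe = query["end"].to_numpy(dtype=np.int64)
    for chrom, grp in sub.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        local_orig = grp.index.to_numpy()
        idx = np.flatnonzero(qc == chrom)
        if not idx.size:
            continue
        hi = np.searchsorted(starts, qe[idx], side="left")
        for qi, h in zip(idx, hi):
            for k in range(h - 1, max(-1, h - 1 - max_backscan), -1):
                if ends[k] > qs[qi]:
                    out[qi] = local_orig[k]
                    break
    return out


@dataclass
class SignalTrack:
    """Fixed-binsize genome-wide signal (bedGraph-backed).

    ``values[chrom][i]`` is raw nonnegative signal in bin
    ``[i*binsize, (i+1)*binsize)``; ``scale_factor`` (e.g. a spike-in
    factor) is applied on access via :meth:`scaled`.
    """

    binsize: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.binsize <= 0:
            raise ValueError("binsize must be positive")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        for chrom, length in self.chrom_lengths.items():
            n = -(-length // self.binsize)
            v = np.asarray(self.values[chrom], dtype=float)
            if len(v) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(v)}")
            if np.any(v < 0):
                raise ValueError(f"{chrom}: negative signal values")
            self.values[chrom] = v

    def scaled(self, chrom: str) -> np.ndarray:
        return self.values[chrom] * self.scale_factor

    def mean(self) -> float:
        """Genome-wide mean of scaled signal."""
        total = sum(v.sum() for v in self.values.values())
        nbins = sum(len(v) for v in self.values.values())
        return float(total * self.scale_factor / nbins)

    def value_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Scaled signal at base positions (vectorized)."""
        return self.scaled(chrom)[np.asarray(pos) // self.binsize]


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware, width-1 TSS and an optional tag set."""

    gene_id: str
    tss: GenomicInterval
    body: GenomicInterval
    tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.tss) != 1:
            raise ValueError("tss must have width 1")
        if not (self.body.start <= self.tss.start < self.body.end):
            raise ValueError("tss must lie within gene body")
        if self.tss.chrom != self.body.chrom:
            raise ValueError("tss and body on different chromosomes")

    @property
    def tss_pos(self) -> int:
        return self.tss.start

    @property
    def length(self) -> int:
        return len(self.body)


def make_gene(gene_id: str, chrom: str, strand: str, start: int, end: int,
              tags: Iterable[str] = ()) -> GeneModel:
    """Build a GeneModel placing the TSS at the strand-appropriate end."""
    tss_pos = start if strand == "+" else end - 1
    return GeneModel(
        gene_id=gene_id,
        tss=GenomicInterval(chrom, tss_pos, tss_pos + 1, strand),
        body=GenomicInterval(chrom, start, end, strand),
        tags=frozenset(tags),
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into a sorted peak frame.

    Column 5 (``score``), when present, is read as the peak signal.
    Raises :class:`ParseError` naming the offending line on malformed
    coordinates.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-integer coordinates") from None
            if end <= start or start < 0 or not chrom:
                raise ParseError(
                    f"line {lineno}: invalid interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else "."
            signal = np.nan
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    signal = float(parts[4])
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: non-numeric score") from None
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, signal, strand))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    return df.sort_values(["chrom", "start", "end"],
                          kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame | PeakSet, path: str | Path) -> None:
    """Write a peak frame (or PeakSet) as BED6; NaN signal written as 0."""
    if isinstance(df, PeakSet):
        df = df.df
    out = df.copy()
    if "name" not in out:
        out["name"] = "."
    if "signal" not in out:
        out["signal"] = 0.0
    if "strand" not in out:
        out["strand"] = "."
    out["signal"] = out["signal"].fillna(0.0)
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path, binsize: int,
                  chrom_lengths: Mapping[str, int],
                  scale_factor: float = 1.0) -> SignalTrack:
    """Read a fixed-binsize bedGraph into a SignalTrack.

    Every record must align to the binsize grid; missing bins are zero.
    """
    values = {c: np.zeros(-(-l // binsize))
              for c, l in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"line {lineno}: expected 4 columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in values:
                continue
            if s % binsize:
                raise ParseError(
                    f"line {lineno}: start {s} off the {binsize}-bp grid")
            if v < 0:
                raise ParseError(f"line {lineno}: negative signal")
            b0, b1 = s // binsize, -(-e // binsize)
            values[chrom][b0:b1] = v
    return SignalTrack(binsize=binsize, chrom_lengths=dict(chrom_lengths),
                       values=values, scale_factor=scale_factor)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a SignalTrack's raw (unscaled) values; zero bins omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            length = track.chrom_lengths[chrom]
            for i in np.flatnonzero(v != 0):
                s = int(i) * track.binsize
                e = min(s + track.binsize, length)
                fh.write(f"{chrom}\t{s}\t{e}\t{v[i]:.6g}\n")


GENE_TSV_COLUMNS = ["gene_id", "chrom", "strand", "tss_pos", "start", "end",
                    "tags"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a TSV gene table (gene_id, chrom, strand, tss_pos, start, end,
    tags with comma-joined labels)."""
    df = pd.read_csv(path, sep="\t", dtype={"tags": str})
    missing = set(GENE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"gene table missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        tags = frozenset(
            t for t in str(row.tags).split(",")
            if t and t != "nan") if pd.notna(row.tags) else frozenset()
        tss_pos = int(row.tss_pos)
        genes.append(GeneModel(
            gene_id=str(row.gene_id),
            tss=GenomicInterval(row.chrom, tss_pos, tss_pos + 1, row.strand),
            body=GenomicInterval(row.chrom, int(row.start), int(row.end),
                                 row.strand),
            tags=tags,
        ))
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = [(g.gene_id, g.body.chrom, g.body.strand, g.tss_pos,
             g.body.start, g.body.end, ",".join(sorted(g.tags)))
            for g in genes]
    pd.DataFrame(rows, columns=GENE_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Meta-profiles
# ---------------------------------------------------------------------------

class EmptyProfileError(ValueError):
    """All centers fell outside usable chromosome range."""


def meta_profile(track: SignalTrack, centers, flank_bp: int,
                 profile_binsize: int):
    """Mean signal around interval centers, +/- flank_bp.

    Each profile bin k covers offsets
    ``[-flank_bp + k*profile_binsize, -flank_bp + (k+1)*profile_binsize)``
    relative to the interval center; the entry is the mean (over centers)
    of the track value sampled at the bin midpoint. Centers whose full
    flank would leave the chromosome are dropped and counted.

    Returns ``(profile, n_used, n_dropped)`` with
    ``len(profile) == 2*flank_bp // profile_binsize``.
    """
    if flank_bp % profile_binsize:
        raise ValueError("flank_bp must be a multiple of profile_binsize")
    if isinstance(centers, PeakSet):
        cframe = centers.centers()
    elif isinstance(centers, pd.DataFrame) and "pos" in centers.columns:
        cframe = centers
    else:
        rows = [(iv.chrom, iv.center) for iv in centers]
        cframe = pd.DataFrame(rows, columns=["chrom", "pos"])
    if not len(cframe):
        raise EmptyProfileError("no centers supplied")

    nbins = 2 * flank_bp // profile_binsize
    offsets = (-flank_bp + np.arange(nbins) * profile_binsize
               + profile_binsize // 2)
    total = np.zeros(nbins)
    n_used = 0
    n_dropped = 0
    for chrom, grp in cframe.groupby("chrom", sort=False):
        if chrom not in track.chrom_lengths:
            n_dropped += len(grp)
            continue
        length = track.chrom_lengths[chrom]
        pos = grp["pos"].to_numpy(dtype=np.int64)
        ok = (pos - flank_bp >= 0) & (pos + flank_bp <= length)
        n_dropped += int((~ok).sum())
        pos = pos[ok]
        if not pos.size:
            continue
        grid = pos[:, None] + offsets[None, :]          # (n, nbins)
        vals = track.scaled(chrom)[grid // track.binsize]
        total += vals.sum(axis=0)
        n_used += pos.size
    if n_used == 0:
        raise EmptyProfileError(
            f"all {n_dropped} centers out of usable range")
    return total / n_used, n_used, n_dropped
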