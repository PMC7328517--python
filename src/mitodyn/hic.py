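"""Contact-matrix construction and 3D-genome statistics.

Everything operates on per-chromosome dense symmetric matrices (desk-scale
genomes stay well under a thousand bins per chromosome): iterative
balancing, distance-decay expected and O/E, compartment eigenvector with an
explicit orientation anchor, quantile saddle plots, insulation-score
boundary detection, aggregate loop (APA) intensity, and meta-profiles of
peak sets around boundaries. Analysis is intra-chromosomal only; trans
records are parsed and ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core_io import GenomicInterval, PeakSet, SignalTrack, meta_profile

DEFAULT_BINSIZE = 25_000
DEFAULT_INSULATION_WINDOW = 10       # bins
DEFAULT_BOUNDARY_PROMINENCE = 0.2    # log2 units
DEFAULT_SADDLE_QUANTILES = 30
DEFAULT_SADDLE_CORNER = 5            # quantiles per corner
DEFAULT_APA_WINDOW = 10              # bins each side of a loop pixel
BAD_BIN_QUANTILE = 0.02              # of nonzero marginals


class BalanceError(RuntimeError):
    """Matrix balancing failed to converge (carries the last residual)."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"balancing did not converge in {max_iter} iterations "
            f"(row-sum residual {residual:.3g})")


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact counts for one chromosome."""

    chrom: str
    binsize: int
    counts: np.ndarray
    weights: np.ndarray | None = None
    bad_bins: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.counts, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("counts must be square")
        if not np.allclose(m, m.T):
            raise ValueError("counts must be symmetric")
        if (m < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = m
        if self.bad_bins is None:
            self.bad_bins = np.zeros(len(m), dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def balanced(self) -> np.ndarray:
        """w_i * w_j * M_ij with bad bins set to NaN."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; call balance() first")
        b = self.counts * np.outer(self.weights, self.weights)
        b[self.bad_bins, :] = np.nan
        b[:, self.bad_bins] = np.nan
        return b


def bin_contacts(records: pd.DataFrame, binsize: int, chrom: str,
                 chrom_length: int) -> ContactMatrix:
    """Accumulate pair or COO records into a symmetric matrix.

    ``records`` is either a pairs frame (``chrom1,pos1,chrom2,pos2``) or a
    COO frame (``bin_i,bin_j,count``). Trans pairs are skipped; the
    diagonal is counted once. Positions beyond the chromosome raise with
    the offending record index.
    """
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    n = -(-chrom_length // binsize)
    m = np.zeros((n, n))
    if {"pos1", "pos2"}.issubset(records.columns):
        rec = records
        if "chrom1" in rec.columns:
            rec = rec[(rec["chrom1"] == chrom) & (rec["chrom2"] == chrom)]
        p1 = rec["pos1"].to_numpy(dtype=np.int64)
        p2 = rec["pos2"].to_numpy(dtype=np.int64)
        bad = (p1 < 0) | (p2 < 0) | (p1 >= chrom_length) | (p2 >= chrom_length)
        if bad.any():
            idx = rec.index[bad][0]
            raise ValueError(f"record {idx}: position beyond {chrom} "
                             f"length {chrom_length}")
        bi, bj = p1 // binsize, p2 // binsize
        cnt = np.ones(len(bi))
    elif {"bin_i", "bin_j", "count"}.issubset(records.columns):
        rec = records
        if "chrom" in rec.columns:
            rec = rec[rec["chrom"] == chrom]
        bi = rec["bin_i"].to_numpy(dtype=np.int64)
        bj = rec["bin_j"].to_numpy(dtype=np.int64)
        cnt = rec["count"].to_numpy(dtype=float)
        bad = (bi < 0) | (bj < 0) | (bi >= n) | (bj >= n)
        if bad.any():
            idx = rec.index[bad][0]
            raise ValueError(f"record {idx}: bin beyond {chrom} ({n} bins)")
    else:
        raise ValueError("records need pos1/pos2 or bin_i/bin_j/count columns")
    lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
    np.add.at(m, (lo, hi), cnt)
    upper = np.triu(m, k=1)
    m = m + upper.T  # symmetrize; diagonal counted once
    return ContactMatrix(chrom=chrom, binsize=binsize, counts=m)


def balance(cm: ContactMatrix, max_iter: int = 500,
            tol: float = 1e-8) -> np.ndarray:
    """Iterative proportional fitting to unit row sums over good bins.

    Bins whose raw marginal falls below the ``BAD_BIN_QUANTILE`` quantile
    of nonzero marginals (or is zero) are masked bad and excluded from
    every downstream statistic. Sinkhorn updates with geometric damping;
    stores weights on the matrix and returns them.
    """
    m = cm.counts
    marg = m.sum(axis=1)
    nz = marg[marg > 0]
    if nz.size == 0:
        raise BalanceError(np.inf, 0)
    # mask only genuinely sparse bins: the low-marginal quantile guards
    # divergence, but on a well-covered matrix the bottom percentiles are
    # healthy bins (boundary-adjacent bins legitimately run low), so the
    # cutoff never exceeds a fixed fraction of the median
    cutoff = min(np.quantile(nz, BAD_BIN_QUANTILE),
                 0.2 * float(np.median(nz)))
    bad = (marg <= 0) | (marg < cutoff)
    good = ~bad
    mg = m[np.ix_(good, good)]
    w = np.ones(good.sum())
    residual = np.inf
    for _ in range(max_iter):
        s = w * (mg @ w)
        residual = float(np.max(np.abs(s - 1.0)))
        if residual < tol:
            break
        w_new = 1.0 / (mg @ w)
        w = np.sqrt(w * w_new)
    else:
        raise BalanceError(residual, max_iter)
    weights = np.zeros(cm.n_bins)
    weights[good] = w
    cm.weights = weights
    cm.bad_bins = bad
    return weights


def observed_expected(cm: ContactMatrix):
    """O/E matrix and the per-distance expected vector.

    expected(d) is the mean of balanced entries at bin distance d over
    good-bin pairs; every O/E diagonal therefore has mean exactly 1.
    Distances with no good pairs (or zero expected) are NaN-masked.
    """
    b = cm.balanced()
    n = cm.n_bins
    expected = np.full(n, np.nan)
    oe = np.full((n, n), np.nan)
    for d in range(n):
        diag = np.diagonal(b, offset=d)
        finite = np.isfinite(diag)
        if not finite.any():
            continue
        e = float(diag[finite].mean())
        expected[d] = e
        if e <= 0:
            continue
        idx = np.arange(n - d)
        oe[idx, idx + d] = diag / e
        oe[idx + d, idx] = diag / e
    return oe, expected


@dataclass
class CompartmentProfile:
    """Per-bin compartment score (leading PC of the O/E correlation)."""

    eigenvector: np.ndarray
    orientation_anchor: str
    no_compartments: bool = False


def compartment_eigenvector(oe: np.ndarray, orientation: np.ndarray,
                            anchor_name: str = "orientation_track"
                            ) -> CompartmentProfile:
    """Leading principal component of the O/E Pearson-correlation matrix.

    The eigen-solver's arbitrary global sign is fixed by requiring
    positive correlation with the supplied orientation track (gene
    density in real data; the planted A-compartment indicator in
    synthetic runs). A near-constant O/E yields a flagged all-zero
    profile rather than a noise vector.
    """
    n = oe.shape[0]
    good = np.isfinite(oe).sum(axis=1) > n // 2
    if good.sum() < 10:
        raise ValueError("fewer than 10 good bins; cannot call compartments")
    sub = oe[np.ix_(good, good)].copy()
    # fill residual NaNs (masked distances) with the column mean
    col_mean = np.nanmean(sub, axis=0)
    nan_pos = np.where(np.isnan(sub))
    sub[nan_pos] = np.take(col_mean, nan_pos[1])
    if float(np.nanstd(sub)) < 1e-10:
        return CompartmentProfile(np.zeros(n), anchor_name,
                                  no_compartments=True)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    if not np.isfinite(corr).all():
        corr = np.nan_to_num(corr, nan=0.0)
    vals, vecs = np.linalg.eigh(corr)
    # the raw leading eigenvector keeps per-bin signs faithful even when
    # one compartment dominates; centering would push the majority class
    # across zero
    v = vecs[:, -1]
    ev = np.full(n, np.nan)
    ev[good] = v
    ori = np.asarray(orientation, dtype=float)[good]
    if np.std(ori) > 0 and np.std(v) > 0:
        if np.corrcoef(v, ori)[0, 1] < 0:
            ev = -ev
    return CompartmentProfile(ev, anchor_name)


def saddle(oe: np.ndarray, profile: np.ndarray,
           n_quantiles: int = DEFAULT_SADDLE_QUANTILES,
           corner: int = DEFAULT_SADDLE_CORNER):
    """Quantile-by-quantile mean O/E grid plus corner summaries.

    Good bins are ranked by the compartment score (ascending: B first)
    and split into ``n_quantiles`` equal groups; grid[a, b] is the mean
    O/E between groups a and b. Corner scores average the ``corner`` x
    ``corner`` extreme-quantile blocks: BB = low-low, AA = high-high,
    AB = the two off corners.
    """
    profile = np.asarray(profile, dtype=float)
    good = np.flatnonzero(np.isfinite(profile))
    if good.size < n_quantiles:
        raise ValueError(
            f"{good.size} good bins < {n_quantiles} quantiles")
    # scatter rank ties with a fixed permutation: a discrete profile
    # (e.g. a +/-1 labeling) would otherwise produce index-contiguous
    # quantile groups whose corner blocks are all short-range pairs,
    # picking up balancing edge artifacts instead of compartment signal
    tiebreak = np.random.default_rng(0).permutation(good.size)
    order = good[np.lexsort((tiebreak, profile[good]))]
    groups = np.array_split(order, n_quantiles)
    grid = np.full((n_quantiles, n_quantiles), np.nan)
    for a in range(n_quantiles):
        for b in range(a, n_quantiles):
            block = oe[np.ix_(groups[a], groups[b])]
            finite = np.isfinite(block)
            if finite.any():
                grid[a, b] = grid[b, a] = float(block[finite].mean())
    c = corner
    corners = {
        "BB": float(np.nanmean(grid[:c, :c])),
        "AA": float(np.nanmean(grid[-c:, -c:])),
        "AB": float(np.nanmean(np.concatenate(
            [grid[:c, -c:].ravel(), grid[-c:, :c].ravel()]))),
    }
    return grid, corners


@dataclass
class InsulationProfile:
    """Per-bin insulation score with detected boundaries."""

    scores: np.ndarray                 # log2 ratio; NaN near edges
    boundaries: np.ndarray             # bin indices of local minima
    strengths: np.ndarray              # prominence per boundary (log2 units)
    window_bins: int = DEFAULT_INSULATION_WINDOW

    def boundary_positions(self, binsize: int) -> np.ndarray:
        """Boundary midpoints in bp."""
        return (self.boundaries * binsize + binsize // 2).astype(np.int64)


def insulation(cm: ContactMatrix,
               window_bins: int = DEFAULT_INSULATION_WINDOW,
               prominence: float = DEFAULT_BOUNDARY_PROMINENCE
               ) -> InsulationProfile:
    """Diamond insulation score and boundary calls.

    score(i) = log2(mean balanced contacts in the window x window square
    just crossing the diagonal at bin i / the chromosome-wide mean of such
    squares). Boundaries are local minima with prominence >= threshold.
    Adding a constant to all contacts leaves relative dips intact (the
    score is a ratio).
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    n = cm.n_bins
    if n < 2 * window_bins + 1:
        raise ValueError("chromosome shorter than twice the window")
    b = cm.balanced()
    w = window_bins
    # the square spans rows [i-w, i) x cols [i, i+w): contacts crossing the
    # left edge of bin i, so a domain edge at bin i is the unique minimum
    raw = np.full(n, np.nan)
    for i in range(w, n - w + 1):
        square = b[i - w:i, i:i + w]
        finite = np.isfinite(square)
        if finite.any():
            raw[i] = float(square[finite].mean())
    overall = np.nanmean(raw)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.log2(raw / overall)
    finite = np.isfinite(scores)
    filled = np.where(finite, scores, np.nanmax(scores))
    # prominence judged within a local neighborhood so chromosome-scale
    # compartment undulation cannot promote shallow dips to boundaries
    peaks, props = find_peaks(-filled, prominence=prominence,
                              wlen=4 * w + 1)
    keep = finite[peaks]
    return InsulationProfile(scores=scores, boundaries=peaks[keep],
                             strengths=props["prominences"][keep],
                             window_bins=w)


# ---------------------------------------------------------------------------
# Loops
# ---------------------------------------------------------------------------

@dataclass
class LoopSet:
    """Pairs of cis loop anchors (anchor1 strictly upstream of anchor2)."""

    loops: list[tuple[GenomicInterval, GenomicInterval]] = field(
        default_factory=list)

    def __post_init__(self) -> None:
        for a1, a2 in self.loops:
            if a1.chrom != a2.chrom:
                raise ValueError("trans loops are rejected")
            if a1.start >= a2.start:
                raise ValueError("anchor1 must be upstream of anchor2")

    def __len__(self) -> int:
        return len(self.loops)

    def anchor_bins(self, chrom: str, binsize: int) -> np.ndarray:
        out = [(a1.center // binsize, a2.center // binsize)
               for a1, a2 in self.loops if a1.chrom == chrom]
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def read_bedpe(path: str | Path) -> LoopSet:
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 6:
                raise ValueError(f"line {lineno}: BEDPE needs 6 columns")
            a1 = GenomicInterval(p[0], int(p[1]), int(p[2]))
            a2 = GenomicInterval(p[3], int(p[4]), int(p[5]))
            loops.append((a1, a2))
    return LoopSet(loops)


def write_bedpe(loopset: LoopSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a1, a2 in loopset.loops:
            fh.write(f"{a1.chrom}\t{a1.start}\t{a1.end}"
                     f"\t{a2.chrom}\t{a2.start}\t{a2.end}\n")


def loop_apa(oe: np.ndarray, loopset: LoopSet, chrom: str, binsize: int,
             window_bins: int = DEFAULT_APA_WINDOW):
    """Aggregate O/E submatrix over loop anchor pairs.

    Loops closer than twice the window to the diagonal (or with a window
    leaving the matrix) are dropped and counted. Returns
    ``(apa_matrix, intensity, center_corner_ratio, n_used, n_dropped)``;
    intensity is the center-pixel mean — the loop intensity.
    """
    n = oe.shape[0]
    w = window_bins
    pairs = loopset.anchor_bins(chrom, binsize)
    stack = []
    n_dropped = 0
    for b1, b2 in pairs:
        if b2 - b1 < 2 * w or b1 - w < 0 or b2 + w >= n:
            n_dropped += 1
            continue
        stack.append(oe[b1 - w:b1 + w + 1, b2 - w:b2 + w + 1])
    if not stack:
        raise ValueError("no usable loops (all short-range or off-matrix)")
    with np.errstate(invalid="ignore"):
        apa = np.nanmean(np.stack(stack), axis=0)
    intensity = float(apa[w, w])
    q = max(1, w // 2)
    corner_mean = float(np.nanmean(np.concatenate([
        apa[:q, :q].ravel(), apa[:q, -q:].ravel(),
        apa[-q:, :q].ravel(), apa[-q:, -q:].ravel()])))
    ratio = intensity / corner_mean if corner_mean > 0 else np.nan
    return apa, intensity, ratio, len(stack), n_dropped


def boundary_peak_profile(peaks: PeakSet | SignalTrack,
                          boundary_positions: Mapping[str, Sequence[int]],
                          chrom_lengths: Mapping[str, int],
                          flank_bp: int = 250_000,
                          profile_binsize: int = 25_000):
    """Mean peak density (or track signal) versus distance from boundaries.

    A PeakSet is first rendered as a center-count density track at the
    profile binsize; a SignalTrack is profiled as-is. Boundary midpoints
    act as meta-profile centers.
    """
    if isinstance(peaks, PeakSet):
        values = {c: np.zeros(-(-l // profile_binsize))
                  for c, l in chrom_lengths.items()}
        for chrom, grp in peaks.centers().groupby("chrom", sort=False):
            if chrom not in values:
                continue
            bins = grp["pos"].to_numpy(dtype=np.int64) // profile_binsize
            np.add.at(values[chrom], bins, 1.0)
        track = SignalTrack(binsize=profile_binsize,
                            chrom_lengths=dict(chrom_lengths), values=values)
    else:
        track = peaks
    rows = [(chrom, int(p)) for chrom, plist in boundary_positions.items()
            for p in plist]
    centers = pd.DataFrame(rows, columns=["chrom", "pos"])
    return meta_profile(track, centers, flank_bp, profile_binsize)


# ---------------------------------------------------------------------------
# COO I/O
# ---------------------------------------------------------------------------

def read_coo(path: str | Path) -> pd.DataFrame:
    """Read contact triples TSV: chrom, bin_i, bin_j, count."""
    return pd.read_csv(path, sep="\t",
                       names=["chrom", "bin_i", "bin_j", "count"],
                       dtype={"chrom": str, "bin_i": np.int64,
                              "bin_j": np.int64, "count": float})


def write_coo(cm: ContactMatrix, path: str | Path, mode: str = "w") -> None:
    """Write the upper triangle (incl. diagonal) as COO triples."""
    iu = np.triu_indices(cm.n_bins)
    vals = cm.counts[iu]
    nz = vals != 0
    df = pd.DataFrame({"chrom": cm.chrom, "bin_i": iu[0][nz],
                       "bin_j": iu[1][nz], "count": vals[nz]})
    df.to_csv(path, sep="\t", header=False, index=False, mode=mode)
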