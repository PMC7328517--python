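"""Synthetic inputs with planted, recoverable structure.

Every pipeline stage can be verified by parameter recovery against a
:class:`SyntheticTruth`: per-mark peak retention and gain fractions across
mitotic phases, a global-signal-loss condition visible only through
spike-ins, gene first-activation times with two spiked control RNAs, and
contact maps that interpolate between a distance-decay-only mitotic state
and a structured interphase state with planted compartments, TADs and
loops.

Layout is element-anchored: genes get promoter H3K4me3 (+H3K27ac) peaks at
their TSS; TSS-distal elements carry H3K4me1 alone (primed enhancers) or
H3K4me1 + H3K27ac (active enhancers); CTCF peaks are biased toward TAD
boundaries. Per-phase peak sets are exact-size uniform subsamples of the
interphase set plus novel non-overlapping gains, so planted fractions are
recoverable to sampling accuracy.

All randomness flows from one integer seed through named substreams, so
the same seed gives byte-identical outputs regardless of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    make_gene,
    write_bed,
    write_bedgraph,
    write_gene_table,
)
from .hic import ContactMatrix, LoopSet, write_bedpe, write_coo
from .spikein import SpikeCounts

MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "CTCF")
PHASES = ("interphase", "prometaphase", "ana_telo")

# substream ids; rng = default_rng([seed, stream, *extra])
_STREAMS = {
    "layout": 0, "peaks": 1, "tracks": 2, "expression": 3,
    "contacts": 4, "dysregulation": 5, "signals": 6,
}

# mitotic retention/gain of interphase peaks, per mark. Methylation marks
# persist on mitotic chromatin (98% of promoters keep H3K4me3 in
# prometaphase) while H3K27ac is nearly erased and regains from
# anaphase/telophase with many novel boundary-biased sites; CTCF is
# largely evicted in prometaphase and partially rebound by ana/telo.
DEFAULT_RETENTION = {
    "H3K4me3": {"prometaphase": 0.98, "ana_telo": 0.96},
    "H3K4me1": {"prometaphase": 0.90, "ana_telo": 0.95},
    "H3K27ac": {"prometaphase": 0.02, "ana_telo": 0.87},
    "CTCF": {"prometaphase": 0.20, "ana_telo": 0.56},
}
DEFAULT_GAIN = {
    "H3K4me3": {"prometaphase": 0.01, "ana_telo": 0.02},
    "H3K4me1": {"prometaphase": 0.02, "ana_telo": 0.03},
    "H3K27ac": {"prometaphase": 0.01, "ana_telo": 0.30},
    "CTCF": {"prometaphase": 0.02, "ana_telo": 0.10},
}
# genome-wide occupancy vs interphase (what only spike-ins can see)
DEFAULT_GLOBAL_RATIO = {
    "H3K4me3": {"interphase": 1.0, "prometaphase": 0.95, "ana_telo": 1.0},
    "H3K4me1": {"interphase": 1.0, "prometaphase": 0.90, "ana_telo": 1.0},
    "H3K27ac": {"interphase": 1.0, "prometaphase": 0.20, "ana_telo": 1.10},
    "CTCF": {"interphase": 1.0, "prometaphase": 0.30, "ana_telo": 0.70},
}

# structure coefficient per Hi-C time point (min after mitotic release):
# near zero through anaphase/telophase, reforming from cytokinesis and
# essentially complete between 90 and 120 min.
DEFAULT_MIXING = {"0": 0.0, "35": 0.05, "60": 0.4, "90": 0.7,
                  "120": 0.9, "180": 0.95, "360": 1.0}

# first-activation class mix: a small mitotic cohort, a large wave at
# 60 min (cytokinesis) covering ~88% cumulatively, and a tail of late
# and asynchronous-only genes.
DEFAULT_ACTIVATION_MIX = {"0": 0.035, "35": 0.19, "60": 0.655,
                          "90": 0.05, "120": 0.03, "180": 0.02,
                          "async": 0.02}

EXPRESSION_CV = 0.2          # lognormal noise on expression means
CONTROL_MASSES = (0.36, 0.036)   # ng of spiked control RNAs, 10:1
COUNT_SCALE = 5.0            # counts per (FPKM-unit x kb x depth)
CONTROL_SCALE = 2e5          # control counts per ng per unit depth
SPIKE_CHIP_READS = 500_000   # exogenous-genome reads per unit depth
ENDO_CHIP_READS = 2_000_000  # endogenous reads per unit depth at ratio 1

DEFAULT_TAD_BOOST = 1.0
DEFAULT_COMP_BOOST = 0.4
DEFAULT_LOOP_ENRICHMENT = 3.0
DEFAULT_HIC_DEPTH = 400.0    # expected counts at distance 0 scale

# dysregulation mixture on inhibiting mitotic acetylation (prometaphase)
DEFAULT_DYSREG_FRACTIONS = {"down": 0.48, "up": 0.08}


class CapacityError(RuntimeError):
    """Genome too small to place the requested non-overlapping intervals."""


@dataclass
class SyntheticTruth:
    """Planted generator parameters — the recovery oracle for all stages."""

    seed: int
    genome: dict[str, int]
    hic_binsize: int
    retention: dict[str, dict[str, float]]
    gain: dict[str, dict[str, float]]
    global_signal_ratio: dict[str, dict[str, float]]
    mixing: dict[str, float]
    tad_boost: float
    comp_boost: float
    loop_enrichment: float
    hic_depth: float
    genes: list[GeneModel] = field(repr=False, default_factory=list)
    gene_mu: pd.Series = field(repr=False, default=None)
    activation_time: pd.Series = field(repr=False, default=None)
    elements: pd.DataFrame = field(repr=False, default=None)
    interphase_peaks: dict[str, pd.DataFrame] = field(
        repr=False, default_factory=dict)
    tad_id: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    boundary_positions: dict[str, np.ndarray] = field(
        repr=False, default_factory=dict)
    compartment_sign: dict[str, np.ndarray] = field(
        repr=False, default_factory=dict)
    loops: LoopSet = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for table in (self.retention, self.gain):
            for mark, by_phase in table.items():
                for ph, f in by_phase.items():
                    if not 0.0 <= f <= 1.0:
                        raise ValueError(
                            f"{mark}/{ph}: fraction {f} outside [0,1]")
        vals = [self.mixing[k] for k in sorted(self.mixing, key=float)]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("mixing must be nondecreasing over time points")

    def rng(self, stream: str, *extra: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.seed % (2**31), _STREAMS[stream], *extra])

    @property
    def gene_lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length for g in self.genes})


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

_GRID = 250  # bp occupancy-grid resolution; conservative non-overlap


class _Occupancy:
    """Coarse per-chromosome occupancy grid for non-overlapping placement."""

    def __init__(self, genome: dict[str, int]):
        self.grid = {c: np.zeros(-(-l // _GRID) + 1, dtype=bool)
                     for c, l in genome.items()}
        self.genome = genome

    def free(self, chrom: str, start: int, end: int) -> bool:
        g = self.grid[chrom]
        return not g[start // _GRID:(end - 1) // _GRID + 1].any()

    def take(self, chrom: str, start: int, end: int) -> None:
        self.grid[chrom][start // _GRID:(end - 1) // _GRID + 1] = True


def _place_distal(rng, truth_genome, occ: _Occupancy, forbidden: _Occupancy,
                  n: int, width_lo=500, width_hi=2000,
                  bias_positions=None, bias_prob=0.0, bias_jitter=20_000,
                  max_tries=200) -> pd.DataFrame:
    """Place n non-overlapping intervals, optionally biased toward given
    (chrom, pos) anchor positions. Raises CapacityError when the genome
    cannot hold them."""
    chroms = list(truth_genome)
    lengths = np.array([truth_genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    rows = []
    for _ in range(n):
        placed = False
        for _try in range(max_tries):
            if bias_positions is not None and rng.random() < bias_prob:
                k = rng.integers(len(bias_positions))
                chrom, anchor = bias_positions[k]
                center = int(anchor + rng.integers(-bias_jitter,
                                                   bias_jitter + 1))
            else:
                chrom = chroms[rng.choice(len(chroms), p=probs)]
                center = int(rng.integers(0, truth_genome[chrom]))
            width = int(rng.integers(width_lo, width_hi + 1))
            start = center - width // 2
            end = start + width
            if start < 0 or end > truth_genome[chrom]:
                continue
            if not (occ.free(chrom, start, end)
                    and forbidden.free(chrom, start, end)):
                continue
            occ.take(chrom, start, end)
            rows.append((chrom, start, end))
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place interval {len(rows) + 1} of {n} after "
                f"{max_tries} tries; genome too crowded")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def make_truth(seed: int,
               genome: dict[str, int] | None = None,
               hic_binsize: int = 25_000,
               n_genes: int = 1200,
               n_active_enhancers: int = 900,
               n_primed_enhancers: int = 900,
               n_extra_k27ac: int = 200,
               n_ctcf: int = 800,
               n_tagged_genes: int = 113,
               tag_label: str = "bone_specific",
               tag_enrichment_at_0: float = 3.0,
               retention=None, gain=None, global_signal_ratio=None,
               mixing=None,
               activation_mix=None,
               tad_boost: float = DEFAULT_TAD_BOOST,
               comp_boost: float = DEFAULT_COMP_BOOST,
               loop_enrichment: float = DEFAULT_LOOP_ENRICHMENT,
               hic_depth: float = DEFAULT_HIC_DEPTH,
               n_loops_per_chrom: int = 40,
               ctcf_boundary_bias: float = 0.4) -> SyntheticTruth:
    """Build the full planted layout for one synthetic study.

    The default desk genome is two 20-Mb chromosomes at 25-kb Hi-C bins;
    element counts scale to it. Larger studies (more genes/elements) pass
    a proportionally larger genome.
    """
    if genome is None:
        genome = {"chr1": 20_000_000, "chr2": 20_000_000}
    truth = SyntheticTruth(
        seed=seed, genome=dict(genome), hic_binsize=hic_binsize,
        retention=retention or {m: dict(v) for m, v in
                                DEFAULT_RETENTION.items()},
        gain=gain or {m: dict(v) for m, v in DEFAULT_GAIN.items()},
        global_signal_ratio=global_signal_ratio or {
            m: dict(v) for m, v in DEFAULT_GLOBAL_RATIO.items()},
        mixing=mixing or dict(DEFAULT_MIXING),
        tad_boost=tad_boost, comp_boost=comp_boost,
        loop_enrichment=loop_enrichment, hic_depth=hic_depth,
    )
    rng = truth.rng("layout")
    mix = activation_mix or dict(DEFAULT_ACTIVATION_MIX)

    # --- TADs, boundaries, compartments, loops (per chromosome) ---
    loops = []
    for chrom, length in genome.items():
        n_bins = length // hic_binsize
        edges = [0]
        while edges[-1] < n_bins:
            edges.append(edges[-1] + int(rng.integers(20, 61)))
        edges[-1] = n_bins
        if edges[-1] - edges[-2] < 10 and len(edges) > 2:
            del edges[-2]
        tad_id = np.zeros(n_bins, dtype=int)
        for k, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
            tad_id[a:b] = k
        truth.tad_id[chrom] = tad_id
        truth.boundary_positions[chrom] = (
            np.asarray(edges[1:-1], dtype=np.int64) * hic_binsize)
        # compartment sign is constant within a TAD and flips between
        # TADs with persistence, so sign changes sit on TAD boundaries
        n_tads = len(edges) - 1
        tad_sign = np.empty(n_tads, dtype=int)
        tad_sign[0] = 1 if rng.random() < 0.5 else -1
        for k in range(1, n_tads):
            flip = rng.random() < 0.3
            tad_sign[k] = -tad_sign[k - 1] if flip else tad_sign[k - 1]
        if (tad_sign == tad_sign[0]).all():  # force both compartments
            tad_sign[n_tads // 2:] = -tad_sign[0]
        truth.compartment_sign[chrom] = tad_sign[tad_id]
        # loops: cis anchor pairs well off the diagonal and off edges
        w = 12
        if n_bins <= 2 * w + 27:  # chromosome too short to host loops
            continue
        for _ in range(n_loops_per_chrom):
            for _try in range(100):
                b1 = int(rng.integers(w, n_bins - w - 26))
                sep = int(rng.integers(25, 151))
                b2 = b1 + sep
                if b2 + w < n_bins:
                    break
            a1 = GenomicInterval(chrom, b1 * hic_binsize,
                                 (b1 + 1) * hic_binsize)
            a2 = GenomicInterval(chrom, b2 * hic_binsize,
                                 (b2 + 1) * hic_binsize)
            loops.append((a1, a2))
    truth.loops = LoopSet(loops)

    # --- genes on a jittered lattice, strand random ---
    occ = _Occupancy(genome)
    forbidden = _Occupancy(genome)  # TSS-proximal zone, distal elements keep out
    total_len = sum(genome.values())
    genes = []
    gid = 0
    for chrom, length in genome.items():
        n_c = max(1, round(n_genes * length / total_len))
        spacing = length / (n_c + 1)
        for k in range(n_c):
            pos = int((k + 1) * spacing + rng.integers(-spacing // 4,
                                                       spacing // 4 + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(1000, 10001))
            if strand == "+":
                start, end = pos, min(pos + glen, length)
            else:
                start, end = max(0, pos - glen), pos
            if end - start < 1000:
                continue
            g = make_gene(f"G{gid:05d}", chrom, strand, start, end)
            genes.append(g)
            gid += 1
            forbidden.take(chrom, max(0, g.tss_pos - 5000),
                           min(length, g.tss_pos + 5000))
    # --- promoter peaks at TSS (H3K4me3 + H3K27ac) ---
    prom_rows = []
    for g in genes:
        width = int(rng.integers(500, 2001))
        jitter = int(rng.integers(-300, 301))
        start = max(0, g.tss_pos + jitter - width // 2)
        end = min(genome[g.tss.chrom], start + width)
        prom_rows.append((g.tss.chrom, start, end, "promoter", g.gene_id))
        occ.take(g.tss.chrom, start, end)
    prom = pd.DataFrame(
        prom_rows, columns=["chrom", "start", "end", "klass", "gene_id"])

    # --- distal enhancers ---
    ae = _place_distal(rng, genome, occ, forbidden, n_active_enhancers)
    ae["klass"] = "active_enhancer"
    pe = _place_distal(rng, genome, occ, forbidden, n_primed_enhancers)
    pe["klass"] = "primed_enhancer"
    extra_ac = _place_distal(rng, genome, occ, forbidden, n_extra_k27ac)

    boundary_anchors = [(c, int(p)) for c, ps in
                        truth.boundary_positions.items() for p in ps]
    ctcf = _place_distal(rng, genome, occ, forbidden, n_ctcf,
                         bias_positions=boundary_anchors,
                         bias_prob=ctcf_boundary_bias, bias_jitter=8000)

    elements = pd.concat([prom, ae.assign(gene_id=None),
                          pe.assign(gene_id=None)], ignore_index=True)
    truth.elements = elements
    truth.genes = genes

    # interphase peak tables per mark (element-anchored)
    cols = ["chrom", "start", "end"]
    truth.interphase_peaks = {
        "H3K4me3": prom[cols].copy(),
        "H3K4me1": pd.concat([ae[cols], pe[cols]], ignore_index=True),
        "H3K27ac": pd.concat([prom[cols], ae[cols], extra_ac[cols]],
                             ignore_index=True),
        "CTCF": ctcf[cols].copy(),
    }

    # --- expression program ---
    gene_ids = [g.gene_id for g in genes]
    classes = list(mix)
    p = np.array([mix[c] for c in classes], dtype=float)
    p /= p.sum()
    truth.activation_time = pd.Series(
        rng.choice(classes, size=len(gene_ids), p=p), index=gene_ids)
    truth.gene_mu = pd.Series(
        np.exp(rng.normal(np.log(8.0), 0.6, size=len(gene_ids))),
        index=gene_ids)
    # tag genes (e.g. bone-specific) enriched among the 0-min class
    w = np.where(truth.activation_time.to_numpy() == "0",
                 tag_enrichment_at_0, 1.0)
    n_tag = min(n_tagged_genes, len(gene_ids))
    tagged = rng.choice(len(gene_ids), size=n_tag, replace=False,
                        p=w / w.sum())
    tagged_set = {gene_ids[i] for i in tagged}
    truth.genes = [
        GeneModel(g.gene_id, g.tss, g.body,
                  frozenset({tag_label}) if g.gene_id in tagged_set
                  else frozenset())
        for g in genes
    ]
    return truth


# ---------------------------------------------------------------------------
# ChIP-seq peaks + spike-ins
# ---------------------------------------------------------------------------

def _peak_signals(truth: SyntheticTruth, mark: str, phase: str,
                  df: pd.DataFrame, rng) -> np.ndarray:
    """Per-peak normalized densities; promoter peaks couple to expression."""
    ratio = truth.global_signal_ratio[mark][phase]
    base = np.exp(rng.normal(0.5, 0.6, size=len(df)))
    if mark in ("H3K4me3", "H3K27ac") and len(df):
        # couple promoter-peak strength to the gene's expression level
        prom = truth.elements[truth.elements["klass"] == "promoter"]
        key_to_gene = {(r.chrom, r.start): r.gene_id
                       for r in prom.itertuples(index=False)}
        mu = truth.gene_mu
        z = (np.log(mu) - np.log(8.0)) / 0.6
        rho = 0.6
        for i, r in enumerate(df.itertuples(index=False)):
            gid = key_to_gene.get((r.chrom, r.start))
            if gid is not None:
                base[i] = np.exp(0.5 + 0.6 * (rho * z[gid]
                                 + np.sqrt(1 - rho**2) * rng.normal()))
    return base * ratio


def gen_peaks(truth: SyntheticTruth, mark: str, phase: str
              ) -> tuple[PeakSet, SpikeCounts]:
    """Peak set and ChIP spike-in counts for one (mark, phase).

    The phase set holds round(retention * N) uniformly chosen interphase
    peaks plus round(gain * N) novel non-overlapping peaks (ana/telo
    H3K27ac gains are biased toward TAD boundaries). Spike-in count pairs
    are drawn so the endogenous/exogenous ratio tracks the planted global
    occupancy ratio.
    """
    mark_i, phase_i = MARKS.index(mark), PHASES.index(phase)
    rng = truth.rng("peaks", mark_i, phase_i)
    inter = truth.interphase_peaks[mark]
    n = len(inter)
    if phase == "interphase":
        df = inter.copy()
    else:
        r = truth.retention[mark][phase]
        g = truth.gain[mark][phase]
        keep = np.sort(rng.choice(n, size=round(r * n), replace=False))
        df = inter.iloc[keep].reset_index(drop=True)
        n_gain = round(g * n)
        if n_gain:
            occ = _Occupancy(truth.genome)
            for row in inter.itertuples(index=False):
                occ.take(row.chrom, row.start, row.end)
            none = _Occupancy(truth.genome)
            bias = None
            bias_prob = 0.0
            if mark == "H3K27ac" and phase == "ana_telo":
                bias = [(c, int(p)) for c, ps in
                        truth.boundary_positions.items() for p in ps]
                bias_prob = 0.5
            gains = _place_distal(rng, truth.genome, occ, none, n_gain,
                                  bias_positions=bias, bias_prob=bias_prob,
                                  bias_jitter=12_000)
            df = pd.concat([df, gains], ignore_index=True)
    sig_rng = truth.rng("signals", mark_i, phase_i)
    df = df.copy()
    df["name"] = "."
    df["signal"] = _peak_signals(truth, mark, phase, df, sig_rng)
    df["strand"] = "."
    peaks = PeakSet(df, mark=mark, phase=phase)

    depth = float(rng.uniform(0.5, 2.0))
    ratio = truth.global_signal_ratio[mark][phase]
    spikes = SpikeCounts(
        sample_id=f"{mark}_{phase}", phase=phase, mark=mark,
        endo_reads=int(rng.poisson(ENDO_CHIP_READS * ratio * depth)),
        spike_reads=int(rng.poisson(SPIKE_CHIP_READS * depth)),
    )
    return peaks, spikes


def gen_signal_tracks(truth: SyntheticTruth, mark: str,
                      binsize: int = 1000,
                      phases=PHASES
                      ) -> dict[str, tuple[SignalTrack, SpikeCounts]]:
    """Binned raw read-density tracks emulating a uniform global loss.

    Interphase occupancy is background plus peak enrichment over the
    interphase peak set; each other phase's true occupancy is the planted
    global ratio times the interphase pattern. Raw tracks are Poisson
    reads at an arbitrary per-sample depth, so only the paired spike-in
    counts can recover the ratio.
    """
    mark_i = MARKS.index(mark)
    rng = truth.rng("tracks", mark_i)
    occupancy = {}
    for chrom, length in truth.genome.items():
        nb = -(-length // binsize)
        occ = np.full(nb, 0.5)  # background density
        occupancy[chrom] = occ
    for row in truth.interphase_peaks[mark].itertuples(index=False):
        b0, b1 = row.start // binsize, -(-row.end // binsize)
        occupancy[row.chrom][b0:b1] += 8.0
    out = {}
    for phase in phases:
        ratio = truth.global_signal_ratio[mark][phase]
        depth = float(rng.uniform(0.5, 2.0))
        values = {c: rng.poisson(occ * ratio * depth).astype(float)
                  for c, occ in occupancy.items()}
        track = SignalTrack(binsize=binsize,
                            chrom_lengths=dict(truth.genome), values=values)
        total_occ = sum(o.sum() for o in occupancy.values())
        spikes = SpikeCounts(
            sample_id=f"{mark}_{phase}", phase=phase, mark=mark,
            endo_reads=int(rng.poisson(total_occ * ratio * depth)),
            spike_reads=int(rng.poisson(SPIKE_CHIP_READS * depth)),
        )
        out[phase] = (track, spikes)
    return out


# ---------------------------------------------------------------------------
# EU-RNA expression
# ---------------------------------------------------------------------------

def gen_expression(truth: SyntheticTruth):
    """Gene x time-point raw nascent counts plus spiked control counts.

    Counts are zero before a gene's planted first-activation time and
    lognormal-mean Poisson from it onward; the asynchronous library
    expresses every gene. Two control RNAs enter at a fixed 10:1 mass
    ratio with deterministic (high-count) reads proportional to per-sample
    depth; depth factors span 5x to force spike-in correction.

    Returns ``(counts, gene_lengths, spike_counts, samples)``.
    """
    if len(truth.genes) < 100:
        raise ValueError("need >= 100 genes for an expression study")
    rng = truth.rng("expression")
    gene_ids = [g.gene_id for g in truth.genes]
    lengths = truth.gene_lengths
    sample_ids = ["t0", "t35", "t60", "t90", "t120", "t180", "async"]
    time_points = ["0", "35", "60", "90", "120", "180", "async"]
    depths = np.geomspace(0.5, 2.5, len(sample_ids))
    rng.shuffle(depths)
    sigma = np.sqrt(np.log(1 + EXPRESSION_CV**2))

    act = truth.activation_time
    mu = truth.gene_mu
    len_kb = lengths / 1000.0
    counts = {}
    for sid, tp, depth in zip(sample_ids, time_points, depths):
        if tp == "async":
            active = np.ones(len(gene_ids), dtype=bool)
        else:
            t = int(tp)
            timed = act.to_numpy() != "async"
            first = np.where(timed,
                             [int(a) if a != "async" else 10**9
                              for a in act.to_numpy()], 10**9)
            active = first <= t
        mean = np.where(
            active,
            mu.to_numpy() * len_kb.reindex(gene_ids).to_numpy()
            * COUNT_SCALE * depth
            * np.exp(rng.normal(-sigma**2 / 2, sigma, len(gene_ids))),
            0.0)
        counts[sid] = rng.poisson(mean)
    counts_df = pd.DataFrame(counts, index=gene_ids)
    spike_df = pd.DataFrame(
        {sid: [round(CONTROL_MASSES[0] * CONTROL_SCALE * d),
               round(CONTROL_MASSES[1] * CONTROL_SCALE * d)]
         for sid, d in zip(sample_ids, depths)},
        index=["control1", "control2"])
    samples = pd.DataFrame({"time_point": time_points,
                            "treatment": "control"}, index=sample_ids)
    return counts_df, lengths, spike_df, samples


def gen_dysregulation(truth: SyntheticTruth,
                      fractions: dict[str, float] | None = None,
                      n_genes: int | None = None):
    """Paired control/treated FPKM with a planted dysregulation mixture.

    Planted effects are well separated from the |log2FC| = 1 decision
    boundary (downs in [-4.5, -2.2], ups in [2.2, 4.5], no-change in
    [-0.4, 0.4]) with lognormal measurement noise (CV 0.2) on both
    members of the pair. Returns ``(control, treated, labels)`` Series.
    """
    fr = fractions or dict(DEFAULT_DYSREG_FRACTIONS)
    rng = truth.rng("dysregulation")
    if n_genes is None:
        n_genes = len(truth.genes)
    gene_ids = [f"G{k:05d}" for k in range(n_genes)]
    u = rng.random(n_genes)
    labels = np.where(u < fr["down"], "down",
                      np.where(u < fr["down"] + fr["up"], "up", "no_change"))
    delta = np.where(labels == "down", rng.uniform(-4.5, -2.2, n_genes),
                     np.where(labels == "up", rng.uniform(2.2, 4.5, n_genes),
                              rng.uniform(-0.4, 0.4, n_genes)))
    base = np.exp(rng.normal(np.log(20.0), 0.6, n_genes))
    sigma = np.sqrt(np.log(1 + EXPRESSION_CV**2))
    noise = lambda: np.exp(rng.normal(-sigma**2 / 2, sigma, n_genes))  # noqa: E731
    control = pd.Series(base * noise(), index=gene_ids)
    treated = pd.Series(base * 2.0**delta * noise(), index=gene_ids)
    return control, treated, pd.Series(labels, index=gene_ids)


# ---------------------------------------------------------------------------
# Hi-C contacts
# ---------------------------------------------------------------------------

def expected_contacts(truth: SyntheticTruth, chrom: str,
                      mixing: float) -> np.ndarray:
    """Noise-free expected count matrix for one chromosome.

    expected = depth * P(d) * [1 + mixing * (tad + comp boosts)]
               * [1 + mixing * (e - 1)] at loop anchor pixels,
    with P(d) = (1 + d)^-1, tad boost inside planted blocks and compartment
    boost between same-sign bins. The loop factor multiplies the local
    structural background so the planted enrichment e is exactly what an
    aggregate O/E analysis should read back at the loop pixel.
    """
    n = len(truth.tad_id[chrom])
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    pd_decay = 1.0 / (1.0 + d)
    tid = truth.tad_id[chrom]
    same_tad = tid[:, None] == tid[None, :]
    sign = truth.compartment_sign[chrom]
    same_sign = sign[:, None] == sign[None, :]
    boost = (truth.tad_boost * same_tad
             + truth.comp_boost * same_sign).astype(float)
    lam = truth.hic_depth * pd_decay * (1.0 + mixing * boost)
    loop_factor = 1.0 + mixing * (truth.loop_enrichment - 1.0)
    for b1, b2 in truth.loops.anchor_bins(chrom, truth.hic_binsize):
        lam[b1, b2] *= loop_factor
        lam[b2, b1] *= loop_factor
    return lam


def gen_contacts(truth: SyntheticTruth, timepoint: str | None = None,
                 mixing: float | None = None,
                 depth_scale: float = 1.0) -> dict[str, ContactMatrix]:
    """Poisson-sampled binned contact maps for one time point.

    Pass either a named time point (looked up in ``truth.mixing``) or an
    explicit mixing coefficient in [0, 1]; ``depth_scale`` multiplies
    sequencing depth without touching structure.
    """
    if mixing is None:
        if timepoint is None:
            raise ValueError("need timepoint or mixing")
        mixing = truth.mixing[str(timepoint)]
    stream_key = int(round(1000 * mixing))
    out = {}
    for ci, chrom in enumerate(truth.genome):
        if truth.genome[chrom] % truth.hic_binsize:
            raise ValueError(
                f"{chrom}: binsize must divide chromosome length")
        rng = truth.rng("contacts", ci, stream_key,
                        int(round(1000 * depth_scale)))
        lam = expected_contacts(truth, chrom, mixing) * depth_scale
        n = lam.shape[0]
        iu = np.triu_indices(n)
        draws = rng.poisson(lam[iu]).astype(float)
        m = np.zeros((n, n))
        m[iu] = draws
        m = m + np.triu(m, k=1).T
        out[chrom] = ContactMatrix(chrom=chrom, binsize=truth.hic_binsize,
                                   counts=m)
    return out


# ---------------------------------------------------------------------------
# file export
# ---------------------------------------------------------------------------

def truth_summary(truth: SyntheticTruth) -> dict:
    """JSON-serializable record of every planted parameter."""
    return {
        "seed": truth.seed,
        "genome": truth.genome,
        "hic_binsize": truth.hic_binsize,
        "retention": truth.retention,
        "gain": truth.gain,
        "global_signal_ratio": truth.global_signal_ratio,
        "mixing": truth.mixing,
        "tad_boost": truth.tad_boost,
        "comp_boost": truth.comp_boost,
        "loop_enrichment": truth.loop_enrichment,
        "boundary_positions": {c: [int(p) for p in ps]
                               for c, ps in truth.boundary_positions.items()},
        "compartment_sign": {c: [int(s) for s in ss]
                             for c, ss in truth.compartment_sign.items()},
        "loops": [[a1.chrom, a1.start, a1.end, a2.start, a2.end]
                  for a1, a2 in truth.loops.loops],
        "n_genes": len(truth.genes),
        "n_elements": int(len(truth.elements)),
        "activation_counts": truth.activation_time.value_counts().to_dict(),
    }


def write_all(truth: SyntheticTruth, outdir: str | Path,
              timepoints=("0", "60", "360")) -> dict[str, Path]:
    """Write every pipeline input format plus the truth JSON.

    Emits per-(mark, phase) BED peaks, a spike-count TSV, the gene table,
    expression counts + control counts + sample sheet TSVs, per-time-point
    COO contact triples, loop BEDPE, boundary BED and truth.json. Returns
    the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    spike_rows = []
    for mark in MARKS:
        for phase in PHASES:
            peaks, spikes = gen_peaks(truth, mark, phase)
            p = outdir / f"peaks_{mark}_{phase}.bed"
            write_bed(peaks, p)
            paths[f"peaks_{mark}_{phase}"] = p
            spike_rows.append((spikes.sample_id, mark, phase,
                               spikes.endo_reads, spikes.spike_reads))
    spike_df = pd.DataFrame(spike_rows, columns=[
        "sample_id", "mark", "phase", "endo_reads", "spike_reads"])
    paths["chip_spikes"] = outdir / "chip_spikes.tsv"
    spike_df.to_csv(paths["chip_spikes"], sep="\t", index=False)

    paths["genes"] = outdir / "genes.tsv"
    write_gene_table(truth.genes, paths["genes"])

    # raw acetylation tracks: the global-loss condition spike-ins resolve
    track_rows = []
    for phase, (track, tsp) in gen_signal_tracks(truth, "H3K27ac").items():
        p = outdir / f"track_H3K27ac_{phase}.bedgraph"
        write_bedgraph(track, p)
        paths[f"track_H3K27ac_{phase}"] = p
        track_rows.append((tsp.sample_id, tsp.mark, tsp.phase,
                           tsp.endo_reads, tsp.spike_reads))
    paths["track_spikes"] = outdir / "track_spikes.tsv"
    pd.DataFrame(track_rows, columns=[
        "sample_id", "mark", "phase", "endo_reads", "spike_reads"
    ]).to_csv(paths["track_spikes"], sep="\t", index=False)

    counts, lengths, spikes, samples = gen_expression(truth)
    paths["eu_counts"] = outdir / "eu_counts.tsv"
    counts.rename_axis("gene_id").to_csv(paths["eu_counts"], sep="\t")
    paths["eu_controls"] = outdir / "eu_controls.tsv"
    spikes.rename_axis("control").to_csv(paths["eu_controls"], sep="\t")
    paths["eu_samples"] = outdir / "eu_samples.tsv"
    samples.rename_axis("sample_id").to_csv(paths["eu_samples"], sep="\t")
    paths["activation_truth"] = outdir / "activation_truth.tsv"
    truth.activation_time.rename("first_active").rename_axis(
        "gene_id").to_csv(paths["activation_truth"], sep="\t")

    for tp in timepoints:
        matrices = gen_contacts(truth, timepoint=tp)
        p = outdir / f"contacts_t{tp}.coo.tsv"
        first = True
        for cm in matrices.values():
            write_coo(cm, p, mode="w" if first else "a")
            first = False
        paths[f"contacts_t{tp}"] = p

    paths["loops"] = outdir / "loops.bedpe"
    write_bedpe(truth.loops, paths["loops"])
    with open(outdir / "boundaries.bed", "w") as fh:
        for chrom, ps in truth.boundary_positions.items():
            for p in ps:
                fh.write(f"{chrom}\t{int(p) - truth.hic_binsize // 2}"
                         f"\t{int(p) + truth.hic_binsize // 2}\n")
    paths["boundaries"] = outdir / "boundaries.bed"

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth_summary(truth), fh, indent=1)
    return paths
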