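"""Spike-in ChIP-seq normalization and cross-phase peak accounting.

Adding a fixed amount of exogenous chromatin to every ChIP sample makes
global occupancy changes measurable: read-depth normalization alone maps
every library onto the same total and hides genome-wide loss (e.g. of
H3K27ac on prometaphase chromatin). Scale factors here are ratios of
exogenous-genome read counts relative to a reference sample, so that equal
true occupancy yields equal scaled signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import PeakSet, overlap_any


@dataclass(frozen=True)
class SpikeCounts:
    """Read counts for one ChIP library: endogenous vs exogenous genome."""

    sample_id: str
    phase: str
    mark: str
    endo_reads: int
    spike_reads: int


@dataclass
class RetentionReport:
    """Cross-phase retention of reference-phase peaks.

    ``three_way`` (when two comparison sets are given) maps Venn region
    labels — e.g. ``"100"`` = reference only, ``"111"`` = all three —
    to counts over a reference-priority deduplicated union, so region
    counts sum to the union size.
    """

    n_reference: int
    n_other: int
    n_overlap: int
    three_way: dict[str, int] | None = None

    @property
    def pct_retained(self) -> float:
        if self.n_reference == 0:
            return 0.0
        return 100.0 * self.n_overlap / self.n_reference

    @property
    def pct_retained_display(self) -> int:
        """Percentage rounded half-up to an integer, for display."""
        import math
        return int(math.floor(self.pct_retained + 0.5))


def spike_scale_factors(samples: Sequence[SpikeCounts],
                        reference_id: str) -> dict[str, float]:
    """Per-sample scale factor = spike_reads(reference) / spike_reads(sample).

    The reference gets factor 1; a sample sequenced twice as deep (twice
    the spike reads) gets factor 0.5, so scaled signal reflects true
    occupancy per unit of input chromatin.
    """
    by_id = {s.sample_id: s for s in samples}
    if reference_id not in by_id:
        raise ValueError(f"reference sample {reference_id!r} not in list")
    for s in samples:
        if s.spike_reads <= 0:
            raise ValueError(
                f"sample {s.sample_id!r} has zero spike-in reads; "
                "cannot normalize")
    ref = by_id[reference_id].spike_reads
    return {s.sample_id: ref / s.spike_reads for s in samples}


def _check_marks(*sets: PeakSet) -> None:
    marks = {s.mark for s in sets if s.mark is not None}
    if len(marks) > 1:
        raise ValueError(f"mark mismatch across peak sets: {sorted(marks)}")


def retention_report(reference: PeakSet, other: PeakSet,
                     other2: PeakSet | None = None) -> RetentionReport:
    """How many reference-phase peaks are detected in the other phase(s).

    Overlap is >= 1 bp; a reference peak overlapping several peaks in the
    other set counts once (reference coordinate space). With two
    comparison sets the full three-way Venn is filled over a union built
    by reference-priority deduplication: all reference peaks, plus
    other-set peaks not overlapping the reference, plus second-set peaks
    overlapping neither.
    """
    _check_marks(reference, other, *( [other2] if other2 else [] ))
    ref_df, oth_df = reference.df, other.df
    ref_hits = overlap_any(ref_df, oth_df)
    report = RetentionReport(
        n_reference=len(ref_df),
        n_other=len(oth_df),
        n_overlap=int(ref_hits.sum()),
    )
    if other2 is None:
        return report

    o2_df = other2.df
    # union representatives, priority reference > other > other2
    in_a = np.concatenate([
        np.ones(len(ref_df), dtype=bool),
        np.zeros(len(oth_df), dtype=bool),
        np.zeros(len(o2_df), dtype=bool),
    ])
    oth_new = oth_df[~overlap_any(oth_df, ref_df)]
    o2_new = o2_df[~(overlap_any(o2_df, ref_df) | overlap_any(o2_df, oth_df))]
    union = pd.concat([ref_df, oth_new, o2_new], ignore_index=True)
    memb_a = np.r_[np.ones(len(ref_df), bool), np.zeros(len(oth_new), bool),
                   np.zeros(len(o2_new), bool)]
    memb_b = overlap_any(union, oth_df)
    memb_b[len(ref_df):len(ref_df) + len(oth_new)] = True
    memb_c = overlap_any(union, o2_df)
    memb_c[len(ref_df) + len(oth_new):] = True
    three_way: dict[str, int] = {}
    for a in (1, 0):
        for b in (1, 0):
            for c in (1, 0):
                if not (a or b or c):
                    continue
                mask = (memb_a == bool(a)) & (memb_b == bool(b)) \
                    & (memb_c == bool(c))
                three_way[f"{a}{b}{c}"] = int(mask.sum())
    report.three_way = three_way
    return report


def phase_categories(inter: PeakSet, at: PeakSet) -> pd.DataFrame:
    """Partition interphase + anaphase/telophase peaks into three categories.

    Returns a frame with columns ``chrom, start, end, category`` where
    category is ``shared`` (interphase peaks overlapping ana/telo —
    interphase coordinates are reported), ``interphase_specific`` or
    ``ana_telo_specific``.
    """
    _check_marks(inter, at)
    cols = ["chrom", "start", "end"]
    inter_hits = overlap_any(inter.df, at.df)
    at_hits = overlap_any(at.df, inter.df)
    shared = inter.df.loc[inter_hits, cols].assign(category="shared")
    ispec = inter.df.loc[~inter_hits, cols].assign(
        category="interphase_specific")
    atspec = at.df.loc[~at_hits, cols].assign(category="ana_telo_specific")
    out = pd.concat([shared, ispec, atspec], ignore_index=True)
    return out.sort_values(cols, kind="mergesort").reset_index(drop=True)


def category_fractions(categories: pd.DataFrame) -> dict[str, float]:
    """Fractions of the union in each phase category (sum to 1)."""
    n = len(categories)
    counts = categories["category"].value_counts()
    return {
        lab: float(counts.get(lab, 0)) / n if n else 0.0
        for lab in ("shared", "interphase_specific", "ana_telo_specific")
    }


def scaled_mean_ratio(track_sample, track_reference,
                      factors: Mapping[str, float],
                      sample_id: str, reference_id: str) -> float:
    """Genome-wide mean signal ratio sample/reference after spike scaling.

    Recovers the true global occupancy ratio that per-million scaling
    hides (both tracks must carry raw, unscaled values).
    """
    s_mean = track_sample.mean() * factors[sample_id]
    r_mean = track_reference.mean() * factors[reference_id]
    return s_mean / r_mean


def naive_mean_ratio(track_sample, track_reference) -> float:
    """Same ratio under naive per-million scaling (each track's total
    signal rescaled to a fixed constant) — the comparison spike-ins exist
    to correct. On a shared genome this is identically 1 regardless of any
    true global change."""
    s_total = sum(v.sum() for v in track_sample.values.values())
    r_total = sum(v.sum() for v in track_reference.values.values())
    s_bins = sum(len(v) for v in track_sample.values.values())
    r_bins = sum(len(v) for v in track_reference.values.values())
    return float((s_total / s_total / s_bins) / (r_total / r_total / r_bins))
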