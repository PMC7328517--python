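"""Cis-regulatory element classification and per-phase chromatin states.

Elements are defined from interphase marks: promoters are H3K4me3 peaks
whose center lies within a TSS window; TSS-distal H3K4me1 peaks are
enhancers — active (AE) when they overlap an interphase H3K27ac peak,
primed (PE) otherwise. The H3K4me1 peak anchors enhancer identity so
elements stay stable when acetylation is lost in prometaphase; H3K27ac
contributes state only. State in any phase is recomputed per mark by
>= 1 bp overlap with that phase's peak set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GeneModel, PeakSet, overlap_any

KLASSES = ("promoter", "active_enhancer", "primed_enhancer")

# per-class state categories for the transition table, most-active first
STATE_CATEGORIES = {
    "promoter": ("K4me3+K27ac", "K4me3 only", "none"),
    "active_enhancer": ("K27ac+K4me1", "K4me1 only", "none"),
    "primed_enhancer": ("K4me1", "none"),
}

DEFAULT_TSS_WINDOW = 2000


class ConfigurationError(ValueError):
    """A required mark peak set is missing."""


@dataclass
class CisElement:
    chrom: str
    start: int
    end: int
    klass: str
    state: dict[str, frozenset] = field(default_factory=dict)
    nearest_gene: str | None = None
    nearest_distance: int | None = None

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def _tss_frame(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "chrom": [g.tss.chrom for g in genes],
        "pos": [g.tss_pos for g in genes],
    })


def _min_tss_distance(df: pd.DataFrame, tss: pd.DataFrame) -> np.ndarray:
    """Distance from each peak center to the nearest TSS (inf off-chrom)."""
    out = np.full(len(df), np.inf)
    centers = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    chroms = df["chrom"].to_numpy()
    for chrom, grp in tss.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        idx = np.flatnonzero(chroms == chrom)
        if not idx.size or not pos.size:
            continue
        c = centers[idx]
        j = np.searchsorted(pos, c)
        left = np.where(j > 0, np.abs(c - pos[np.maximum(j - 1, 0)]), np.inf)
        right = np.where(j < len(pos), np.abs(pos[np.minimum(j, len(pos) - 1)]
                                              - c), np.inf)
        out[idx] = np.minimum(left, right)
    return out


def classify_elements(peaks_by_mark: dict[str, PeakSet],
                      genes: list[GeneModel],
                      tss_window_bp: int = DEFAULT_TSS_WINDOW
                      ) -> list[CisElement]:
    """Classify interphase peaks into promoter / AE / PE.

    ``peaks_by_mark`` must contain interphase H3K4me3, H3K4me1 and
    H3K27ac sets. The partition is exclusive: a peak is a promoter or an
    enhancer, never both; every TSS-distal H3K4me1 peak is exactly one of
    AE/PE.
    """
    for mark in ("H3K4me3", "H3K4me1", "H3K27ac"):
        if mark not in peaks_by_mark:
            raise ConfigurationError(f"missing interphase {mark} peak set")
    tss = _tss_frame(genes)
    elements: list[CisElement] = []

    k4me3 = peaks_by_mark["H3K4me3"].df
    d3 = _min_tss_distance(k4me3, tss)
    for row, dist in zip(k4me3.itertuples(index=False), d3):
        if dist <= tss_window_bp:
            elements.append(CisElement(row.chrom, int(row.start),
                                       int(row.end), "promoter"))

    k4me1 = peaks_by_mark["H3K4me1"].df
    d1 = _min_tss_distance(k4me1, tss)
    distal = d1 > tss_window_bp
    has_ac = overlap_any(k4me1, peaks_by_mark["H3K27ac"].df)
    for row, is_distal, ac in zip(k4me1.itertuples(index=False), distal,
                                  has_ac):
        if not is_distal:
            continue
        klass = "active_enhancer" if ac else "primed_enhancer"
        elements.append(CisElement(row.chrom, int(row.start), int(row.end),
                                   klass))
    return elements


def _elements_frame(elements: list[CisElement]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [e.chrom for e in elements],
        "start": [e.start for e in elements],
        "end": [e.end for e in elements],
    })


def annotate_states(elements: list[CisElement],
                    peaks: dict[str, dict[str, PeakSet]]) -> None:
    """Fill ``element.state[phase]`` with the set of marks present.

    ``peaks[mark][phase]`` gives the peak set; a mark is present in a
    phase iff the element overlaps that phase's peak set by >= 1 bp
    (independently per mark).
    """
    if not elements:
        return
    edf = _elements_frame(elements)
    phases = {ph for by_phase in peaks.values() for ph in by_phase}
    hits = {
        (mark, ph): overlap_any(edf, peaks[mark][ph].df)
        for mark in peaks for ph in peaks[mark]
    }
    for i, el in enumerate(elements):
        for ph in phases:
            el.state[ph] = frozenset(
                mark for mark in peaks
                if ph in peaks[mark] and hits[(mark, ph)][i])


def _state_category(klass: str, marks: frozenset) -> str:
    if klass == "promoter":
        if "H3K4me3" in marks and "H3K27ac" in marks:
            return "K4me3+K27ac"
        if "H3K4me3" in marks:
            return "K4me3 only"
        return "none"
    if klass == "active_enhancer":
        if "H3K4me1" in marks and "H3K27ac" in marks:
            return "K27ac+K4me1"
        if "H3K4me1" in marks:
            return "K4me1 only"
        return "none"
    # primed enhancer
    return "K4me1" if "H3K4me1" in marks else "none"


def transition_table(elements: list[CisElement],
                     peaks: dict[str, dict[str, PeakSet]]) -> pd.DataFrame:
    """Per-class, per-phase fractions of elements in each state category.

    Rows are (klass, phase); fraction columns per category sum to 1.
    """
    annotate_states(elements, peaks)
    phases = sorted({ph for by_phase in peaks.values() for ph in by_phase})
    rows = []
    for klass in KLASSES:
        els = [e for e in elements if e.klass == klass]
        cats = STATE_CATEGORIES[klass]
        for ph in phases:
            row = {"klass": klass, "phase": ph, "n": len(els)}
            if els:
                labels = [_state_category(klass, e.state.get(ph, frozenset()))
                          for e in els]
                for cat in cats:
                    row[cat] = labels.count(cat) / len(els)
            else:
                for cat in cats:
                    row[cat] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def nearest_gene_assignment(elements: list[CisElement],
                            genes: list[GeneModel]) -> None:
    """Assign each element the gene with minimum |TSS - element center|.

    Ties break toward the lexicographically smaller gene_id. Fills
    ``nearest_gene`` / ``nearest_distance`` in place. Cross-chromosome
    genes are never assigned; elements on chromosomes with no gene keep
    None.
    """
    if not genes:
        raise ValueError("gene list is empty")
    tss = _tss_frame(genes)
    by_chrom = {}
    for chrom, grp in tss.groupby("chrom", sort=False):
        # sort by (pos, gene_id) so equal positions favor the smaller id
        grp = grp.sort_values(["pos", "gene_id"], kind="mergesort")
        by_chrom[chrom] = (grp["pos"].to_numpy(dtype=np.int64),
                           grp["gene_id"].to_numpy())
    for el in elements:
        if el.chrom not in by_chrom:
            el.nearest_gene = None
            el.nearest_distance = None
            continue
        pos, ids = by_chrom[el.chrom]
        c = el.center
        j = int(np.searchsorted(pos, c))
        best_id, best_d = None, None
        for k in range(max(0, j - 1), min(len(pos), j + 1) + 1):
            if k >= len(pos):
                continue
            d = abs(int(pos[k]) - c)
            if best_d is None or d < best_d or (d == best_d
                                                and ids[k] < best_id):
                best_id, best_d = ids[k], d
        # equal-distance ties can involve non-adjacent entries with the
        # same position; scan all entries at the winning distance
        lo = int(np.searchsorted(pos, c - best_d))
        hi = int(np.searchsorted(pos, c + best_d, side="right"))
        for k in range(lo, hi):
            d = abs(int(pos[k]) - c)
            if d == best_d and ids[k] < best_id:
                best_id = ids[k]
        el.nearest_gene = str(best_id)
        el.nearest_distance = int(best_d)


def bookmarked_gene_table(elements: list[CisElement],
                          genes: list[GeneModel],
                          phase: str = "prometaphase",
                          max_distance: int | None = None) -> pd.DataFrame:
    """Per-gene indicators of association with mitotically marked elements.

    A gene is mitotic-promoter-associated iff some element assigned to it
    (nearest-TSS) is a promoter retaining H3K4me3 in the given phase;
    mitotic-AE-associated iff an assigned AE retains H3K4me1 (with or
    without H3K27ac); analogously for PEs. ``annotate_states`` and
    ``nearest_gene_assignment`` must have run.
    """
    flags = {g.gene_id: {"mitotic_promoter": False, "mitotic_AE": False,
                         "mitotic_PE": False} for g in genes}
    for el in elements:
        if el.nearest_gene is None or el.nearest_gene not in flags:
            continue
        if max_distance is not None and el.nearest_distance > max_distance:
            continue
        marks = el.state.get(phase, frozenset())
        if el.klass == "promoter" and "H3K4me3" in marks:
            flags[el.nearest_gene]["mitotic_promoter"] = True
        elif el.klass == "active_enhancer" and "H3K4me1" in marks:
            flags[el.nearest_gene]["mitotic_AE"] = True
        elif el.klass == "primed_enhancer" and "H3K4me1" in marks:
            flags[el.nearest_gene]["mitotic_PE"] = True
    df = pd.DataFrame.from_dict(flags, orient="index")
    df.index.name = "gene_id"
    return df.reset_index()


def elements_to_frame(elements: list[CisElement]) -> pd.DataFrame:
    """Flat table of elements for TSV export."""
    rows = []
    for e in elements:
        row = {"chrom": e.chrom, "start": e.start, "end": e.end,
               "klass": e.klass, "nearest_gene": e.nearest_gene,
               "nearest_distance": e.nearest_distance}
        for ph, marks in sorted(e.state.items()):
            row[f"state_{ph}"] = ",".join(sorted(marks))
        rows.append(row)
    return pd.DataFrame(rows)
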