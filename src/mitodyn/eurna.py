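"""Spike-in-normalized nascent-RNA quantification and activation calling.

Nascent (EU pulse-labeled) RNA yield differs hugely between mitotic and
interphase cells, so per-million scaling erases the biology. Two spiked
control RNAs added at fixed mass (10:1 ratio) anchor a per-sample factor:
after scaling, both controls are constant across libraries. Expression is
reported on an FPKM-like scale — factor-scaled counts per kb of gene
length per million scaled reads, with the library-size constant taken
from the reference sample so genuine global shifts stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TIMED_POINTS = (0, 35, 60, 90, 120, 180)
ACTIVATION_CLASSES = ("0", "35", "60", "90", "120", "180", "async")

DEFAULT_THETA = 1.0
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass
class ExpressionTable:
    """Gene x sample normalized expression.

    ``fpkm`` is a genes x samples frame; ``samples`` carries per-sample
    metadata (``time_point`` in {0,35,60,90,120,180,'async'},
    ``treatment`` in {'control','A485'}); ``spike_norm_factor`` maps
    sample id -> the positive factor that was applied.
    """

    fpkm: pd.DataFrame
    samples: pd.DataFrame
    spike_norm_factor: dict[str, float]

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM must be nonnegative")
        for sid, f in self.spike_norm_factor.items():
            if f <= 0:
                raise ValueError(f"nonpositive factor for sample {sid!r}")

    def subset(self, treatment: str) -> "ExpressionTable":
        keep = self.samples.index[self.samples["treatment"] == treatment]
        return ExpressionTable(self.fpkm[keep], self.samples.loc[keep],
                               {k: self.spike_norm_factor[k] for k in keep})


def eu_normalize(raw_counts: pd.DataFrame, gene_lengths: pd.Series,
                 spike_counts: pd.DataFrame,
                 samples: pd.DataFrame,
                 reference: str | None = None) -> ExpressionTable:
    """Normalize raw nascent-RNA counts by two spiked control RNAs.

    ``raw_counts``: genes x samples integer counts. ``spike_counts``: a
    2 x samples frame (rows = the two controls) of control read counts.
    The per-sample factor is the geometric mean, over the two controls,
    of (control count in reference) / (control count in sample); using
    both spikes is robust to one outlier. FPKM uses the reference
    sample's scaled total as the library-size constant for every sample.
    """
    if reference is None:
        reference = raw_counts.columns[0]
    if spike_counts.shape[0] != 2:
        raise ValueError("expected exactly two spiked controls")
    zeros = spike_counts.columns[(spike_counts <= 0).any(axis=0)]
    if len(zeros):
        raise ValueError(
            f"zero spike-control counts in sample(s): {list(zeros)}")
    ref_spikes = spike_counts[reference]
    ratios = ref_spikes.to_numpy()[:, None] / spike_counts.to_numpy()
    factors = pd.Series(np.exp(np.log(ratios).mean(axis=0)),
                        index=spike_counts.columns)
    scaled = raw_counts * factors
    lib_constant = float(scaled[reference].sum())
    if lib_constant <= 0:
        raise ValueError("reference sample has zero scaled counts")
    len_kb = gene_lengths.reindex(raw_counts.index) / 1000.0
    fpkm = scaled.div(len_kb, axis=0) / (lib_constant / 1e6)
    return ExpressionTable(
        fpkm=fpkm, samples=samples,
        spike_norm_factor={c: float(factors[c]) for c in raw_counts.columns})


@dataclass(frozen=True)
class ActivationCall:
    gene_id: str
    first_active: str  # one of ACTIVATION_CLASSES, or "excluded"


def call_first_activation(table: ExpressionTable,
                          theta: float = DEFAULT_THETA) -> pd.DataFrame:
    """Earliest time point at which each gene's FPKM reaches theta.

    Uses control-treatment samples only. Genes below theta at every timed
    point but at or above theta in the asynchronous library are class
    'async'; genes never reaching theta anywhere are 'excluded' (reported,
    not silently dropped). Returns a frame with gene_id, first_active.
    """
    meta = table.samples
    ctrl = meta.index[meta["treatment"] == "control"]
    fpkm = table.fpkm[ctrl]
    tp = meta.loc[ctrl, "time_point"]

    timed_cols: dict[int, list] = {}
    async_cols = []
    for sid in ctrl:
        t = tp[sid]
        if t == "async":
            async_cols.append(sid)
        else:
            timed_cols.setdefault(int(t), []).append(sid)
    ordered = [t for t in TIMED_POINTS if t in timed_cols]

    n = len(fpkm)
    calls = np.full(n, "excluded", dtype=object)
    undecided = np.ones(n, dtype=bool)
    for t in ordered:
        level = fpkm[timed_cols[t]].mean(axis=1).to_numpy()
        hit = undecided & (level >= theta)
        calls[hit] = str(t)
        undecided &= ~hit
    if async_cols:
        level = fpkm[async_cols].mean(axis=1).to_numpy()
        hit = undecided & (level >= theta)
        calls[hit] = "async"
    return pd.DataFrame({"gene_id": fpkm.index, "first_active": calls})


@dataclass(frozen=True)
class DysregulationRecord:
    gene_id: str
    log2fc: float
    label: str  # down | up | no_change


def call_dysregulation(control: pd.Series, treated: pd.Series,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT,
                       fc_threshold: float = 1.0) -> pd.DataFrame:
    """Classify genes by log2((treated+c)/(control+c)).

    down iff log2fc < -threshold; up iff log2fc > threshold; otherwise
    no_change. Returns gene_id, log2fc, label.
    """
    control, treated = control.align(treated, join="inner")
    log2fc = np.log2((treated + pseudocount) / (control + pseudocount))
    label = np.where(log2fc < -fc_threshold, "down",
                     np.where(log2fc > fc_threshold, "up", "no_change"))
    return pd.DataFrame({"gene_id": control.index, "log2fc": log2fc.to_numpy(),
                         "label": label})


def dysregulation_fractions(records: pd.DataFrame) -> dict[str, float]:
    """Fractions per label; they sum to 1 over the classified genes."""
    n = len(records)
    counts = records["label"].value_counts()
    return {lab: float(counts.get(lab, 0)) / n if n else 0.0
            for lab in ("down", "up", "no_change")}
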