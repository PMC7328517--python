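"""End-to-end orchestration: configuration, stage sequencing, recovery report.

The demo pipeline synthesizes a full study (peaks, tracks, expression,
contacts) to disk, then runs every analysis stage *from those files* and
compares each recovered quantity against the planted truth at the stated
tolerance. All randomness flows from one seed; the same seed yields
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cisre, eurna, hic, integration, spikein, synthetic
from .core_io import (
    PeakSet,
    first_overlap_index,
    read_bed,
    read_bedgraph,
    read_gene_table,
)
from .spikein import SpikeCounts

logger = logging.getLogger(__name__)

MARKS = synthetic.MARKS
PHASES = synthetic.PHASES


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips through YAML losslessly."""

    seed: int = 0
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000})
    hic_binsize: int = 25_000
    tss_window: int = cisre.DEFAULT_TSS_WINDOW
    theta: float = eurna.DEFAULT_THETA
    pseudocount: float = eurna.DEFAULT_PSEUDOCOUNT
    insulation_window: int = hic.DEFAULT_INSULATION_WINDOW
    boundary_prominence: float = hic.DEFAULT_BOUNDARY_PROMINENCE
    saddle_quantiles: int = hic.DEFAULT_SADDLE_QUANTILES
    apa_window: int = hic.DEFAULT_APA_WINDOW
    flank_bp: int = 250_000
    profile_binsize: int = 25_000
    n_genes: int = 1200
    n_active_enhancers: int = 900
    n_primed_enhancers: int = 900
    hic_timepoints: tuple = ("0", "60", "360")
    outdir: str = "runs/demo"

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        for name in ("hic_binsize", "tss_window", "insulation_window",
                     "apa_window", "flank_bp", "profile_binsize", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.saddle_quantiles < 2:
            raise ValueError("saddle_quantiles must be >= 2")
        for chrom, length in self.genome.items():
            if length % self.hic_binsize:
                raise ValueError(
                    f"{chrom}: hic_binsize must divide chromosome length")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["hic_timepoints"] = list(self.hic_timepoints)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "hic_timepoints" in d:
            d["hic_timepoints"] = tuple(d["hic_timepoints"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def sha256(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = asdict(self)
        d["hic_timepoints"] = list(self.hic_timepoints)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RecoveryRow:
    name: str
    truth: float
    estimate: float
    tolerance: str
    passed: bool


@dataclass
class RecoveryReport:
    rows: list[RecoveryRow] = field(default_factory=list)

    def add(self, name: str, truth: float, estimate: float,
            tolerance: str, passed: bool) -> None:
        self.rows.append(RecoveryRow(name, float(truth), float(estimate),
                                     tolerance, bool(passed)))

    @property
    def overall_pass(self) -> bool:
        return all(r.passed for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    def to_json(self, path: str | Path, provenance: dict | None = None
                ) -> None:
        payload = {"overall_pass": self.overall_pass,
                   "rows": [asdict(r) for r in self.rows]}
        if provenance:
            payload["provenance"] = provenance
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _load_peaks(paths: dict, mark: str, phase: str) -> PeakSet:
    df = read_bed(paths[f"peaks_{mark}_{phase}"])
    return PeakSet(df, mark=mark, phase=phase)


def _match_boundaries(called_bins: np.ndarray, true_bins: np.ndarray,
                      slack: int = 1) -> tuple[float, float]:
    """(recall, precision) of called vs true boundary bins, +/- slack bins."""
    if not len(true_bins):
        return np.nan, np.nan
    hit_true = np.array([np.any(np.abs(called_bins - t) <= slack)
                         for t in true_bins]) if len(called_bins) else \
        np.zeros(len(true_bins), dtype=bool)
    hit_called = np.array([np.any(np.abs(true_bins - c) <= slack)
                           for c in called_bins]) if len(called_bins) else \
        np.array([], dtype=bool)
    recall = float(hit_true.mean())
    precision = float(hit_called.mean()) if len(called_bins) else 0.0
    return recall, precision


def element_signal_map(elements: list[cisre.CisElement],
                       peaks: dict[str, dict[str, PeakSet]]) -> dict:
    """(chrom, start, end) -> {(mark, phase): overlapping-peak signal}."""
    edf = pd.DataFrame({"chrom": [e.chrom for e in elements],
                        "start": [e.start for e in elements],
                        "end": [e.end for e in elements]})
    out = {(e.chrom, e.start, e.end): {} for e in elements}
    for mark, by_phase in peaks.items():
        for phase, ps in by_phase.items():
            idx = first_overlap_index(edf, ps.df)
            sig = ps.df["signal"].to_numpy()
            for e, j in zip(elements, idx):
                if j >= 0 and np.isfinite(sig[j]):
                    out[(e.chrom, e.start, e.end)][(mark, phase)] = \
                        float(sig[j])
    return out


def run_pipeline(config: RunConfig) -> RecoveryReport:
    """Synthesize -> write -> re-read -> analyze -> score recovery."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RecoveryReport()
    t0 = time.perf_counter()

    # --- synthesize ---
    truth = synthetic.make_truth(
        config.seed, genome=dict(config.genome),
        hic_binsize=config.hic_binsize, n_genes=config.n_genes,
        n_active_enhancers=config.n_active_enhancers,
        n_primed_enhancers=config.n_primed_enhancers)
    paths = synthetic.write_all(truth, outdir / "inputs",
                                timepoints=config.hic_timepoints)
    logger.info("synthesize: %.1fs", time.perf_counter() - t0)

    # --- stage: spike-in ChIP normalization + retention ---
    t = time.perf_counter()
    peaks: dict[str, dict[str, PeakSet]] = {
        mark: {phase: _load_peaks(paths, mark, phase) for phase in PHASES}
        for mark in MARKS
    }
    for mark in ("H3K4me3", "H3K4me1", "H3K27ac", "CTCF"):
        for phase in ("prometaphase", "ana_telo"):
            rep = spikein.retention_report(peaks[mark]["interphase"],
                                           peaks[mark][phase])
            planted = truth.retention[mark][phase]
            est = rep.pct_retained / 100.0
            report.add(f"{mark} retention {phase}", planted, est,
                       "abs 0.02", abs(est - planted) <= 0.02)

    tsp = pd.read_csv(paths["track_spikes"], sep="\t")
    track_samples = [SpikeCounts(r.sample_id, r.phase, r.mark,
                                 int(r.endo_reads), int(r.spike_reads))
                     for r in tsp.itertuples(index=False)]
    factors = spikein.spike_scale_factors(track_samples,
                                          "H3K27ac_interphase")
    tracks = {
        phase: read_bedgraph(paths[f"track_H3K27ac_{phase}"], 1000,
                             truth.genome)
        for phase in PHASES
    }
    ratio = spikein.scaled_mean_ratio(
        tracks["prometaphase"], tracks["interphase"], factors,
        "H3K27ac_prometaphase", "H3K27ac_interphase")
    planted = truth.global_signal_ratio["H3K27ac"]["prometaphase"]
    report.add("H3K27ac global ratio prometaphase (spike-in)", planted,
               ratio, "abs 0.01", abs(ratio - planted) <= 0.01)
    naive = spikein.naive_mean_ratio(tracks["prometaphase"],
                                     tracks["interphase"])
    report.add("naive per-million ratio misestimates by > 2x",
               1.0, naive / planted, "ratio > 2",
               naive / planted > 2.0)
    logger.info("spike-in stage: %.1fs", time.perf_counter() - t)

    # --- stage: element classification + transitions ---
    t = time.perf_counter()
    genes = read_gene_table(paths["genes"])
    elements = cisre.classify_elements(
        {m: peaks[m]["interphase"] for m in
         ("H3K4me3", "H3K4me1", "H3K27ac")},
        genes, tss_window_bp=config.tss_window)
    trans = cisre.transition_table(
        elements, {m: peaks[m] for m in ("H3K4me3", "H3K4me1", "H3K27ac")})
    r3 = truth.retention["H3K4me3"]["prometaphase"]
    rac = truth.retention["H3K27ac"]["prometaphase"]
    r1 = truth.retention["H3K4me1"]["prometaphase"]
    prom_row = trans[(trans["klass"] == "promoter")
                     & (trans["phase"] == "prometaphase")].iloc[0]
    report.add("promoter K4me3-only fraction prometaphase",
               r3 * (1 - rac), prom_row["K4me3 only"], "abs 0.02",
               abs(prom_row["K4me3 only"] - r3 * (1 - rac)) <= 0.02)
    ae_row = trans[(trans["klass"] == "active_enhancer")
                   & (trans["phase"] == "prometaphase")].iloc[0]
    report.add("AE K4me1-only fraction prometaphase",
               r1 * (1 - rac), ae_row["K4me1 only"], "abs 0.02",
               abs(ae_row["K4me1 only"] - r1 * (1 - rac)) <= 0.02)
    trans.to_csv(outdir / "transition_table.tsv", sep="\t", index=False)
    cisre.nearest_gene_assignment(elements, genes)
    cisre.elements_to_frame(elements).to_csv(
        outdir / "elements.tsv", sep="\t", index=False)
    logger.info("cis-RE stage: %.1fs", time.perf_counter() - t)

    # --- stage: EU-RNA activation ---
    t = time.perf_counter()
    counts = pd.read_csv(paths["eu_counts"], sep="\t", index_col="gene_id")
    controls = pd.read_csv(paths["eu_controls"], sep="\t",
                           index_col="control")
    samples = pd.read_csv(paths["eu_samples"], sep="\t",
                          index_col="sample_id")
    table = eurna.eu_normalize(counts, truth.gene_lengths, controls,
                               samples, reference="async")
    calls = eurna.call_first_activation(table, theta=config.theta)
    truth_act = pd.read_csv(paths["activation_truth"], sep="\t",
                            index_col="gene_id")["first_active"].astype(str)
    merged = calls.set_index("gene_id")["first_active"]
    agree = float((merged == truth_act.reindex(merged.index)).mean())
    report.add("first-activation class recovery", 1.0, agree,
               ">= 0.95", agree >= 0.95)
    calls.to_csv(outdir / "activation_calls.tsv", sep="\t", index=False)

    ctrl, trt, planted_labels = synthetic.gen_dysregulation(truth)
    dys = eurna.call_dysregulation(ctrl, trt, pseudocount=config.pseudocount)
    frac = eurna.dysregulation_fractions(dys)
    planted_frac = planted_labels.value_counts(normalize=True)
    for lab in ("down", "up"):
        pf = float(planted_frac.get(lab, 0.0))
        report.add(f"dysregulation fraction {lab}", pf, frac[lab],
                   "abs 0.03", abs(frac[lab] - pf) <= 0.03)
    logger.info("EU-RNA stage: %.1fs", time.perf_counter() - t)

    # --- stage: Hi-C ---
    t = time.perf_counter()
    chrom = next(iter(truth.genome))
    true_bounds = {
        c: truth.boundary_positions[c] // config.hic_binsize
        for c in truth.genome
    }
    corner_series: dict[str, list[float]] = {"AA": [], "BB": []}
    strength_series: list[float] = []
    final_tp = config.hic_timepoints[-1]
    for tp in config.hic_timepoints:
        coo = hic.read_coo(paths[f"contacts_t{tp}"])
        aa, bb, strengths = [], [], []
        for c, length in truth.genome.items():
            cm = hic.bin_contacts(coo, config.hic_binsize, c, length)
            hic.balance(cm)
            oe, _ = hic.observed_expected(cm)
            ins = hic.insulation(cm, config.insulation_window,
                                 config.boundary_prominence)
            # boundary strength: depth of the insulation dip at true edges
            score = ins.scores
            for b in true_bounds[c]:
                if 0 <= b < len(score) and np.isfinite(score[b]):
                    strengths.append(-score[b])
            comp = hic.compartment_eigenvector(
                oe, truth.compartment_sign[c].astype(float))
            prof, corners = hic.saddle(oe, comp.eigenvector,
                                       config.saddle_quantiles)
            aa.append(corners["AA"])
            bb.append(corners["BB"])
            if tp == final_tp:
                good = np.isfinite(comp.eigenvector)
                agree_c = float(
                    (np.sign(comp.eigenvector[good])
                     == truth.compartment_sign[c][good]).mean())
                report.add(f"compartment sign agreement {c} (t{tp})",
                           1.0, agree_c, ">= 0.95", agree_c >= 0.95)
                rec, prec = _match_boundaries(ins.boundaries,
                                              true_bounds[c])
                report.add(f"boundary recall {c} (t{tp})", 1.0, rec,
                           ">= 0.9", rec >= 0.9)
                report.add(f"boundary precision {c} (t{tp})", 1.0, prec,
                           ">= 0.9", prec >= 0.9)
                loops = hic.read_bedpe(paths["loops"])
                _, intensity, _, n_used, _ = hic.loop_apa(
                    oe, loops, c, config.hic_binsize, config.apa_window)
                e = truth.loop_enrichment
                report.add(f"loop APA intensity {c} (t{tp})", e, intensity,
                           "rel 0.2", abs(intensity - e) <= 0.2 * e)
        corner_series["AA"].append(float(np.mean(aa)))
        corner_series["BB"].append(float(np.mean(bb)))
        strength_series.append(float(np.mean(strengths)))
    for key in ("AA", "BB"):
        vals = corner_series[key]
        mono = all(b > a for a, b in zip(vals, vals[1:]))
        report.add(f"saddle {key} corner strictly increases over time",
                   1.0, float(mono), "monotone", mono)
    mono = all(b > a for a, b in
               zip(strength_series, strength_series[1:]))
    report.add("boundary strength strictly increases over time",
               1.0, float(mono), "monotone", mono)
    logger.info("Hi-C stage: %.1fs", time.perf_counter() - t)

    # --- stage: integration ---
    t = time.perf_counter()
    sig_map = element_signal_map(
        elements, {m: peaks[m] for m in ("H3K4me3", "H3K27ac", "H3K4me1")})
    async_fpkm = table.fpkm["async"]
    cells = integration.corr_marks_expression(
        elements, sig_map, async_fpkm, calls, target_class="60")
    integration.correlation_frame(cells).to_csv(
        outdir / "correlations.tsv", sep="\t", index=False)
    if any(np.isfinite(c.r) for c in cells):
        integration.plot_correlation_grid(cells, outdir / "correlations.png")
    prom_cells = [c for c in cells
                  if c.klass == "promoter" and c.mark == "H3K27ac"
                  and np.isfinite(c.r)]
    if prom_cells:
        best = max(c.r for c in prom_cells)
        report.add("promoter H3K27ac-expression correlation positive",
                   1.0, best, "> 0", best > 0)
    enrich = integration.timepoint_enrichment(calls, genes, "bone_specific")
    enrich.to_csv(outdir / "timepoint_enrichment.tsv", sep="\t", index=False)
    ratio0 = float(
        enrich.loc[enrich["first_active"] == "0", "ratio"].iloc[0])
    report.add("tagged-gene enrichment at 0 min exceeds 1",
               3.0, ratio0, "> 1", ratio0 > 1.0)
    logger.info("integration stage: %.1fs", time.perf_counter() - t)

    provenance = {"config_sha256": config.sha256(),
                  "package_version": _version()}
    report.to_json(outdir / "recovery_report.json", provenance)
    config.to_yaml(outdir / "config.yaml")
    logger.info("total: %.1fs; overall pass: %s",
                time.perf_counter() - t0, report.overall_pass)
    return report


def _version() -> str:
    from . import __version__
    return __version__
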