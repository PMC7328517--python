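# mitodyn

Quantitative analysis of chromatin and transcription dynamics across the
mitosis–G1 transition: spike-in-normalized ChIP-seq comparison, mitotic
bookmarking of cis-regulatory elements, nascent-RNA (EU-RNA-seq)
activation timing, and 3D-genome reformation (compartments, TADs, loops).

## The problem

When cells divide, chromatin condenses, most transcription stops, and
long-range genome architecture dissolves — yet daughter cells re-establish
the parental expression program within hours. *Mitotic bookmarking* is the
hypothesis that features persisting on mitotic chromatin (here: H3K4me3,
H3K4me1, H3K27ac, CTCF) transmit that regulatory memory. Testing it
quantitatively requires tooling that:

- compares ChIP-seq *globally* across cell-cycle phases, which naive
  per-million scaling cannot do — a fixed exogenous chromatin spike-in
  anchors scale factors `spike_reads(ref) / spike_reads(sample)` so a
  genome-wide loss of a mark is measurable rather than normalized away;
- classifies cis-regulatory elements (promoter: H3K4me3 near a TSS;
  active enhancer: TSS-distal H3K4me1 + H3K27ac; primed enhancer:
  H3K4me1 only) and tracks their mark state per phase;
- assigns each gene a *first-activation class* — the earliest time after
  mitotic release (0/35/60/90/120/180 min, or asynchronous-only) at which
  spike-normalized nascent FPKM reaches a threshold θ — and classifies
  drug-induced dysregulation at |log2FC| > 1;
- derives Hi-C statistics: matrix balancing, distance-normalized O/E,
  compartment eigenvector (PC1 of the O/E correlation matrix, sign
  anchored to an orientation track), 30-quantile saddle plots, diamond
  insulation scores with boundary calls, and aggregate loop (APA)
  intensity.

Because the original sequencing data are not required, a first-class
synthetic-data generator plants every parameter the pipeline estimates —
retention/gain fractions per mark, a global signal loss visible only via
spike-ins, first-activation times, TAD/compartment/loop coordinates with a
mitotic→interphase mixing coefficient — and the pipeline is validated by
recovering them.

## Worked example

```python
from mitodyn import synthetic, spikein, hic

truth = synthetic.make_truth(seed=7)          # 2 x 20 Mb planted study

# mitotic retention of acetylation peaks (three-way, vs interphase)
inter, _ = synthetic.gen_peaks(truth, "H3K27ac", "interphase")
prometa, _ = synthetic.gen_peaks(truth, "H3K27ac", "prometaphase")
anatelo, _ = synthetic.gen_peaks(truth, "H3K27ac", "ana_telo")
rep = spikein.retention_report(inter, prometa, anatelo)
print(f"interphase peaks: {rep.n_reference}")
print(f"retained in prometaphase: {rep.n_overlap} "
      f"({rep.pct_retained_display}%)")

# fully reformed (360 min) contact map: loops and boundaries
cm = synthetic.gen_contacts(truth, timepoint="360")["chr1"]
hic.balance(cm)
oe, _ = hic.observed_expected(cm)
_, intensity, _, n_used, _ = hic.loop_apa(oe, truth.loops, "chr1",
                                          truth.hic_binsize)
print(f"loop APA intensity over {n_used} loops: {intensity:.2f}")
ins = hic.insulation(cm)
print(f"boundaries called: {len(ins.boundaries)} "
      f"(planted: {len(truth.boundary_positions['chr1'])})")
```

prints

```
interphase peaks: 2300
retained in prometaphase: 46 (2%)
loop APA intensity over 40 loops: 2.90
boundaries called: 18 (planted: 18)
```

Only 2% of acetylation peaks survive prometaphase (the planted retention
is 0.02 — this mark is erased on mitotic chromatin and regained in
anaphase/telophase), while the 360-min map returns the planted loop
enrichment (3.0, read back as 2.90) and all 18 planted TAD boundaries.

The same analyses run from the shell on standard formats (BED, bedGraph,
TSV, COO contact triples, BEDPE):

```sh
mitodyn demo --seed 7 --out runs/demo       # end-to-end + recovery report
mitodyn chip-retention --ref inter.bed --other prometa.bed --json rep.json
mitodyn classify --k4me3 a.bed --k4me1 b.bed --k27ac c.bed \
    --genes genes.tsv --out elements.tsv
mitodyn eurna --counts counts.tsv --controls controls.tsv \
    --samples samples.tsv --lengths lengths.tsv --theta 1.0 --out calls.tsv
mitodyn hic --coo contacts.tsv --chrom chr1 --chrom-length 20000000 \
    --loops loops.bedpe --out hic.json
```

`mitodyn demo` synthesizes a full study to disk, re-reads it through the
standard-format readers, runs every stage, and writes
`recovery_report.json` comparing each estimate to the planted truth; it
exits nonzero if any mandatory recovery fails.

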