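# Methods

`mitodyn` quantifies how the regulatory landscape of a dividing cell —
histone modifications at cis-regulatory elements, nascent transcription,
and 3D genome architecture — is carried through mitosis and rebuilt in G1.
The package implements the analysis stages as a library with a thin CLI,
plus a synthetic-data generator so every stage is verifiable by parameter
recovery without any external data. This note documents the models,
defaults, numerical choices, and what the synthetic recoveries do and do
not demonstrate.

## Coordinate and interval conventions

All coordinates are 0-based, half-open (BED convention). 1-based inputs
are never auto-detected; silent convention guessing produces off-by-one
corruption that is far harder to find than an explicit conversion.
Overlap means ≥ 1 bp shared under the half-open rule, everywhere —
including peak-retention accounting, element-state calls and Venn
construction. Strand is ignored for peaks and honored only when placing a
gene's TSS. Peaks straddling a chromosome end are clipped at load time
with a logged warning.

## Spike-in ChIP normalization

Read-depth ("per-million") normalization maps every library onto the same
total signal, so a genome-wide loss of a mark between interphase and
mitosis is invisible by construction. With a fixed mass of exogenous
chromatin spiked into each immunoprecipitation, the exogenous read count
is proportional to sequencing depth per unit input, and

    factor(sample) = spike_reads(reference) / spike_reads(sample)

rescales each library so equal true occupancy gives equal scaled signal.
The reference is the interphase library of each mark, since all phase
comparisons are made against interphase. Per-peak signal after scaling is
the scaled mean track value over the peak interval — a stable summary of
read density.

Cross-phase accounting reports, for a reference peak set, the count and
percentage re-detected in each other phase (a reference peak overlapping
several peaks in the other set counts once; percentages are rounded
half-up for display, kept exact internally). The three-way Venn is built
over a reference-priority deduplicated union (all reference peaks, plus
other-set peaks not overlapping the reference, plus third-set peaks
overlapping neither), which guarantees region counts sum to the union
size. The two-phase categorization used for boundary meta-profiles labels
interphase peaks overlapping anaphase/telophase as `shared` (interphase
coordinates reported), the rest `interphase_specific`, and non-overlapping
ana/telo peaks `ana_telo_specific`.

## Cis-regulatory element classes

Elements are defined from interphase peaks:

- **promoter** — H3K4me3 peak whose center lies within `tss_window`
  (default 2000 bp) of a TSS;
- **active enhancer (AE)** — TSS-distal H3K4me1 peak overlapping an
  H3K27ac peak;
- **primed enhancer (PE)** — TSS-distal H3K4me1 peak without H3K27ac.

The H3K4me1 peak anchors enhancer identity; H3K27ac contributes state
only. This keeps the element fixed when acetylation is lost in
prometaphase, so state transitions are attributable to the marks rather
than to shifting element definitions. The 2-kb window is a documented
choice (it matches the ±2 kb scale used for peak-centered profiles); it is
configurable, as is everything else, through `RunConfig`.

Element state in any phase is recomputed per mark by ≥ 1 bp overlap with
that phase's peak set, independently per mark. The transition table
reports, per class and phase, fractions over the interphase elements of
each state category (promoters: both marks / H3K4me3 only / none; AEs:
both / H3K4me1 only / none; PEs: H3K4me1 / none); each row sums to 1.

Gene association uses nearest TSS by |TSS − element center| with ties
broken toward the lexicographically smaller gene id, and a 100-kb cap for
enhancer links. Region-to-gene rule systems (GREAT-style) are out of
scope; the nearest-TSS stand-in is the documented simplification.

## Nascent-RNA normalization and activation classes

EU pulse-labeled RNA yield differs by an order of magnitude between
mitotic and interphase cells, so external controls are required. Two
control RNAs enter each sample at a fixed 10:1 mass ratio. The per-sample
factor is the geometric mean, over the two controls, of the control-count
ratio to the reference sample — using both spikes is robust to one
outlier. Expression is reported as FPKM-like values: factor-scaled counts
per kb of gene length per million scaled reads, where the library-size
constant is the **reference sample's** scaled total applied to every
sample. Dividing each sample by its own total would re-introduce exactly
the per-million blindness the spike-ins exist to remove; a shared constant
keeps genuine global shifts visible. The asynchronous library is the
natural reference (all genes active).

A gene's first-activation class is the earliest time point
(0/35/60/90/120/180 min) with mean FPKM ≥ θ (default 1.0, configurable;
sensitivity to θ is the caller's to examine — raising θ provably never
moves a call earlier). Genes below θ at all timed points but ≥ θ in the
asynchronous library are class `async`; genes never reaching θ are
excluded and counted. Dysregulation under p300/CBP inhibition is
classified by log2((treated + c)/(control + c)) with pseudocount c = 0.1
for stability at zero counts: `down` below −1, `up` above +1, `no_change`
otherwise.

## Hi-C statistics

Contact analysis is intra-chromosomal on dense per-chromosome matrices
(desk-scale genomes keep these below ~10^3 bins); trans records are parsed
and ignored. Defaults: 25-kb bins, insulation window 10 bins, boundary
prominence 0.2 (log2 units), 30 saddle quantiles with 5×5 corners, APA
window ±10 bins.

**Balancing.** Sinkhorn iterations with geometric damping
(w ← sqrt(w · 1/(Mw))) to unit row sums over good bins; non-convergence
raises with the last residual. Bins are masked bad only when genuinely
sparse: below the 2nd percentile of nonzero marginals *and* below 0.2× the
median. A pure quantile rule would always discard 2% of bins, and on
well-covered maps those are systematically boundary-adjacent bins whose
marginals are legitimately low — masking them distorts exactly the dips
the insulation score needs.

**O/E.** expected(d) is the mean balanced value at bin distance d over
good pairs; every O/E diagonal has mean exactly 1 by construction.

**Compartments.** The profile is the leading eigenvector of the Pearson
correlation matrix of O/E columns (good bins only; residual NaNs filled
with column means). The eigenvector is *not* re-centered: when one
compartment occupies most of a chromosome, zero-meaning pushes the
majority class across zero and corrupts per-bin sign calls. The
eigen-solver's arbitrary global sign is fixed by positive correlation with
an explicit orientation track (gene density on real data; the planted
compartment indicator in synthetic runs). A near-constant O/E yields a
flagged all-zero profile ("no compartments") rather than noise.

**Saddle.** Good bins ranked by compartment score (ascending, B first)
are split into equal quantile groups; the grid holds mean O/E between
groups, and corners average the extreme 5×5 blocks (BB low-low, AA
high-high, AB off-corners). Rank ties are scattered with a fixed
permutation: a discrete profile would otherwise yield index-contiguous
groups whose corner blocks consist of short-range pairs and pick up
balancing edge artifacts instead of compartment preference.

**Insulation and boundaries.** score(i) = log2 of the mean balanced
signal in the w×w square spanning rows [i−w, i) × columns [i, i+w) —
contacts crossing the left edge of bin i — divided by the chromosome-wide
mean of such squares. This edge-aligned square makes a domain edge at bin
i the unique minimum (a square straddling bin i itself produces a two-bin
plateau and off-by-one boundary calls). Boundaries are local minima with
prominence ≥ 0.2, with prominence evaluated within a 4w-bin neighborhood
so chromosome-scale compartment undulation cannot promote shallow dips.
Because the score is a ratio, adding a constant to all contacts leaves
relative dips intact.

**Loops (APA).** Loop lists are inputs (BEDPE); calling them is out of
scope. The aggregate O/E submatrix over anchors (±10 bins) gives the loop
intensity as the center-pixel mean; loops within 2 windows of the diagonal
or off the matrix are dropped and counted. A center-vs-corner ratio is
reported as a background-robust alternative.

**Boundary meta-profiles.** Peak sets (or phase-category subsets) are
rendered as center-count density tracks at the profile binsize and
averaged around boundary midpoints via the shared meta-profile routine.

## The synthetic-data generator

The generator plants every parameter the pipeline estimates and is the
package's acceptance oracle. All randomness flows from one seed through
named substreams, so identical seeds give byte-identical outputs
regardless of call order.

*Layout.* Default desk genome: two 20-Mb chromosomes, 25-kb Hi-C bins,
1200 genes on a jittered lattice, 900 AEs + 900 PEs placed TSS-distally
and non-overlapping (a 250-bp occupancy grid enforces spacing), 200 extra
distal H3K27ac peaks, 800 CTCF peaks with 40% placed at TAD boundaries.
Peak widths are uniform 500–2000 bp. Larger studies pass a proportionally
larger genome (element-state recovery runs 20,000 elements on 5×40 Mb;
activation recovery 5,000 genes on 4×25 Mb) — the default genome cannot
hold that many non-overlapping elements.

*Peaks.* Each (mark, phase) set keeps round(retention·N) uniformly chosen
interphase peaks plus round(gain·N) novel non-overlapping peaks.
Default retentions follow the biology being emulated: H3K4me3 0.98 and
H3K4me1 0.90 persist through prometaphase, H3K27ac collapses to 0.02 and
regains to 0.87 by anaphase/telophase with a 0.30 gain fraction biased
(probability 0.5) toward TAD boundaries; CTCF drops to 0.20 and partially
rebinds (0.56). Genome-wide occupancy ratios (what only spike-ins can
see) include the prometaphase H3K27ac ratio of 0.20. ChIP spike counts
are Poisson with exogenous reads proportional to a per-sample depth drawn
in [0.5, 2], endogenous reads additionally scaled by the occupancy ratio.
Signal tracks emulate a *uniform* global loss (phase occupancy = ratio ×
interphase pattern) with Poisson reads, so the scaled mean ratio recovers
the planted ratio while per-million scaling reads exactly 1.

*Expression.* Genes draw a first-activation class from a mix emulating
post-mitotic reactivation (3.5% at 0 min, 19% at 35 min, 65.5% at 60 min
— ~88% cumulative by cytokinesis — then a late tail and 2%
asynchronous-only). Counts are zero before the class time and
lognormal-mean (CV 0.2) Poisson from it on; the asynchronous library
expresses everything. Control counts are deterministic rounded values
(high-count spike-ins; Poisson noise there is negligible and determinism
keeps the 10:1 construction exact), and per-sample depths span exactly 5×
to force spike correction. 113 genes carry a `bone_specific` tag with 3×
enrichment among the 0-min class, emulating a cell-type-specific gene set.
A dysregulation generator pairs control/treated values with planted
effects well separated from the |log2FC| = 1 boundary (downs in
[−4.5, −2.2], ups in [2.2, 4.5], no-change in [−0.4, 0.4]; default mix
48% down / 8% up) under the same CV-0.2 measurement noise on both members.

*Contacts.* expected = depth · (1+d)^(−1) · [1 + mixing·(tad + comp)],
multiplied by [1 + mixing·(e−1)] at loop anchor pixels, Poisson-sampled
per upper-triangle pixel. The −1.0 decay exponent is standard contact-map
phenomenology, documented as a constant. TADs are 20–60 bin blocks;
compartment sign is constant within a TAD and flips between TADs with
probability 0.3, so sign changes sit on TAD boundaries (as domain and
compartment transitions co-occur in real maps — and so insulation dips at
sign flips are true boundaries, not artifacts). 40 loops per chromosome
sit 25–150 bins off the diagonal with enrichment e = 3. The loop factor
multiplies the local structural background, making e exactly the quantity
an aggregate O/E analysis should read back. The mixing coefficient per
time point (0 → 0.05 → 0.4 → 0.7 → 0.9 → 0.95 → 1.0 for 0–360 min)
emulates architecture lost in mitosis and rebuilt between cytokinesis and
late G1.

*What the generator does not emulate.* Read-level artifacts (mappability,
duplicates, GC bias), peak-caller behavior, enhancer–promoter specificity
of loops, negative-binomial overdispersion beyond the planted lognormal
CV, trans contacts, and restriction-fragment structure. Recovery of
planted parameters therefore validates the estimators and their wiring,
not robustness to every artifact of real libraries.

## Numerical and degenerate-input choices

- Balancing: max 500 iterations, residual tolerance 1e-8 on row sums;
  failure raises with the residual rather than returning bad weights.
- Insulation is undefined within one window of chromosome edges; a
  chromosome shorter than 2 windows raises.
- Saddle requires at least as many good bins as quantiles; compartment
  calling requires ≥ 10 good bins.
- Empty diagonals in O/E are NaN-masked, never imputed.
- Pearson cells with n < 3 genes are reported empty (NaN) with their n.
- Correlations are computed on log2(x + 0.1); FPKM and peak densities are
  heavy-tailed and the log stabilizes the estimate.
- Wilson 95% intervals for tagged-gene fractions (statsmodels).
- All percentage displays round half-up; exact values are retained in the
  objects.

## Pipeline and reproducibility

`run_pipeline` (or `mitodyn demo --seed N --out DIR`) synthesizes a study
to disk, re-reads every input through the standard-format readers, runs
all stages, and writes a recovery report comparing each estimate to its
planted truth at a stated tolerance (retentions ±2%, global ratio ±0.01,
transition fractions ±2%, activation recovery ≥ 95%, dysregulation
fractions ±3%, APA ±20%, boundary recall/precision ≥ 0.9 at ±1 bin,
compartment sign agreement ≥ 95%, strict monotonicity of boundary
strength and saddle corners across mixing). The report carries a
provenance block (SHA-256 of the scientific parameters, package version)
and is byte-identical across runs with the same seed. Problem sizes used
by the test suite and acceptance script are the desk-scale defaults above;
the two larger recoveries state their genomes explicitly.

## Known limitations

- The 1-bp overlap rule and the 2-kb TSS window are field-standard but
  not uniquely determined choices; both are single config keys.
- Nearest-TSS gene linking ignores regulatory domains and contact-based
  assignment; enhancer correlations inherit that simplification.
- Insulation-minimum boundary calling is the only TAD detector; no
  multi-scale or corner-score method is provided.
- Compartment calling is per-chromosome PC1; no trans or multi-eigenvector
  analysis.
- The FPKM-like unit depends on the chosen reference sample's scaled
  total; comparisons are meaningful within a normalized table, not across
  independently normalized tables.
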