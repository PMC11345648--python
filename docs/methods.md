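# Methods

## Coordinate and signal conventions

All intervals are 0-based half-open (BED convention); GTF input (1-based
closed) is converted at the boundary. Overlap means ≥ 1 bp of shared span,
so `[0,10)` and `[10,20)` do not overlap. TSS and TES are single-base,
strand-aware anchors (`start` / `end − 1` on the plus strand, swapped on the
minus strand). A strand-aware window "u bp upstream, d bp downstream" of an
anchor t is `[t − u, t + d)` on the plus strand and `[t + 1 − d, t + 1 + u)`
on the minus strand; it always contains the anchor base when d ≥ 1.

Coverage is piecewise-constant with bedGraph semantics: gaps are signal 0,
not missing data; overlapping segments are rejected. Library-size
normalization scales a track so its genome-wide integral Σ value·span is
10⁶ ("signal per million"); window density is the integral over the window
divided by its width (signal/bp). Chromosomes absent from the declared
chromosome sizes are dropped on input with a logged count, which keeps
behaviour deterministic on dirty files.

## Synthetic-data model

The generator is the package's study-conditions stand-in for a real
CUT&Tag + RNA-seq knockdown experiment. Its defaults *are* the conditions
under which the package's properties are demonstrated.

**Genome.** `n_chrom = 2` chromosomes of 2 Mb; 300 genes of 3–8 kb placed
without overlap, separated by ≥ 3 kb margins, all coordinates snapped to the
10 bp simulation grid; 2–4 exons per gene tile each gene body. 70% of TSSs
receive a CpG island (400–800 bp, jittered around the TSS); 100 background
CGIs are placed in distal space so they can never be TSS-proximal.

**Signal.** Counts are drawn per 10 bp bin from a Poisson whose mean encodes
the designed densities — desk-scale speed with the same mean structure as
per-read placement. Each gene carries a flat promoter plateau over
`[TSS − 50, TSS + 300)` at rate `body_rate × PI_g` and a uniform body rate
(`body_rate = 0.3` signal/bp at depth 1), so the designed pausing index is
exactly the expected promoter/body density ratio and plateau edges align
with the default PI windows (grid-snapped placement makes designed densities
the exact expectation of any bin-aligned window). Genes designated silent or
off are scaled by 0.1 — occupancy near the sampling floor. The plateau is
deliberately flat rather than Gaussian around the TSS: it makes designed
densities exactly recoverable by window averaging. Pause classes are drawn
from {highly: PI 5.0 (p=0.35), moderately: 2.0 (0.40), nonpaused: 0.8
(0.25)}, matching the conventional three-class thresholds.

**Peaks.** 2000 peaks of 200–500 bp with feature mixture
(promoter, exon, intron, distal) = (0.724, 0.050, 0.119, 0.107) by default.
The mixture is applied as an exact largest-remainder allocation rather than
per-peak multinomial draws, so the designed proportions are recoverable to
within one peak by construction. Peaks are placed wholly inside
priority-painted regions of their class (promoter paint wins over exon over
intron over distal), so the designed label is also the analysis label.
Distal peaks carry their own signal footprint at `promoter_rate = 0.6`;
exon/intron peaks sit on the gene-body signal that already exists (adding
extra signal inside gene bodies would perturb the designed pausing indices).

**Knockdown.** Each named effect set (default: 40 genes × factor 0.4, i.e. a
60% occupancy loss) multiplies the gene's whole signal in the knockdown
condition (`kd_scope="gene"`): a depleted factor loses occupancy everywhere
it binds, which makes the designed reduction recoverable in any within-gene
window. `kd_scope="promoter"` scales only the plateau, which changes the
designed PI by the same factor — the scenario used for group-wise
pausing-index comparisons. Reductions are assigned among nonsilent genes
only; a designed reduction on a gene whose occupancy sits at the noise
floor would be meaningless and unrecoverable.

**Expression and DE.** For nonsilent genes, per-replicate TPM is
`scale · (d_g/d_min)^coupling · exp(N(0, σ))` with coupling 1, scale 10 and
σ = 0.2 (natural-log), where d_g is the designed promoter density —
monotone occupancy→expression coupling with the minimum nonsilent TPM held
above 1. Silent genes get TPM in (0, 1); off genes exactly 0. Designed DE
genes (default 25 down + 15 up among bound genes) receive an exact
log2 fold-change of ±3 in the knockdown condition. The DE table carries the
exact designed log2FC, a pooled-variance Student t p-value computed on the
simulated log2 replicate TPMs (3 replicates per condition), and BH FDR.
Two design constraints matter here: (i) the emitted log2FC column is the
designed value, so null genes can never cross the |fold| ≥ 1.5 threshold;
(ii) the designed effect must dominate replicate noise for its own t-test —
at 3 replicates a designed |log2FC| of 3 keeps worst-case BH-FDR safely
below 0.05 (Welch's test was rejected because its Satterthwaite df collapses
toward 2 at n = 3, capping attainable significance regardless of effect
size; generator noise is homoskedastic, so the pooled test is exact).

**What the generator does not emulate.** Read-level artefacts (fragment
lengths, Tn5 bias, duplicates, mappability), peak-caller behaviour (peaks
are constructed, not called), overdispersion beyond Poisson, inter-gene
signal correlation, and real TPM compositionality. Passing tests therefore
demonstrate the correctness of the analysis arithmetic and its operating
characteristics under a Poisson world, not robustness to every artefact of
real libraries.

## Analysis choices

**Feature annotation.** One label per peak under
promoter > exon > intron > distal priority (the convention standard ChIP
annotators imply), ≥ 1 bp overlap rule; a majority-overlap variant is
available (`min_overlap_frac`). Introns are the gene body minus exons.
Promoter window (−2000, +500) by default, configurable. The engine is
provably equivalent to per-base priority painting (tested against a
paint-the-genome oracle).

**Metagene.** 2 kb flanks in 40 fixed-bp bins each, body scaled to 100
bins; minus-strand rows are flipped so column 0 is always 5′. Bin densities
use exact (fractional) bin edges, so the mean of the body columns equals
the body window density exactly. TSS-adjacent density for the
occupancy–expression trend is the mean of the 5 bins centred on the
flank/body boundary — robust to single-bin noise. Replicate correlation:
Pearson r on log2(1 + density) in 10 kb bins, dropping bins empty in both
tracks.

**Stratification.** Off (TPM = 0) and silent (0 < TPM < 1) are set aside;
the nonsilent rest is cut at quartiles of mean TPM (high = top 25%,
low = bottom 25%). Ties at the boundary break by gene id, making the
partition deterministic.

**Pausing.** PI windows default to promoter (−50, +300) and body
[TSS+300, TES); both configurable — any window consistent with the
generator's plateau geometry recovers the designed PI. Genes with zero body
density get PI = NA and are excluded from class counts rather than being
assigned infinite PI (avoids depth-dependent artefacts). Group-wise
condition comparison uses control-defined classes, median ΔPI, the fraction
of genes with relative decrease above a margin (default 0), and a two-sided
Wilcoxon signed-rank p (NA below 3 informative pairs).

**Differential occupancy.** Windows default to ±1 kb around the TSS or TES.
The default test is a pooled two-sided exact binomial rate-ratio test on
summed window counts, with the null proportion set by *effective* library
sizes. Effective sizes come from median-of-ratios scaling — the log-space
median of per-gene knockdown/control count ratios — because total-signal
scaling is composition-biased: when a sizable gene set loses occupancy,
every unchanged gene appears shifted the other way, and with deep windows
the pooled test then rejects massively on nulls. The log-space median makes
the size factor exactly reciprocal under condition swap, so direction
labels and p-values are antisymmetric. Total-signal scaling remains
available (`normalization="library"`). A Welch t on log2(1 + density)
across replicates is provided for ≥ 2 replicates per condition; with a
single replicate it reports fold changes only (p = NA, with a warning).
Fold changes use a half-count pseudocount so log2FC is finite and
antisymmetric. BH FDR is applied within each call (one factor × window
family). Occupancy-loss sets use the strict inequality
(control − kd)/control > loss, so a reduction of exactly 50% is excluded
from an "over 50%" set; genes with zero control density are excluded with a
logged count. FC-only counting (e.g. fold ≥ 1.1) is threshold-inclusive and
ignores significance.

**Targets.** Bound = any peak overlapping `[TSS − 2 kb, TES + 0.3 kb)`,
clamped at chromosome bounds so edge genes remain testable; peaks are
unstranded, so overlap is unstranded. "Fold change ≥ 1.5" is interpreted
symmetrically as |log2FC| ≥ log2 1.5, threshold-inclusive. DE statistics are
inputs — this module classifies and integrates; it does not fit expression
models.

## Numerical and determinism notes

All randomness flows from one root seed through named, hash-derived
substreams per stage, so rerunning a stage alone reproduces its output.
Written artefacts format floats with `%.6g` and JSON with sorted keys; a
fixed seed yields byte-identical output trees. Degenerate inputs are
handled explicitly: empty peak sets annotate to an empty table with a
warning; correlation requires ≥ 3 informative bins; stratification requires
≥ 4 nonsilent genes; Mann–Whitney on all-tied widths reports p = 1 under
the mid-rank convention and p = NA below 2 peaks per set.

## Problem sizes

Defaults (2 × 2 Mb genome, 300 genes, 2000 peaks, 2 coverage replicates per
condition) run the full pipeline in a few seconds. The differential
operating-characteristics configuration (1200 genes on 4 × 3 Mb, 200
reduced + 1000 null) and the high-depth loss-set configuration (depth 20)
each run in a few seconds more; these sizes give the binomial test per-gene
pooled counts in the hundreds-to-thousands, where its discreteness is
negligible and designed effects of 60% are detected at essentially unit
power.

## Known limitations

Peak calling, read alignment, spike-in normalization, GO enrichment and
strand-specific (PRO-seq-style) pausing are out of scope. The binomial test
assumes Poisson counts; real CUT&Tag windows are overdispersed, so on real
data its p-values will be anticonservative and the Welch option (or an
external count model) is the safer choice at ≥ 3 replicates. The
occupancy–expression coupling in the generator is monotone by construction;
the trend statistic demonstrates recovery of that design, not a biological
claim.
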