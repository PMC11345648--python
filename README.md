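# occutag

Chromatin occupancy analysis for CUT&Tag / ChIP-style data: annotate where a
factor binds, relate its occupancy to gene expression, quantify
promoter-proximal Pol II pausing, compare occupancy between a control and a
knockdown condition, and call the factor's direct target genes. A seeded
synthetic-data generator with full ground truth makes every stage testable
end to end without any external dataset.

## Who this is for

Analysts integrating factor-occupancy sequencing (CUT&Tag, ChIP-seq) with
RNA-seq in knockdown/degron experiments, and anyone who wants a small,
fully-deterministic sandbox in which each step of such a pipeline can be
validated against designed truth.

## What it computes

For genes with strand-aware TSS/TES on 0-based half-open coordinates:

- **Peak feature annotation** — each peak gets exactly one label under the
  priority `promoter > exon > intron > distal_intergenic`, with the promoter
  window defaulting to `[TSS − 2000, TSS + 500)`. CGI context flags mark
  peaks over CpG islands and over *TSS-proximal* CGIs (CGIs overlapping
  `TSS ± 500 bp`).
- **Occupancy–expression stratification** — genes split into
  high / medium / low (quartiles of mean TPM among nonsilent genes,
  mean TPM ≥ 1), silent (0 < mean TPM < 1) and off (TPM = 0); metagene
  matrices (fixed-bp flanks, scaled body) summarise occupancy per stratum.
- **Pausing index** —
  `PI = promoter density / gene-body density`, promoter window
  `[TSS − 50, TSS + 300)`, body from `TSS + 300` to the TES; classes
  highly paused (PI ≥ 3), moderately paused (1.5 ≤ PI < 3), nonpaused
  (PI < 1.5).
- **Differential occupancy** — per-gene densities in strand-aware ±1 kb
  windows at the TSS or TES, compared between conditions with a pooled
  rate-ratio binomial test on median-of-ratios–scaled window counts
  (Welch t on replicate densities available), BH FDR per window family,
  and direction calls at |fold| ≥ 1.5 and FDR < 0.05.
- **Occupancy-loss sets and FC-only counts** — genes with *over* 50%
  occupancy reduction (strict), and pure fold-change-threshold counts
  (e.g. fold ≥ 1.1, significance not required).
- **Direct targets** — a gene is bound if any peak overlaps
  `[TSS − 2 kb, TES + 0.3 kb)`; a direct target is bound **and**
  significantly differentially expressed (|fold| ≥ 1.5, FDR < 0.05);
  common targets of two factors are the intersection, reported with Venn
  counts.

The synthetic generator (`occutag.simulate`) draws per-10-bp-bin Poisson
signal whose means encode designed pausing indices, knockdown reductions and
an occupancy-coupled expression table, so every downstream number has a
known truth value. See `docs/methods.md` for the model.

## Worked example

```sh
occutag demo --seed 0 --outdir demo_run
```

simulates 300 genes / 2000 peaks on a 4 Mb toy genome, runs every stage, and
writes per-stage TSVs plus a `scorecard.json` comparing each recovered
quantity with the generator's design. Key lines of the scorecard at seed 0:

```
"feature_percentages": {"promoter": 72.4, "exon": 5.0, "intron": 11.9, "distal_intergenic": 10.7}
"feature_label_accuracy": 1.0
"occupancy_expression_spearman_rho": 1.0
"replicate_correlation_r": 0.997979
"pi_class_recovery": 1.0
"pi_median_rel_error": 0.047632
"differential_sensitivity": 1.0
"n_direct_targets": 40
"direct_targets_match_design": true
```

Reading: the annotation stage reproduces the designed feature mixture
exactly; the four expression strata order perfectly by TSS occupancy
(Spearman ρ = 1 across stratum means); replicate coverage tracks correlate
at r ≈ 0.998 in 10 kb bins; every gene's pausing class is recovered with a
median PI error under 5%; all 40 genes with a designed 60% occupancy loss
are called significantly decreased; and the 40 designed bound-and-DE genes
are exactly the called direct targets.

Each stage also runs standalone on the emitted files, e.g.

```sh
occutag pausing --track demo_run/factorX_control_rep1.bedgraph \
    --genes demo_run/genes.gtf --chrom-sizes demo_run/chrom_sizes.tsv \
    --expr demo_run/expression.tsv --out pi.tsv
```

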