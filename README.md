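# neuroloc

Compartment-resolved multi-omics analysis of protein and RNA
localization in neurons.

## The problem

Neurons are extremely polarized: many proteins accumulate in neurites
(axons and dendrites) far from the cell body (soma). Three mechanisms
can put a protein there — transport of the finished protein, transport
of its mRNA followed by translation on site, and preferential local
translation of an evenly distributed mRNA. Experiments that fractionate
neurons grown on microporous membranes into a soma and a neurite
fraction, and then quantify each fraction with RNA-seq, ribosome
profiling (Ribo-seq), label-free mass spectrometry and pulsed-SILAC,
make it possible to ask which mechanism explains each localized
protein. `neuroloc` implements that analysis as a tested, reusable
library for anyone working with compartment-separated omics data —
plus a synthetic-data generator with known per-gene ground truth, so
every stage of the pipeline can be verified without any external
download.

## What it computes

For every omics layer the common statistic is compartment enrichment:

* log2FC = log2(mean neurite abundance / mean soma abundance), with a
  two-sample t-test on per-replicate log2 values (pooled-variance
  Student t by default — exact size at 3-vs-3 replicates — Welch
  optional) and BH-adjusted p-values reported alongside.
* Localization calls use strict thresholds |log2FC| > 1 and p < 0.05.

Layer-specific machinery around it:

* **quant** — RPKM (reads per kilobase per million mapped reads),
  biotype-specific detection thresholds (> 1 RPKM coding, > 10 RPKM
  lncRNA), and down-shifted Gaussian imputation of missing protein
  intensities (draws from N(mu - 1.8 sd, 0.3 sd) per sample, the
  standard treatment of MNAR dropout in label-free proteomics).
* **riboseq** — footprint length filter (27–30 nt), P-site assignment
  (5' end + 12 nt), reading-frame periodicity QC (frame-0 fraction,
  chi-square vs uniform), and CDS-level RPKM for translation
  enrichment ("locally translated" = log2FC > 1, p < 0.05).
* **silac** — label-swap ratio aggregation: forward H/M and reverse
  M/H ratios are averaged in log2 space (a geometric mean), which makes
  the aggregate independent of the labeling direction; comparison to
  Ribo-seq fold changes by Pearson correlation.
* **noncoding** — neurite-enriched lncRNA calls, and circular/linear
  transcript preference per compartment: a gene is
  *neurite-preferential circular* when log2(circ/linear) > 1 in
  neurites and < 0 in soma.
* **integrate** — the headline classifier. Each neurite-localized
  protein (protein log2FC > 1, p < 0.05) is attributed to
  `mrna_localization` (RNA log2FC > 1, p < 0.05), `intermediate`
  (0 < RNA log2FC < 1), or — when its mRNA is not neurite-enriched
  (RNA log2FC < 0) — to `protein_transport` (Ribo log2FC < 0),
  `local_translation` (Ribo log2FC > 1) or `combination`
  (0 < Ribo log2FC < 1). The categories, plus `unquantified`, always
  partition the localized set. An RNA-binding-protein census can be
  overlaid on the protein calls.
* **assoc** — Fisher's exact test (two-sided probability-mass rule,
  sample odds ratio) for motif/modification-site association, the
  foreground/reference gene-set definitions (localized-and-translated
  vs soma-localized vs |log2FC| < 0.58), and a log2-odds PWM scanner
  to produce hit tables.
* **simulate** — the ground-truth generator: negative-binomial RNA
  counts, footprints with tunable frame-0 bias, log-normal protein
  intensities with intensity-dependent missingness, label-swap ratio
  pairs, and circular/linear junction counts, all driven by per-gene
  mechanism labels.

## Worked example

```python
from neuroloc import SimConfig, analyze_bundle, score_against_truth, simulate_bundle

bundle = simulate_bundle(SimConfig(n_genes=2000, seed=1))
result = analyze_bundle(bundle)

print(f"neurite-localized proteins: {result.summary.n_localized_total}")
for category, count in result.summary.counts.items():
    print(f"  {category:18s} {count:4d}  ({result.summary.fractions[category]:.1%})")
print(f"RNA-protein Pearson r:      {result.summary.rna_protein_pearson:.2f}")
print(f"frame-0 fraction (Ribo QC): {result.frame_profile.frame0_fraction:.3f}")

metrics = score_against_truth(bundle, result)
print(f"protein call recovery vs truth:     {metrics.protein_call_recovery:.1%}")
print(f"mechanism category recovery:        {metrics.mechanism_recovery:.1%}")
```

prints

```
neurite-localized proteins: 325
  mrna_localization   131  (40.3%)
  intermediate         84  (25.8%)
  protein_transport    44  (13.5%)
  local_translation    19  (5.8%)
  combination          47  (14.5%)
  unquantified          0  (0.0%)
RNA-protein Pearson r:      0.64
frame-0 fraction (Ribo QC): 0.850
protein call recovery vs truth:     95.3%
mechanism category recovery:        90.8%
```

Of the 325 proteins called neurite-localized in this simulated
experiment, 40% are explained by localization of their mRNA, a quarter
by moderately enriched mRNA, and the rest by protein transport, local
translation, or both; 95% of the truly localized proteins were called
and 91% received their generating mechanism. The frame-0 fraction
confirms the generator's 0.85 reading-frame bias survives the 27–30 nt
filter and P-site offsetting.

The same stages are available from a shell via the `neuroloc` CLI
(`simulate`, `enrich`, `riboseq`, `silac`, `circ`, `integrate`,
`assoc`, `scan`); run `neuroloc --help` for the commands and options.

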