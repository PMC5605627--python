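# Methods

## Statistical model of compartment enrichment

Every omics layer is reduced to one record per feature: the log2 fold
change of mean neurite over mean soma abundance and a two-sided
p-value from a two-sample t-test on per-replicate log2 values. For
linear-scale data (counts, RPKM, junction CPM) a pseudocount (default
0.5) is added before logs and ratios, so single-compartment features
remain finite; log2-scale protein intensities are used directly.
Localization calls use the raw p-value at strict thresholds
(|log2FC| > 1, p < 0.05); Benjamini–Hochberg adjusted p-values are
reported alongside for reuse, not used for the calls.

**Choice of t-statistic.** The default is the pooled-variance Student
t (df = n1 + n2 − 2). At the replicate counts this pipeline targets
(3 vs 3), the Welch–Satterthwaite approximation is markedly
conservative: on 20,000 exact-null normal features its measured size
at the 0.05 level is ~0.033, while the pooled test achieves
0.048–0.050. With equal group sizes and similar group variances —
the situation for every layer here — the pooled test is exact under
the null and loses nothing in power, so calibration decided the
default. Welch remains available (`test="welch"`) for unbalanced or
heteroskedastic designs.

**Degenerate inputs.** A feature whose two groups are constant and
equal gets p = 1; constant and unequal (zero variance, nonzero
difference — the t is undefined) gets the smallest positive float and
a `degenerate` flag, never p = 0. Features with fewer than two
observed replicates in either group get p = NaN and no call. NaN-aware
means/variances let partially observed proteins be tested on the
replicates that exist.

## Protein missingness and imputation

Label-free MS intensities are missing not at random: the probability
of dropout rises as intensity falls. Missing cells are imputed from a
down-shifted Gaussian per sample column — N(mu − 1.8 sd, 0.3 sd) with
mu, sd from that column's observed values — the field-standard
treatment (the shift and width are exposed as `ImputationParams`).

The pipeline does **not** impute every missing cell. Imputing an
isolated dropout into an otherwise observed replicate group injects a
value ~4 column-SDs below the group and destroys the within-group
variance estimate. Imputation is therefore restricted to compartments
with fewer than two observed replicates for that protein (notably
proteins detected in only one compartment, which would otherwise have
no fold change at all); scattered single-cell dropout is handled by
the NaN-aware test instead. Proteins observed in no sample are dropped
as unquantified.

## Ribosome profiling

Footprints are transcript-relative records (gene, raw 5' offset from
the CDS start, length). QC and quantification apply, in order: the
27–30 nt size-selection window; P-site assignment as 5' end + 12 nt
(the standard offset for ~29-mers, configurable since it is
protocol-dependent); reading-frame composition per length and pooled,
with a chi-square goodness-of-fit test against the uniform frame
distribution (df = 2) as the periodicity check; and CDS quantification
counting P-sites in the half-open interval [0, cds_length), converted
to RPKM with the CDS length as feature length. Coordinates are 0-based
and frame 0 is the frame of the start codon. Translation enrichment
reuses the common enrichment machinery; "locally translated" means
log2FC > 1 with p < 0.05.

## Label-swap SILAC aggregation

Forward (H/M, heavy on neurites) and reverse (M/H, heavy on soma)
ratios both estimate the same neurite/soma translation-rate ratio with
opposite labeling bias. They are combined as the mean of the log2
ratios — a geometric mean — which makes two identities exact:
exchanging which experiment is called forward leaves the aggregate
unchanged, and inverting every ratio negates it. An arithmetic mean of
raw ratios satisfies neither (it is biased upward by Jensen's
inequality). Proteins quantified in a single experiment are retained
with `n_experiments = 1`; non-positive ratios are rejected and
reported.

## Mechanism attribution

Neurite-localized proteins (protein log2FC > 1, p < 0.05) are
partitioned by the RNA layer first: significantly localized mRNA
(log2FC > 1, p < 0.05) gives `mrna_localization`; non-negative RNA
fold change without that significance gives `intermediate` (this
deliberately absorbs RNA log2FC > 1 with p ≥ 0.05 — the moderate class
carries no significance condition — and the measure-zero boundaries at
exactly 0 and 1). Only when the mRNA is depleted (RNA log2FC < 0) does
the translation layer arbitrate: Ribo log2FC < 0 is
`protein_transport`, > 1 is `local_translation`, and the closed
interval [0, 1] is `combination` (ribo boundaries fall to the
combination class). Genes missing a layer the decision needs are
reported as `unquantified`, never dropped, so
{mrna_localization, intermediate, protein_transport,
local_translation, combination, unquantified} always partitions the
localized set — an invariant asserted on every run.

## Set association and motif scanning

Fisher's exact test uses the two-sided probability-mass rule (sum of
hypergeometric probabilities of all margin-preserving tables no more
likely than the observed one) and reports the sample cross-product
odds ratio a·d/(b·c), with ∞ when b·c = 0 and a·d > 0. The test suite
checks the p-value against an exhaustive rational-arithmetic
enumeration for every 2×2 table with N ≤ 30. Foreground/reference gene
sets are: both RNA and protein log2FC > 1 with both p < 0.05
(localized and translated in neurites); both < −1 with p < 0.05
(soma); both strictly inside ±0.58 (~1.5-fold, equally distributed) —
pairwise disjoint by construction. The PWM scanner scores every window
with additive log2-odds weights over {A, C, G, U} (T read as U;
background uniform 0.25 by default) and reports the best window per
sequence; sequences shorter than the motif are flagged, not scored.

## The synthetic-data generator

The generator emulates the statistical structure of a
membrane-fractionation experiment, not its raw data. Each gene carries
a mechanism label that fixes the sign pattern of its true RNA,
translation and protein log2 effects (with L = 2.0 the localization
effect and M = 0.5 the moderate effect): `mrna_localization`
(L, L, L), `intermediate` (M, M, L), `protein_transport`
(−L/2, −L/2, L), `local_translation` (−L/2, L, L), `combination`
(−L/2, M, L), `soma_restricted` (−L, −L, −L), `unlocalized` (0, 0, 0).
Mechanism counts are allocated by largest-remainder quota, not
multinomial sampling, so class counts are exactly testable. lncRNAs
(10% of genes by default) take only RNA-level mechanisms and carry no
translation or protein effects.

Observable tables, each from its own RNG stream (`seed` + a fixed
per-table offset, so adding a table never perturbs another):

* **RNA counts** — negative binomial (dispersion 0.05) around
  base expression × 2^(RNA effect) in neurites, each library scaled to
  an expected 1e6 reads. Because libraries are normalized to a fixed
  total, an asymmetric localized mass induces a small composition
  shift in fold changes (~−0.2 log2 under the defaults), exactly as in
  real library-normalized data.
* **Footprints** — Poisson per gene/library (200k per library),
  lengths 27–31 nt (5% at 31 purely to exercise the size filter),
  P-site on a uniform CDS codon, frame 0 with probability
  `frame0_bias` (default 0.85), emitted as raw 5' ends (P-site − 12)
  so the downstream offset logic is exercised.
* **Protein intensities** — log2 intensity = 18 + log2(base
  expression) + protein effect × [neurite] + N(0, 0.4). The 0.4 log2
  replicate noise (~28% CV) sits in the typical range for label-free
  replicates. Each cell is masked missing with probability
  logistic((19 − intensity)/1.5), giving ~11% missing cells and ~58%
  complete rows under the defaults — dropout concentrated at low
  intensity (MNAR), which is what justifies the down-shifted
  imputation.
* **SILAC ratios** — fw and rev both 2^(ribo effect + N(0, 0.3)) for
  a random 20% of proteins, mimicking the shallow coverage of a short
  labeling pulse.
* **Junction counts** — Poisson circular and linear counts sharing a
  per-library depth; a flagged 5% of genes follow the reversal
  pattern 10:1 circular:linear in neurites vs 1:7 in soma, the rest
  keep a constant 0.1 background ratio. Circ/linear ratios are
  normalized per sample by the combined circular+linear junction
  total, which preserves within-sample ratios (normalizing the two
  tables separately would rescale every ratio by the table-total
  ratio and distort the classes).

**What passing tests do and do not show.** The generator's effects are
log2-additive with a binary compartment covariate, replicates are iid,
and every layer's noise is independent given the gene — real data add
isoform structure, correlated batch effects, peptide-level roll-up
noise, multi-mapping reads and UTR footprints, none of which are
modeled. Recovery rates measured here (e.g. ~95% of truly localized
proteins called at 3 replicates) are therefore upper bounds on what
the same thresholds achieve on real data; the exact-arithmetic and
calibration properties (RPKM conservation, Fisher enumeration, type-I
error) transfer directly.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| replicates | 3 per compartment | — | the design the thresholds target |
| localization effect L | 2.0 | log2 | a 4-fold effect, comfortably above the 2-fold call threshold |
| moderate effect M | 0.5 | log2 | center of the (0, 1) moderate band |
| RNA dispersion | 0.05 | NB dispersion | typical for biological replicates of bulk RNA-seq |
| protein noise | 0.4 | log2 SD | ~28% CV, typical label-free replicate noise |
| missingness midpoint / steepness | 19 / 1.5 | log2 intensity | ~11% missing cells, MNAR |
| imputation shift / width | 1.8 / 0.3 | column SDs | the standard down-shifted Gaussian |
| pseudocount | 0.5 | abundance units | keeps single-compartment features finite |
| P-site offset | 12 | nt | standard for ~29-nt footprints; configurable |
| footprint window | 27–30 | nt | gel size-selection window |
| frame-0 bias | 0.85 | probability | strong but sub-perfect periodicity, as observed in good libraries |
| detection thresholds | 1 (coding), 10 (lncRNA) | mean RPKM, strict > | biotype-specific detection |
| fold/significance thresholds | 1.0 log2, 0.05 | — | the 2-fold / p < 0.05 call convention |
| SILAC noise / coverage | 0.3 log2 / 20% | — | shallow-pulse measurement error and coverage |

## Known limitations

Single transcript per gene (no isoform-level localization); no
between-library normalization beyond RPKM/CPM, so composition shifts
are inherited rather than corrected; no variance moderation across
features (each gene is tested on its own replicates); the circular/
linear classifier consumes junction counts and does not detect
back-splicing; the PWM scanner is single-motif, best-window only. The
`unquantified` category makes explicit that mechanism denominators
depend on all three layers being measured — analyses on real data
should report it rather than silently shrinking the denominator.
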