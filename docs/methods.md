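# Methods

This note documents the statistical procedures implemented in `methylink`,
the choices made where the underlying study design left the method open, and
what the synthetic data generator does and does not emulate.

## Setting

The package analyses a two-group whole-genome bisulfite sequencing (WGBS)
and RNA-seq design: two groups of animals (labelled H and L, e.g. high and
low growth rate), four biological replicates each, with per-cytosine
methylation calls (CG/CHG/CHH contexts) and a genes × samples RPKM table.
All genomic coordinates are 0-based half-open internally; 1-based inputs
(cytosine reports, GTF) are converted at the parser boundary.

## Region model

Each gene defines three strand-aware regions: a 3 kb flank upstream of the
TSS, the gene body (the full gene span — introns are not distinguished), and
a 3 kb flank downstream of the TTS. For a minus-strand gene the upstream
flank lies at higher genomic coordinates. Flanks are clipped at chromosome
boundaries. An interval (e.g. a DMR) is assigned to the region containing
its midpoint, giving every DMR exactly one positional class per gene; a DMR
within flank range of several genes is linked to each of them.

## Methylation estimators

Two estimators are used deliberately, following common practice:

* **Region summaries** use the *weighted methylation level*
  Σ meth / Σ total over covered cytosines of the requested context with at
  least `min_coverage` (default 4) reads. This estimator is robust to
  uneven coverage. A region with no qualifying site yields no record
  (rather than a level of 0), and sites with zero total reads are dropped
  at parse time — treating them as 0% methylated would create
  coverage-dependent artefacts.
* **Metagene profiles** average per-site levels (m/c) within each bin,
  which is what "average methylation rate" curves plot. The footprint is
  divided into 30 fixed 100 bp bins per flank and 60 per-gene scaled body
  bins, indexed 5′→3′ in transcript orientation. The bin counts are our
  choice (the 100 bp flank resolution resolves the TSS dip); genes shorter
  than the body bin count are excluded from profiles to avoid empty bins.

Gene methylation classes follow the rank rule: genes with a level of
exactly 0 form the non-methylated class (an epsilon alternative is
configurable), and the rest are sorted and cut into Low/Middle/High tertile
rank groups whose sizes differ by at most one (remainder to the lower
classes first; boundary ties broken by stable gene id order). Classes are
computed per region (upstream, gene body, downstream) since each region's
distribution differs.

## Expression classes and differential expression

Expression classes use the standard RPKM cut-offs: non (≤ 1),
low (1–10], middle (10–100], high (> 100), applied to the mean across all
samples.

Differential expression between H and L uses **Welch's t-test on
log2(rpkm + 1)** with raw p < 0.05 by default. A count-model test is not
possible from an RPKM table, and the simple p-threshold mirrors the DEG
rule the design specifies; Benjamini–Hochberg adjustment is available by
flag. Fold changes are log2((mean_H + 1)/(mean_L + 1)); the pseudocount
keeps group-exclusive genes finite. Direction classes:

* `special_up` / `special_down`: all samples of one group above RPKM 1 and
  all samples of the other at or below it (the threshold reuses the
  non-expressed cut-off). These are checked before significance, so a
  group-exclusive gene is "special" even when its t-test is insignificant.
* `other_up` / `other_down`: significant shift, sign of the fold change.
* `none` otherwise.

## DMR calling

The caller is a standard pooled-Fisher sliding window scan (window 200 bp,
step 50 bp, per context):

1. Read counts are pooled across replicates within each group, per site.
2. Windows with ≥ 4 sites covered in both groups are evaluated; the pooled
   methylated/unmethylated counts form a 2×2 table tested with two-sided
   Fisher's exact.
3. Significant windows (p < 0.05 and |level_H − level_L| ≥ 0.1) of the same
   direction are merged when overlapping; counts are re-pooled over the
   merged span and the p-value recomputed on it.

All parameters are exposed; BH adjustment is available. **Known
limitation:** pooling replicates discards between-replicate variation, so
under replicate overdispersion the raw Fisher p-values are anticonservative
(with the generator's default dispersion the null window fraction below
0.05 is roughly 0.2 rather than 0.05). The null-calibration tests therefore
draw same-distribution binomial counts — the sampling model the pooled test
targets — and the overdispersion behaviour is stated here rather than
hidden. A replicate-aware (e.g. beta-binomial regression) caller is out of
scope.

## Integration statistics

* **Region-wise correlation:** Spearman's rho between region methylation
  and mean RPKM over genes with both values, average ranks for ties,
  t-approximation p for n > 9 and an exact permutation p (all n!
  orderings) for n ≤ 9; no result below n = 3.
* **Expression change by DMR:** every (DMR, gene) link contributes the
  linked gene's log2 fold change, grouped by region and DMR direction
  (UP_DMR = hyper in H); medians summarise each cell.
* **Quadrant tables:** distinct (gene, DMR) pairs counted per context,
  region, E± (DEG direction) and M± (DMR direction); genes without DEG
  status are excluded from the counts.
* **Enrichment:** hypergeometric upper tail P(X ≥ k) against a background
  of annotated genes with expression records, sets supplied as GMT and
  intersected with the background before testing; raw p by default with
  optional BH q-values. GO/KEGG retrieval, DAG propagation and pathway
  topology are out of scope.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes, on
one chromosome by default:

* Non-overlapping genes (1.5–4 kb, strands 50/50) with disjoint ±3 kb
  footprints; cytosines at geometric gaps (mean 25 bp), 70% CG with the
  remainder CHG/CHH at a flat low level (0.02), matching the near-absence
  of non-CG methylation in animal somatic tissue.
* Truth methylation: per-gene upstream/body levels drawn from beta
  distributions around 0.65 and 0.75 (concentration 10), with a linear dip
  to 0.25 within ±500 bp of the TSS. These defaults reproduce the canonical
  profile of a somatic methylome — body/downstream levels around 70–80%
  with a TSS minimum around 20–30%. The downstream flank level is tied to
  the body level (slope 0.9 plus small noise) because downstream
  methylation continues the gene-body domain, and this gives downstream
  methylation the same positive expression coupling as the body.
* Read counts: Poisson coverage (mean 30×) with beta-binomial methylated
  counts (intraclass correlation 0.05) capturing replicate overdispersion.
* Expression: ln(mean rpkm) = baseline (Normal(2.5, 1.0)) − 4·(upstream
  level − 0.65) + 5·(body level − 0.75), with lognormal per-sample noise
  (sd 0.3). The coupling signs encode the expected biology (promoter
  methylation represses, gene-body methylation tracks expression); the
  magnitudes are chosen so both couplings have comparable detectable
  effect after the TSS dip attenuates the body-level signal, yielding
  region-level |rho| around 0.2–0.3 at 500 genes — the magnitude range
  typical of methylome–transcriptome studies. A quarter of genes are
  forced into the non-expressed stratum (rpkm ≤ 1) so all four expression
  classes are populated.
* Injected signal: 30 DMRs (300 bp, ±0.4 level shift in group H, clipped
  to [0, 1]) in distinct gene footprints, and 50 DEGs (group-H mean × 2^±2)
  chosen among expressed genes — a fold change on a gene already at
  rpkm ≈ 0.3 would be invisible through the log2(rpkm + 1) transform and
  is not a meaningful recovery target.

Everything derives from one `numpy` generator seeded from the config, so a
fixed configuration yields byte-identical files.

**What the generator does not emulate:** genomic sequence context and CpG
islands, chromosome-scale methylation domains, isoform structure, mapping
and conversion errors, library-size effects in expression, and correlated
replicate structure beyond beta-binomial dispersion. Passing recovery tests
therefore demonstrates that the estimators and tests behave correctly under
the assumed model, not that they are robust to artefacts of real libraries.

## Problem sizes and numerics

The test-suite and acceptance runs use 500 genes × 8 samples (about 1.5 M
call rows, ~5 Mb of chromosome), which gives stable statistics for all the
checks while keeping a full run in seconds. Degenerate cases are defined
explicitly: zero-variance identical groups give p = 1 in the Welch test;
regions and windows with no qualifying sites emit no record rather than a
zero; empty inputs yield empty outputs except where a contract demands an
error (empty enrichment study). Tertile and rank ties are broken by stable
gene-id order so reruns are identical.
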