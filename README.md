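# telomethyl

A tested, reusable pipeline for asking whether DNA methylation near gene
promoters tracks telomere length in a small human cohort — and whether the
genes it flags cluster near telomeres, near centromeres, or among imprinted
loci regulated by the methyl-sensitive zinc-finger protein Zfp57.

It is written for epigenomics analysts who have (or want to emulate):

* multiplex qPCR plates measuring relative telomere length (T/S ratio:
  telomere-repeat signal over a single-copy gene such as beta-globin,
  normalised so a common reference sample equals 1),
* a CpG × sample methylation matrix (array-style beta- or M-values) with
  CpG coordinates and gene TSS annotations,
* chromosome sizes, centromere intervals, and an imprinted-gene list,
* optionally a genome FASTA for the Zfp57 motif scan.

Because cohorts of this design are rarely shareable, the package ships a
first-class synthetic-data generator that emulates every input with a
recorded ground truth, so the whole pipeline is testable end to end.

## The statistics at its core

1. **T/S quantification.** Per target, Cq is regressed on log10(input ng)
   over serial dilutions of a reference DNA (standard curve; efficiency
   `10^(-1/slope) - 1`). Each unknown replicate yields T/S =
   (telomere quantity)/(single-copy quantity); sample values are duplicate
   means, normalised to the reference sample.
2. **Per-CpG linear models.** M-values (`log2(beta/(1-beta))`) are regressed
   on T/S plus covariates by OLS; optionally residual variances are shrunk
   toward an inverse-gamma prior fitted by method of moments (empirical-Bayes
   moderation), giving a moderated t per CpG.
3. **Promoter enrichment.** Each CpG is assigned to the gene with the
   nearest TSS within 10 kb. Per gene, a two-sided Wilcoxon rank-sum test
   compares its CpGs' t-statistics with all other CpGs'; Benjamini–Hochberg
   converts p to Q. A CpG is a *significant site* when its gene's Q < 0.05
   and its own p < 0.05, signed by its t.
4. **Positional tests.** Genes are labelled subtelomeric (TSS within 4 Mb of
   a chromosome end) or centromeric (within 1.5 Mb of the centromere);
   2×2 Fisher exact tests ask whether significant genes concentrate there.
5. **Imprinted-gene permutation test.** Imprinted genes sit near unusually
   many array CpGs, so a naive Fisher test is biased. The test draws 100,000
   gene sets matched on each gene's *nearest count* (number of CpGs whose
   nearest TSS is that gene) and compares the observed imprinted tally with
   that matched null; p uses the add-one estimator.
6. **Motif scan.** Every occurrence of TGCCGC[A/G] — the motif Zfp57 binds
   when methylated — is found on both strands; subtelomeric enrichment and
   centromeric depletion are tested with log-space hypergeometric tails.

## Worked example

```bash
telomethyl run-all --seed 3 --out-dir demo
```

generates a 24-sample cohort (T/S ~ N(1.0, 0.29), 200 genes, ~1,600 promoter
CpGs, 10 planted genes with slope ±1 M-units per T/S unit), simulates and
quantifies a qPCR plate, fits the models and writes every table. The
manifest prints, among others:

```
"qpcr":     { "n_samples": 24, "mean_cv": 0.0367 }
"enrich":   { "n_genes_associated": 7, "n_sites_positive": 31,
              "n_sites_negative": 9, "pct_positive": 78, "pct_negative": 22 }
"motif_scan": { "total_hits": 13, "subtelomeric_hits": 7, "centromeric_hits": 3 }
```

Reading: duplicate T/S measurements vary by ~3.7% (the assay's expected
precision at 0.05-cycle Cq noise); 7 of the 10 planted gene promoters were
recovered at Q < 0.05 in this draw, with 40 significant sites of which 78%
are positively associated; and the scanner found exactly the 13 motif
occurrences that were planted (7 subtelomeric, 3 centromeric, 3
interstitial). `sites.tsv`, `gene_enrichment.tsv`, `positional_tests.tsv`,
`imprinted_permutation.json` and `motif_report.json` hold the full results;
`ground_truth.json` holds what was actually planted.

Stages can also be run individually (`telomethyl simulate`, `qpcr`,
`associate`, `enrich`, `positional`, `imprint-test`, `motif-scan`); see
`--help` on each.

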