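# Methods

This note documents the models, defaults and numerical choices behind
`telomethyl`, and what the synthetic study conditions do and do not show
about real data.

## qPCR T/S quantification

The assay model is log-linear amplification: for a well with input quantity
`q` (ng-equivalents), `Cq = intercept + slope * log10(q) + noise`, with
`slope < 0`. Standard curves are fit per target (telomere repeat `TEL`,
single-copy gene `SCG`) by OLS over all standard wells — five serial
dilutions spanning 5–50 ng in triplicate, entered individually, not as
dilution means. Efficiency is `10^(-1/slope) - 1`; a perfect doubling per
cycle gives slope `-1/log10(2) ≈ -3.3219` and efficiency exactly 1. A curve
with r² < 0.99 warns but does not fail, since no hard threshold is standard;
a non-negative slope is a failed curve and an error.

Unknowns are quantified off the curve (`q = 10^((Cq - intercept)/slope)`),
the per-replicate ratio is `T/S`, a sample's value is the mean over its
duplicates, and all values are divided by the reference sample's mean so the
reference is exactly 1. Consequences worth knowing:

* the reference normalisation cancels units, so rescaling the standard
  masses (even per target) leaves T/S unchanged;
* both duplicates are always averaged — no outlier rejection;
* the per-sample CV uses the n−1 SD over replicate ratios.

Error propagation sets the precision expectation: Cq noise σ on every well
gives a single-replicate relative T/S SD of
`σ · ln10 · sqrt(1/s_T² + 1/s_S²)`; duplicate averaging halves the variance
and the noisy reference doubles it back. At the generator default
σ = 0.05 cycles this predicts a mean duplicate CV near 4%, which is what
simulated plates reproduce and what this assay typically achieves.

## Per-CpG association models

Methylation enters regression as M-values, `log2(beta/(1-beta))`, with betas
clamped to `[1e-6, 1-1e-6]` so the logit stays finite. Each CpG is fit by
OLS on `[intercept, T/S, covariates]`; the t and two-sided p of the T/S
coefficient feed enrichment. Surrogate variables or other confounders enter
as plain covariate columns; no surrogate-variable inference is performed
here. Rank-deficient designs fail loudly, naming the collinear columns; a
CpG with numerically zero residual variance has an undefined t and is
excluded from ranking.

Variance moderation (default on) re-implements the empirical-Bayes shrinkage
familiar from microarray linear modelling: a scaled inverse chi-square prior
`(d0, s0²)` is fitted to the residual variances by method of moments on
log s² (the excess of `var(log s²)` over the sampling term `trigamma(d/2)`
identifies `trigamma(d0/2)`, inverted by root finding), and the posterior
variance `(d0·s0² + d·s²)/(d0 + d)` with `d0 + d` degrees of freedom forms
the moderated t. With homoscedastic synthetic noise the fitted `d0` is
large and moderation barely reorders CpGs; the plain-OLS mode is the exact,
tested reference. One test cross-checks the moderated t against R/limma's
`eBayes` on the same matrix (agreement to < 0.02 in t; the prior-fitting
details differ slightly).

## Promoter enrichment

CpGs map to the gene with the nearest TSS at distance ≤ 10,000 bp (10,001 is
out). Equidistant ties — including co-located TSSs — go to the
lexicographically smallest gene id, which is deterministic and independent
of annotation order. The gene-level test is a two-sided Wilcoxon rank-sum of
the gene's CpG t-statistics against all other CpGs with defined t; by
default the background includes CpGs assigned to no gene (a flag restricts
it to assigned CpGs — whether unassignable probes belong in the background
is a genuinely open choice). The p-value is exact (full enumeration of the
U distribution) when the combined sample is ≤ 25 without ties, otherwise a
normal approximation with tie and continuity corrections; degenerate
all-tied input returns p = 1. BH q-values use the literal step-up
definition with m = number of genes tested (≥ 1 assigned CpG).

Sites are called with two strict thresholds: gene Q < 0.05 **and** site
p < 0.05, signed by t. A gene with sites of both signs counts in both the
positive and negative tallies. Summary percentages are of all called sites,
rounded to whole percent.

## Positional and imprinted-gene tests

Subtelomeric: `min(tss, length - tss) ≤ 4 Mb`. Centromeric: distance to the
half-open centromere interval ≤ 1.5 Mb (0 inside; the last centromeric base
is `cen_end - 1`). Both boundaries are inclusive — the distinction only
matters on zero-measure boundaries. Genes on chromosomes without centromere
annotation are excluded from centromere tests with a logged count. Fisher
tables are built over the universe of tested genes, separately for all,
positively- and negatively-associated significant sets; p comes from the
exact conditional test and the reported odds ratio is the conditional MLE.

The imprinted-gene test matches on *nearest counts* because genes near many
array CpGs are more likely to be called significant; imprinted genes sit
near roughly twice as many CpGs as average, so an unmatched test is
anti-conservative. Strata partition the universe: any count shared by ≥ 5
genes is its own stratum; remaining genes pool into doubling count bins
(1, 2, 3–4, 5–8, …), merged with a neighbour if ever undersized (with the
significant set drawn from the universe this cannot occur; the guard covers
foreign gene lists). Each permutation draws, without replacement, as many
genes per stratum as the significant set contains there. Since strata are
disjoint, the imprinted count of each stratum's draw is exactly
hypergeometric, and that variate is sampled directly — distributionally
identical to drawing explicit gene sets and fast enough for the default
100,000 resamples. The p-value uses the add-one estimator
`(1 + #{null ≥ observed})/(1 + N)`, so it is never 0 and bottoms out at
`1/(N+1) = 1e-5` at the default N — reported as `p < 1e-5` territory. With
uniform counts the test collapses, correctly, to the one-sided Fisher
hypergeometric.

## Motif scan

The scanner reports every occurrence of TGCCGC[A/G] on both strands,
overlapping occurrences included (forward regex plus the reverse-complement
pattern `[TC]GCGGCA` on the forward text). Coordinates are 0-based
half-open, anchored at the forward-strand start of the 7-mer for both
strands. Scanning is case-insensitive (soft-masked sequence is scanned); `N`
never matches; other characters are an error naming the position. The motif
is non-palindromic, so no occurrence is double-counted — asserted at import.
On real assemblies a flag restricts the scan to chr1–22, X, Y, since
unplaced and alt contigs would inflate genome-wide counts.

Regional tests treat every base-pair position as one trial: population =
genome positions, successes = positions inside the region (computed
discretely from the same inclusive-window definitions as the hit
classification), draws = total hits. Tails are evaluated in log space
(`hypergeom.logsf`/`logcdf`), so genome-scale results far below double
precision (p « 1e-300) remain quantified via `log10_p`. Windows
overlapping on short chromosomes are tolerated; each test is marginal.

## Synthetic study conditions

Defaults emulate the target design: n = 24 samples; T/S ~ Normal(1.0, 0.29)
truncated at 0.1 (observed cohorts of this design bottom out near 0.5, so
truncation is a non-physicality guard, not a data feature); 200 genes on
4 × 30 Mb chromosomes with centred 3 Mb centromeres; CpG counts per gene
from a negative binomial (mean 8, dispersion 4, shifted to ≥ 1) so nearest
counts vary — the permutation test needs that variation — with an exact-count
mode for power studies; CpGs within ±2 kb of the TSS; baseline M-values from
an equal mixture of Normal(−3, 0.5) and Normal(+3, 0.5), mimicking the
bimodal methylation of array data; 5% of genes planted with slope
`sign · |Normal(1.0, 0.25)|` M-units per T/S unit against Normal(0, 0.5)
noise, sign constant within a gene.

The planted effect size is a design choice justified by power, not by any
cohort: at slope 1.0, the expected per-CpG |t| is roughly
`1.0 · 0.29/0.5 · sqrt(24) ≈ 2.8`, which puts an 8-CpG gene's rank-sum test
comfortably past Q < 0.05 — planted-gene recovery measures ≥ 90% over
replicates (≈ 99% in practice) while single CpGs remain individually
noisy, which is the regime the gene-level procedure is designed for.

Synthetic genomes make background sequence motif-free by re-randomising each
offending 7-mer window until none remain (whole-sequence rejection is
infeasible at ~1 spontaneous hit per 4 kb), then plant motifs at recorded
positions and strands with ≥ 13 bp spacing so planted counts are exact.

What the generator does **not** emulate: Infinium probe chemistry and
normalisation artefacts, batch/plate structure, cell-composition
heterogeneity, spatial correlation of methylation beyond shared gene slopes,
realistic base composition or repeat structure of genomic sequence, and any
biological coupling between imprinted status and methylation. Passing tests
therefore demonstrate the statistical machinery — error control, power at a
stated effect size, calibration, exact inversions — not that a real cohort
of this size would yield any particular gene list.

## Problem sizes and numerics

Simulation-based checks use 24 samples × ~1,600 CpGs × 200 genes per
replicate (50–200 replicates), 100,000 permutation resamples, and megabase
synthetic genomes — sizes at which every check runs in seconds to a couple
of minutes on one CPU while keeping Monte-Carlo error well inside the
asserted tolerances. Seeds fan out from a single integer through
fixed-purpose `SeedSequence` children, so stages are independently
reproducible and byte-identical under a fixed seed. Known limitations: the
moderated-t prior fit assumes a common residual df across CpGs (no missing
values); the nearest-TSS assignment is one-dimensional per chromosome and
ignores strandedness beyond the TSS position; and the permutation test's
stratum partition is one of several defensible readings of "matched on
nearest count" — with uniform counts all readings coincide.
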