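# Methods

`cardiogwas` implements the quantitative-genetic analysis of cardiac
performance traits in a panel of sequenced inbred lines (a DGRP-style
design): each line is effectively homozygous, many individuals are phenotyped
per line, and the line structure separates genetic from micro-environmental
variation. This note records the models, the defaults and why, the numerical
choices, and what the synthetic panels do and do not establish.

## Traits and QC

Seven per-fly traits are derived from per-beat series: DI and SI (mean
diastolic and systolic intervals, s), HP (mean per-beat DI+SI, s), AI
(SD of per-beat HP divided by a central HP value, dimensionless), EDD and ESD
(end-diastolic and end-systolic diameters, µm) and FS = (EDD−ESD)/EDD.
The AI denominator is the median per-beat HP by default (`ai_center`
switches to the mean); with fewer than two beats AI is missing, never zero.
Per-fly traits may also be supplied directly in the phenotype CSV.

Outlier QC flags values strictly outside the closed Tukey interval
[Q1 − k·IQR, Q3 + k·IQR], applied per line and per trait, with k = 1.5 and
linearly interpolated quartiles by default (both configurable). Lines keep a
trait only if ≥ 7 observations survive (`min_line_n`). QC is not exactly
idempotent: removing a point re-estimates the quartiles on fewer values and
the fences can shrink; at n = 12 Gaussian observations per line a second
pass removes something in roughly 8% of lines. The same fence rule, applied
to line-level means/CVe values, removes high-leverage lines before
association scans.

## Variance components, heritability and variance heterogeneity

A one-way random-effects ANOVA across lines gives Ve = MS_within and
Vg = max(0, (MS_among − MS_within)/n0) with
n0 = (N − Σnᵢ²/N)/(a−1) for unbalanced designs; H2 = Vg/(Vg+Ve).
Negative Vg estimates are truncated to zero so H2 ∈ [0, 1]. The reported F
is MS_among/MS_within with the usual F(a−1, N−a) reference distribution.
Heterogeneity of within-line (micro-environmental) variance uses the Levene
test — one-way ANOVA on absolute deviations from the per-line center —
with the classical mean center by default and the Brown–Forsythe median
variant by flag. The within-line coefficient of variation (CVe = sd/mean,
n−1 SD) is the micro-environmental variance metric carried into GWAS.

## Mixed-model GWAS

Line-level responses (trait means or CVe) are scanned with
y = Wα + xβ + u + ε, u ~ N(0, σg²K). K is the realized-relationship matrix
ZZᵀ/m over polymorphic variants; columns are mean-imputed and standardized
by sqrt(p(1−p)) (a centered-only variant is available). The fit follows the
FaST-LMM strategy: one spectral decomposition of K, maximum-likelihood
estimation of δ = σe²/σg² on the covariates-only null model (grid search
over log10 δ ∈ [−5, 5] refined by bounded scalar minimization), then a
1-df F test per variant by generalized least squares in the rotated basis,
with residual df = n − rank(W) − 1. Fixing δ at its null value is the
standard approximation and makes the scan a single pass of closed-form
algebra; with K = I it reduces exactly to OLS, which the tests exploit as an
oracle. Variants monomorphic in the retained lines are skipped and logged;
a singular covariate design raises an error naming the collinear column.

Candidate selection takes the `top_k` (default 100) smallest p-values —
ties broken deterministically by (position, ID) — then filters to
MAF strictly > 4% and optionally drops synonymous sites; selection precedes
filtering, so fewer than `top_k` candidates can emerge. The Bonferroni
threshold is not used as a gate.

## Epistasis scan

For each focal variant (typically a GWAS candidate) and every partner with
MAF > 5%, the line-level model y ~ µ + g_f + g_t + g_f·g_t is fitted on 0/1
genotypes and the interaction term tested (F, 1 df); the partner with the
smallest interaction p is reported per focal. All partner regressions for
one focal are solved from batched 4×4 normal equations assembled from shared
cross-products — algebraically identical to per-pair regression (asserted
against a brute-force double loop in tests). No covariates or kinship enter
this stage by default; a flag residualizes the response on covariates first.
Partners identical to the focal column are skipped; a perfect interaction
fit (zero residual) saturates the F statistic by clamping the denominator at
1e−12 of the response sum of squares, rather than being discarded, and the
p-value is floored at the smallest positive double.

## Variant-to-gene mapping and category bias

A variant inside a gene span (1-based inclusive, GFF3 convention) maps to
that gene — category 5'UTR/3'UTR/exon/intron by containment, exonic
synonymous/non-synonymous status taken from the variant annotation input —
with containment taking precedence over proximity. Otherwise a variant maps
to every gene whose span boundary is within 1 kb (inclusive; "within 1 kb"
is read as ≤ 1000 bp), labelled upstream/downstream by strand; otherwise it
is NA. Multi-gene assignments are retained for gene-set construction; for
category counting each variant contributes its single highest-precedence
category (UTR/exon/intron > upstream > downstream). Category bias against a
background uses the Pearson chi-square with per-category residuals
(O−E)/√E, whose squares sum to the statistic by construction.

## Gene-set statistics

Enrichment of an overlap k between a sample of n and a category of K genes
in an N-gene universe uses the upper-tail hypergeometric p (computed in log
space, so p-values far below double underflow remain usable through
log10_p) and FC = k/(nK/N), i.e. observed over expected. The overlap
coefficient is |A∩B|/min(|A|,|B|). Conservation rows test
orthologue-bearing genes against the whole-genome universe, and disease
lists within the orthologue-bearing sub-universe by default (a fly gene
counts as a hit if any of its orthologues is in the list); a flag switches
disease rows to the whole-genome universe.

## Motif discovery

Windows of ±75 nt (151 bp; flank configurable) around non-coding candidate
variants are scanned for over-represented k-mers of width 6–8, each k-mer
identified with its reverse complement by canonical collapsing on a single
forward-strand scan — this pools both orientations without double-counting
occurrences, which matters for calibration because every physical occurrence
would otherwise enter the binomial count twice. Expected frequencies come
from an order-2 Markov model fitted on the windows themselves ("intrinsic",
default) or from composition-matched random sequences ("random"). The
maximal order k−2 is available but is far more conservative, since an
abundant motif inflates its own subword frequencies and absorbs most of its
signal. Significance is a one-sided binomial upper tail with E-value =
p × number of distinct k-mers tested at that width, threshold E ≤ 1e−4
per width. Significant k-mers are greedily assembled (seed = most
significant; merge on overlap ≥ k−2 with ≤ 1 mismatch, either orientation;
columns weighted by observed counts, pseudocount 0.25 per base) into PSSMs,
and annotated against a MEME-minimal library by the best summed column-wise
Pearson correlation over all offsets and orientations (≥ 4 aligned columns),
normalized by the smaller motif width so a self-match scores 1. This stage
is a deliberately simplified reimplementation of the oligo-analysis /
peak-motifs / matrix-clustering toolchain; exact replication is out of
scope.

## Synthetic panels

The generator defaults to the study design: 167 lines × 12 individuals,
5000 independent variants with allele frequencies uniform on the MAF range
(0.05, 0.5], haploid-equivalent 0/1 genotypes with no missing calls, and
per-trait baselines on the observed scales of the real panel (mean,
within-line SD = √Ve, between-line SD = √Vg per trait). Ten mean-effect
variants (|β| = 0.3 phenotypic SD, random sign, one trait each) and five
variance-QTLs (within-line SD × 1.5 per alternate allele) are planted by
default; binary Wolbachia-like and inversion-like line covariates
(prevalence 0.5, effects 0.1 and 0.05 SD) and symmetric 10× noise outliers
at rate 0.01 complete the individual model. HP is DI + SI per individual;
other traits are simulated independently, reflecting the weak trait
correlations in the real panel. Within-line noise is Gaussian by default
(the real distribution is unstated); a Student-t option exercises heavy
tails. The synthetic genome is one random-sequence chromosome tiled with
2 kb genes (UTR/exon/intron template, alternating strands) separated by
2.5 kb gaps, so mapped and unmapped variants both exist. An optional block
mode adds crude linkage disequilibrium (seed column copied with 10% flips);
real LD structure is not modeled. What passing tests show is therefore
internal correctness and statistical calibration under independence and
normality — not robustness to LD, shared environment, or measurement
artifacts of real panels.

## Problem sizes in the test suite

The acceptance tests run the property checks at sizes chosen for a single
CPU: 50 panels of 40×60 for the LMM-vs-OLS oracle, one 60×50 panel
for the epistasis oracle, 100 panels of 167×12 for heritability recovery,
50 seeds of 167 lines × 500 variants for variance-QTL detection, 50 seeds
of 200×151 bp windows for planted-motif recovery, and a 10⁴ variants ×
10³ genes broadcast oracle for gene mapping.

## Known limitations

Exact per-variant REML is not implemented (δ is fixed from the null);
permutation-based genome-wide thresholds are out of scope; transcript-aware
mapping and codon-level effect prediction are not attempted (exonic effect
classes are consumed from the annotation input); motif clustering trees and
allele-level binding scores are out of scope.
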