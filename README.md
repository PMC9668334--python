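# cardiogwas

Quantitative genetics of cardiac performance in panels of sequenced inbred
lines. The package is aimed at researchers dissecting natural variation of
heart function in a DGRP-style design — many homozygous lines, ~a dozen
individuals phenotyped per line — where the line structure separates genetic
variance from micro-environmental variance and supports genome-wide
association on both trait means and trait variability.

It covers the full analysis chain:

- **Trait derivation and QC** — per-fly cardiac traits from per-beat series
  (DI, SI, HP = DI+SI, AI = SD(HP)/median(HP), EDD, ESD,
  FS = (EDD−ESD)/EDD), Tukey-fence outlier removal
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] per line and trait, per-line means and CVe
  (within-line sd/mean) with a ≥7-observations rule.
- **Variance components** — one-way random-effects ANOVA across lines:
  Ve = MS_within, Vg = max(0, (MS_among − MS_within)/n0),
  H2 = Vg/(Vg+Ve), plus the Levene test for heterogeneity of within-line
  variance.
- **Mixed-model GWAS** (`MixedGWAS(...).fit()` → results object) — FaST-LMM
  style scan of line means or line CVe: y = Wα + xβ + u + ε with
  u ~ N(0, σg²K), K = ZZᵀ/m over standardized genotypes, δ = σe²/σg²
  estimated once on the null model, per-variant 1-df F tests; binary line
  covariates (Wolbachia infection, inversion markers); top-100-then-filter
  candidate selection (MAF > 4%, synonymous sites dropped).
- **Epistasis** (`EpistasisScan(...).fit()`) — exhaustive focal-SNP ×
  partner interaction scan (partners at MAF > 5%), reporting the best
  partner per focal variant, solved by batched closed-form regression.
- **Gene mapping** — containment then ≤1 kb TSS/TES proximity rules,
  multi-gene assignments, Pearson chi-square category-bias test with
  per-category residuals.
- **Enrichment** — upper-tail hypergeometric p with fold change
  FC = k/(nK/N), overlap coefficients, gene-set union/intersection
  bookkeeping, and fly→human conservation tables over an orthologue-bearing
  sub-universe.
- **Motif discovery** — ±75 nt windows around non-coding candidate variants,
  canonical k-mer over-representation (k = 6–8) under intrinsic-Markov or
  composition-matched random backgrounds (E ≤ 1e−4), greedy PSSM assembly
  and annotation against a MEME-minimal PSSM library.
- **Synthetic panels** (`syndata`) — generator with known ground truth
  (planted mean-effect variants and variance-QTLs, line covariates,
  outliers, gene models, genome) so every stage is testable end to end.

## Worked example

```python
import cardiogwas as cg
from cardiogwas.pheno import apply_qc, line_summaries
from cardiogwas.quantgen import quantgen_table

cfg = cg.SimConfig(n_lines=167, n_per_line=12, n_variants=2000,
                   genome_length=150_000, beta_mean=1.0, seed=42)
panel, genes, genome = cg.simulate_panel(cfg)
pheno, covariates, truth = cg.simulate_phenotypes(panel, cfg)

qc = apply_qc(pheno)
print(quantgen_table(qc, ["DI", "SI", "HP", "EDD", "ESD", "FS", "AI"]))
```

```
trait  n_lines  n_indiv    mean       Vg       Ve     H2  levene_p
   DI      167     1926  0.6320   0.0589   0.0509 0.5367       0.0
   SI      167     1937  0.2106   0.0008   0.0005 0.6269       0.0
   HP      167     1922  0.8421   0.0606   0.0516 0.5398       0.0
  EDD      167     1945 78.3737 121.6852 158.0384 0.4350       0.0
  ESD      167     1924 53.7211  55.9925  79.6767 0.4127       0.0
   FS      167     1929  0.3400   0.0036   0.0028 0.5614       0.0
   AI      167     1944  0.1585   0.0417   0.0553 0.4299       0.0
```

Each row is one trait: numbers of lines and individuals retained after QC,
the pooled mean, the among-line (Vg) and within-line (Ve) variance
components, broad-sense heritability H2 = Vg/(Vg+Ve), and the Levene
p-value for heterogeneity of within-line variance (here ~0: the generator
plants variance-QTLs by default).

The mixed-model scan on EDD line means then recovers the planted variant:

```python
summ = line_summaries(pheno)
vals = summ[summ.trait == "EDD"].set_index("line_id")["mean"].dropna()
vals = vals.loc[cg.leverage_filter(vals)]
res = cg.MixedGWAS(vals, panel, covariates, trait="EDD").fit()
print(res.summary(5))
```

```
rank variant_id chrom   pos    maf     site_class     beta     se  statistic      p
   1     v00276  chr1 20642 0.1446          5'UTR -13.9152 2.3920    33.8420 0.0000
   2     v00823  chr1 61031 0.4277          3'UTR   6.2788 1.7923    12.2718 0.0006
   3     v00606  chr1 44419 0.3735 non-synonymous   6.3437 1.8178    12.1781 0.0006
   4     v00665  chr1 49180 0.4518         intron   6.0553 1.7703    11.6991 0.0008
   5     v00258  chr1 19618 0.4217   upstream_1kb   5.5998 1.7894     9.7938 0.0021
```

The top hit `v00276` is the single planted EDD mean-effect variant
(simulated β = −14.1 µm per alternate allele; estimated −13.9). The
`rank`/`p` columns feed candidate selection
(`res.select_candidates(top_k=100, maf_min=0.04)`), whose variants become
focal SNPs for `EpistasisScan` and inputs to gene mapping, enrichment and
motif discovery. The whole chain also runs as a CLI:

```sh
cardiogwas run --seed 1 --out-dir run1      # full pipeline on a synthetic panel
cardiogwas report --run-dir run1
```

with stage-wise subcommands (`simulate`, `qc`, `quantgen`, `gwas`,
`epistasis`, `map`, `enrich`, `motifs`) reading and writing plain
CSV/TSV/VCF/GFF3/FASTA/MEME files.

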