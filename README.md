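# mlgwas

A machine-learning-mediated genome-wide association (GWAS) toolkit for
plant-breeding panels, built around the workflow used for soybean yield
and its component traits (reproductive/non-reproductive node counts, pods
per plant, maturity, seed yield). Conventional single-marker engines often
lack power in narrow-genetic-base crops; this package runs two
conventional engines and two machine-learning importance engines side by
side over one data model, so marker-trait associations can be compared and
combined across methods.

## What it computes

**Phenotype preparation.** Plot-level records from a multi-environment
trial (locations × years, randomized complete blocks) are fitted with the
mixed model

    Y = Ab + Bg + Ci + ε,   g ~ N(0, σ²_g I),  i ~ N(0, σ²_int I),  ε ~ N(0, σ²_ε I)

where `b` holds environment/block fixed effects, `g` random genotype
effects and `i` genotype-by-environment interactions. REML variance
components give broad-sense heritability `H² = σ²_g / (σ²_g + σ²_ε)`, and
the genotype BLUPs are the phenotype every association engine scans.

**Association engines.**

- **MLM** — per-SNP mixed linear model `y = Xa + Z_M y_M + e` with a
  VanRaden kinship random effect; the variance ratio δ = σ²_e/σ²_g is
  estimated once on the SNP-free model by spectral (eigendecomposition)
  REML and held fixed across markers, so each test is weighted least
  squares.
- **FarmCPU** — iterative fixed/random alternation: a fixed-effect scan
  conditioned on pseudo-QTN covariates, then a random-effect model whose
  kinship is built from candidate pseudo-QTN genotypes and whose REML
  likelihood selects the (bin size, pseudo-QTN count) combination.
- **RF** — regression-forest impurity (variance-reduction) importance per
  SNP, averaged over repeated 5-fold cross-validation.
- **SVR** — ε-insensitive support-vector regression with polynomial kernel
  `K(x, z) = (x·z/p + c)^d`; per-SNP importance is the held-out loss in
  predictive R² when that SNP's column is permuted.

**Significance.** MLM/FarmCPU p-values are thresholded by
Benjamini–Hochberg FDR. ML importances (scaled 0–100 per scan) are tested
against a *global empirical threshold*: the phenotype is permuted across
individuals, the engine re-fitted, the maximum importance stored, and the
(1 − α) quantile of those maxima (α = 0.05, 1000 permutations by default)
is the genome-wide cutoff — a family-wise-error guarantee that needs no
distributional assumptions.

**Post-GWAS.** Significant SNPs collapse to peaks; each peak expands to an
LD-decay-informed window (default ±150 kbp); gene models from GFF3
overlapping the window become candidates ordered by edge distance from the
peak; allelic effects are homozygote-class BLUP mean differences; a
Venn-style report counts loci shared across engines.

**Synthetic panels.** `mlgwas.simdata` generates inbred biallelic panels
with LD blocks, a MAF spectrum, optional Balding–Nichols subpopulation
structure, and phenotypes under the trial design above with planted QTL at
known variance shares — every statistical guarantee in the test suite is
validated against this known truth.

## Worked example

`examples/03_four_engine_scan.py` simulates a 150 × 600 panel with one QTL
explaining 25% of plot-level variance (h² = 0.5), prepares BLUPs and runs
all four engines:

```
causal SNP: Chr05_36589057
MLM:     top Chr05_36589057  p=1.38e-26  BH threshold=8.10e-05  (2 significant)
FarmCPU: top Chr05_36589057  p=2.48e-49  pseudo-QTNs=['Chr05_36589057', ...]
RF:      top Chr05_36589057  importance=100/100  empirical threshold=15.2  (1 significant)
SVR:     top Chr05_36589057  importance=100/100  empirical threshold=6.5  (19 significant)
```

All four engines rank the planted causal marker first; the ML engines
declare it genome-wide significant because its scaled importance exceeds
the permutation threshold. The other examples cover panel simulation and
LD decay (`01`), BLUPs/heritability (`02`), and QTL windows, candidate
genes and allelic effects (`04`).

A command-line interface wraps the same library:

```bash
mlgwas simulate --n-individuals 227 --n-snps 2000 --seed 1 --out-prefix sim
mlgwas run --genotype sim.vcf --phenotype sim_phenotypes.tsv --out-dir out
mlgwas windows out/assoc_svr.tsv --flank 150000 --gff3 genes.gff3
```

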