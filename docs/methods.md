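# Methods

This note documents the statistical models, numerical choices and
synthetic-data assumptions behind `mlgwas`, in the order the pipeline
runs them.

## Data model and coordinates

Genotypes are biallelic SNP dosages counting ALT-allele copies (VCF
convention); the HapMap reader takes the first listed allele as the
reference so both readers agree exactly. Positions are 1-based inclusive
everywhere internally; only BED export converts to 0-based half-open.
Heterozygous calls are retained in the matrix even though the target
panels are near-fully inbred — the QC filter, not the reader, decides
their fate.

## Genotype QC and imputation

SNPs are dropped when minor allele frequency (computed on non-missing
calls) is below `maf_min` (default 0.05) or the heterozygote fraction
exceeds `het_max` (default 0.5). Filters run on raw calls *before*
imputation: filtering first is conservative and avoids rescuing markers
with imputed alleles.

Remaining missing calls are filled by a first-order Markov chain along
each chromosome. Transition tables between adjacent SNPs are estimated
from individuals observed at both markers (Laplace-smoothed 3×3 counts);
a left-to-right and a right-to-left pass are averaged to remove
orientation asymmetry, and each missing call takes the most probable
state. Terminal columns use the marker's marginal state frequencies as
prior, which makes the degenerate cases (single-marker chromosome,
no informative neighbour) reduce to a modal-dosage fill. Observed calls
are never altered.

## Kinship, structure, LD

Kinship is the VanRaden centered cross-product
`K = W W' / Σⱼ 2 pⱼ(1 − pⱼ)` with `W = dosage − 2p`; monomorphic markers
are excluded from the scaling sum. Note one consequence of in-sample
centering: rows of K sum to zero, so the mean off-diagonal is exactly
`−trace(K)/(n(n−1))`, about −1/n, not 0 — tests assert the identity
rather than a naive zero.

Population structure is controlled with principal-component covariates of
the centered dosage matrix (deterministic sign: the largest-magnitude
loading of each component is positive). The number of components is a
knob playing the role a model-based subpopulation count (e.g. K = 7)
would play in an external structure analysis; PCA keeps the pipeline
self-contained.

LD is summarized as squared Pearson correlation of dosage for
intra-chromosome pairs within a distance cap, binned by distance; the
decay distance is the first (linearly interpolated) crossing of a
configurable r² level, defaulting to half the first-bin mean. The decay
distance motivates the QTL window flank; the package default flank is
150 kbp, the LD-informed choice for a soybean-type GBS panel.

## Multi-environment mixed model

For one trait, `Y = Ab + Bg + Ci + ε` with environment/block cells fixed
(`b`), genotype effects `g ~ N(0, σ²_g I)`, genotype-by-environment
interactions `i ~ N(0, σ²_int I)` and residual `ε ~ N(0, σ²_ε I)`.
Records with missing values are dropped (REML handles the imbalance);
outliers can first be flagged missing by Tukey fences per
trait × environment (quartile ± k·IQR, default k = 1.5, flagging ≲1% of
clean Gaussian data — the rule is a knob).

REML is maximized by profiling out `b` and `σ²_ε` and searching the two
variance ratios `γ_g = σ²_g/σ²_ε`, `γ_int = σ²_int/σ²_ε` on the log
scale with Nelder-Mead. Each likelihood evaluation uses the Woodbury
identity, so its cost is one sparse factorization in the random-effect
dimension (q = n_genotypes + n_genotype×env cells) — a few milliseconds
at panel scale. The log parameterization keeps components positive and
clamps vanishing ones at (numerically) zero; an explicit initial simplex
is supplied because the default Nelder-Mead simplex degenerates when a
start coordinate is 0, and one restart is performed if the first pass
fails to converge. A best-so-far log-likelihood trace is recorded; it is
non-decreasing by construction and asserted in tests. The G×E component
is dropped automatically when unidentifiable (one environment, or no
replication within genotype-environment cells). Tolerances: 1e−6 on the
log-ratios, 1e−8 on the log-likelihood, 200 iterations per pass.

Heritability defaults to the literal variance ratio
`H² = σ²_g / (σ²_g + σ²_ε)`. An entry-mean variant
`σ²_g / (σ²_g + σ²_int/n_env + σ²_ε/(n_env·n_rep))` is available behind
`plot_basis=True` because the two conventions coexist in multi-environment
trial practice; the literal ratio is the package contract.

## MLM engine

The null model `y = Xa + u + e`, `u ~ N(0, σ²_g K)`, is fitted by
spectral REML: the restricted likelihood depends on δ = σ²_e/σ²_g only
through the eigenvalues of `S K S` (S the fixed-effect annihilator), so a
bounded 1-D search on ln δ (tolerance 1e−8) is exact. δ is then held
fixed for all markers (the population-parameters-previously-determined
approximation), making each per-SNP test generalized least squares on
spectrally rotated data, computed for all SNPs at once by
Frisch–Waugh residualization. With identity kinship the scan reduces
*exactly* to per-SNP ordinary least squares, which is the oracle used in
tests. p-values are two-sided Wald (normal) for n > 100 and Student-t
with df = n − c − 1 otherwise; monomorphic SNPs report β = 0, p = 1.

## FarmCPU engine

Iteration alternates: (1) a fixed-effect scan of every SNP with the
current pseudo-QTNs as covariates — a SNP falling inside a pseudo-QTN's
bin is tested with that pseudo-QTN removed, so no marker is conditioned
on itself; (2) candidate pseudo-QTN sets formed by picking the best SNP
per bin over a bin-size ladder {50 kb, 500 kb, 5 Mb} and candidate counts
t ∈ {2, 4, …, n/10}; (3) a random-effect model `y = μ + u + e` whose
kinship is built from the candidate pseudo-QTN genotypes — its REML
likelihood selects the winning (bin size, t). The loop stops when the
pseudo-QTN set repeats or after `max_iter` (default 10). Iteration 1
requires at least one marker to pass a Bonferroni-scaled entry threshold
(p < 0.01/m, a knob); otherwise the plain covariates-only scan is
returned with an empty pseudo-QTN set, which is also the correct
behaviour under a global null. Collinear pseudo-QTNs (perfect-LD
duplicates) are pruned greedily before the conditioned scan.

## Importance engines

Both engines scan genotype → BLUP with repeated K-fold cross-validation
(default 5 folds × 10 repeats, all folds seeded from one root seed).

**Random forest.** Regression forests (default 1000 trees, mtry = p/3,
min leaf 5) are fitted per training fold; a SNP's raw importance is the
mean impurity (variance) reduction over its splits, averaged across all
fold × repeat fits. A constant column has importance exactly 0.

**SVR.** Dosages are standardized per SNP and the response per training
fold; an ε-insensitive SVR with polynomial kernel
`K(x, z) = (x·z/p + c)^d` (defaults d = 2, c = 1, C = 1, ε = 0.1; the 1/p
factor keeps the kernel scale dimension-free) is fitted per fold. Raw
importance is *held-out permutation importance*: the drop in test-fold R²
when the SNP's column is permuted, clamped at zero, averaged over folds.
This is the model-agnostic realization of margin-based SVM feature
scoring, defined for any kernel and directly testable; a gradient-based
criterion could be slotted in as an alternative backend. Implementation
note: permuting column j shifts the test-vs-support-vector Gram matrix by
a rank-1 term, and expanding the polynomial kernel binomially turns the
per-SNP prediction update into d matmuls shared across SNPs — an exact
shortcut (verified against the naive rebuild to machine precision) that
makes thousand-replicate permutation studies affordable.

**Scaling.** Raw importances map affinely to [0, 100] (min → 0,
max → 100, clipped against float overshoot); an all-equal profile maps to
all zeros with a warning. The map is monotone, so rankings are preserved.

**Global empirical threshold.** For each of `n_reps` replicates (default
1000) the phenotype vector is permuted across individuals (genotypes
untouched), the engine's importance computation is rerun — a reduced
configuration (fewer repeats, or a single fit) is permitted and must then
match the real scan's configuration — and the maximum importance stored.
The threshold is the empirical (1 − α) quantile (type-7 interpolation) of
the stored maxima, α = 0.05 by default. One scaling subtlety: re-scaling
0–100 *within* each permutation replicate would pin every maximum at 100,
so the stored maxima are expressed on the observed scan's affine scale
instead. The map is monotone and common to both sides, so the
construction is exactly the permutation distribution of the maximum
statistic and controls family-wise error at α; a threshold above 100
simply means nothing is declared. Fewer than 20 replicates is rejected as
quantile-unstable.

Linear-engine thresholds use Benjamini–Hochberg step-up FDR at q = 0.05.

## Post-GWAS

Significant SNPs within the flank distance of each other (transitively,
per chromosome and method) collapse to the best-statistic peak, ties to
the lower position. Windows are `[max(1, pos − flank), min(L, pos + flank)]`,
merged per method when overlapping (best peak kept); window extraction is
idempotent. A gene is a candidate if it overlaps the window by ≥ 1 bp;
distance is peak-to-nearest-gene-edge, 0 when the gene contains the peak,
and genes sort by that distance. Allelic effects are
`mean(BLUP | dosage 2) − mean(BLUP | dosage 0)`; heterozygotes are
excluded (inbred material), an empty homozygote class yields a missing
effect, and the quantity is exactly antisymmetric under allele
relabeling. The formula slot is pluggable should a different allelic
summary be preferred. The cross-method overlap report matches loci by
window co-location rather than exact base identity (method-specific peaks
shift within LD blocks); counts partition the union of loci.

## Synthetic panels

Haplotypes are first-order Markov chains per chromosome: the allele
correlation between neighbours is `exp(−d·ln2 / (2L))`, so marker r²
halves every `L` bp (`ld_half_length`, default 150 kbp). Ancestral allele
frequencies are *block-constant* (renewal process, mean block ≈ 10 L)
rather than iid per SNP: the Fréchet bound caps the correlation
achievable between frequency-mismatched loci, and iid frequencies made
realized LD decay several-fold faster than configured. Frequency blocks
mirror real LD-block structure and make the configured decay realizable;
Balding–Nichols subpopulation drift (parameter `fst`) is likewise applied
per block. Individuals are haplotype pairs; with probability
`inbreeding` (default 0.95) the second haplotype copies the first, giving
the residual heterozygosity of essentially-inbred lines.

Phenotypes follow the trial design (default 4 environments × 2 blocks,
matching a 2-locations × 2-years RCBD): fixed environment and block
effects, per-genotype genetic value, optional G×E draw, Gaussian
residual. The genetic value is planted QTL (`β = √(share/var(dosage))`
per QTL) plus an *iid* polygenic remainder scaled so total genetic
variance is `h2`; residual variance is `1 − h2`, so the literal
heritability equals `h2` by construction. Defaults mirror the target
panel: 227 genotypes, 20 chromosomes, heritabilities configurable across
the realistic 0.24–0.78 range. Because the polygenic remainder is drawn
independently of the markers, a panel with no planted QTL is an exact
marker-level null with a non-degenerate BLUP phenotype — the reference
object for calibration studies (with `h2 = 0` REML rightly shrinks every
BLUP to zero and there is nothing to scan).

What the generator does *not* emulate: realistic demography and
coalescent LD, allele-frequency/effect-size coupling, non-Gaussian trait
distributions, spatial field trends, and genotype-specific missingness
patterns (missingness is uniform). Passing tests therefore demonstrate
correctness of the machinery and its statistical guarantees under the
stated generative model, not performance on any particular real panel.

## Study sizes used in validation

The automated studies run at sizes chosen to exercise the claims while
staying desk-scale: regression-oracle checks at 50 × 20; null calibration
over 20 panels of 200 × 500 (both linear engines pooled, ≈20k tests);
family-wise-error calibration over 100 panels of 150 × 300 with 200
permutation replicates per panel and single-fit engine configurations
(25-tree forests); power at the panel's native 227 × 2000 with a
20%-variance QTL over 20 replicates; variance-component recovery over 50
fits. The acceptance script repeats the same studies at moderately
reduced replicate counts and records the size next to every number.

## Known limitations

- The MLM scan shares one δ across markers; markers with very large
  effects would warrant exact per-SNP REML (deliberately out of scope).
- FarmCPU's random-effect step rebuilds a kinship from few pseudo-QTNs;
  with t = 2 this likelihood is low-rank and occasionally selects more
  pseudo-QTNs than there are true signals. Final inference comes from the
  conditioned fixed-effect scan, which stays calibrated under the null.
- Permutation thresholds assume exchangeability of the phenotype across
  individuals; strong unmodelled structure in the BLUPs (e.g. severe
  stratification not captured by covariates) would weaken the guarantee.
- Spatial (nearest-neighbour) field adjustment and maturity-adjusted
  yield correction are not implemented; the data model carries no plot
  coordinates.
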