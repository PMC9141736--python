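"""Generate a synthetic soybean-like GWAS panel and inspect its structure.

Builds a 227-genotype, 2000-SNP inbred panel with LD blocks, a planted
QTL and multi-environment phenotypes, then prints marker QC and LD-decay
summaries.  The printed decay distance is what sets the QTL window flank
in the post-GWAS stage.
"""

from mlgwas import (apply_snp_qc, compute_snp_qc, estimate_ld_decay,
                    impute_markov, pairwise_r2)
from mlgwas.simdata import QtlSpec, SimulationConfig, simulate_panel

cfg = SimulationConfig(
    n_individuals=227, n_snps=2000, n_chromosomes=20,
    ld_half_length=150_000, qtl=(QtlSpec("random", 0.2),),
    h2=0.5, missing_rate=0.02, seed=11,
)
sim = simulate_panel(cfg)
print(f"panel: {sim.panel.n_samples} genotypes x {sim.panel.n_snps} SNPs "
      f"on {len(set(sim.panel.chrom))} chromosomes")
print(f"planted QTL: {sim.causal_snp_ids[0]} "
      f"(per-allele effect {sim.causal_effects[0]:.3f} trait SD)")

report = compute_snp_qc(sim.panel)
kept = int(report.df["kept"].sum())
print(f"QC: {kept}/{sim.panel.n_snps} SNPs pass (MAF >= 0.05, het <= 0.5)")

panel = impute_markov(apply_snp_qc(sim.panel, report))
pairs = pairwise_r2(panel, max_dist=1_000_000)
curve = estimate_ld_decay(pairs, bin_width=25_000)
print(f"LD decay: r2 falls to {curve.r2_level:.3f} at "
      f"{curve.decay_distance / 1000:.0f} kbp "
      f"(half-decay configured at {cfg.ld_half_length / 1000:.0f} kbp)")
# The decay distance motivates the default 150-kbp QTL window flank.
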