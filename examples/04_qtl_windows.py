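"""From significant markers to QTL windows, candidate genes and effects.

Takes an association table, collapses significant SNPs into peaks,
builds 150-kbp flanking windows, intersects them with gene models and
summarizes the allelic effect (difference between homozygote-class BLUP
means) at each peak.
"""

import numpy as np
import pandas as pd

from mlgwas import (GeneAnnotation, annotate_candidate_genes,
                    apply_snp_qc, bh_fdr_threshold, call_significant,
                    compute_kinship, compute_snp_qc, estimate_allele_effects,
                    extract_qtl_windows, fit_mlm_null, fit_multi_env_blup,
                    impute_markov, mlm_scan)
from mlgwas.io_formats import AssociationTable
from mlgwas.simdata import QtlSpec, SimulationConfig, simulate_panel

sim = simulate_panel(SimulationConfig(
    n_individuals=150, n_snps=400, n_chromosomes=4,
    qtl=(QtlSpec("random", 0.3),), h2=0.5, seed=41))
panel = impute_markov(apply_snp_qc(sim.panel, compute_snp_qc(sim.panel)))
fit = fit_multi_env_blup(sim.phenotypes)
y = fit.blups.reindex(panel.sample_ids).to_numpy()

res = mlm_scan(fit_mlm_null(y, None, compute_kinship(panel)), panel, y)
thr, sig = bh_fdr_threshold(res.df["p_value"].to_numpy(), q=0.05)
table = AssociationTable(df=pd.DataFrame({
    "snp_id": res.df["snp_id"], "chrom": res.df["chrom"], "pos": res.df["pos"],
    "method": "MLM", "statistic": res.df["p_value"],
    "threshold": 0.0 if np.isnan(thr) else thr, "significant": sig}))

peaks = call_significant(table, flank=150_000)
print(f"{int(sig.sum())} significant SNPs collapse to {len(peaks)} peak(s)")

windows = extract_qtl_windows(peaks, flank=150_000)
# a toy annotation: one gene at the causal position, one 119 kbp away
cj = list(panel.snp_ids).index(sim.causal_snp_ids[0])
pos, chrom = int(panel.pos[cj]), str(panel.chrom[cj])
genes = [
    GeneAnnotation("Gene.at.peak", chrom, pos - 2000, pos + 2000),
    GeneAnnotation("Gene.119kb", chrom, pos + 119_000, pos + 125_000),
    GeneAnnotation("Gene.far", chrom, pos + 600_000, pos + 610_000),
]
for w in annotate_candidate_genes(windows, genes):
    print(f"window {w.chrom}:{w.start}-{w.end} (peak {w.peak_snp})")
    for g, d in zip(w.genes, w.gene_distances):
        print(f"  candidate {g.gene_id}  edge distance {d / 1000:.0f} kbp")

for e in estimate_allele_effects(panel, fit.blups, peaks, trait="trait"):
    print(f"allelic effect at {e.snp_id}: ref mean {e.mean_ref:+.3f} "
          f"(n={e.n_ref}), alt mean {e.mean_alt:+.3f} (n={e.n_alt}), "
          f"effect {e.effect:+.3f}")
# Genes whose edge lies within the 150-kbp flank are candidates; a gene
# containing the peak has distance 0 and is listed first.
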