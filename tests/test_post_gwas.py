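"""QTL windows, candidate genes, allele effects and overlap reports."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mlgwas.io_formats import AssociationTable, GeneAnnotation
from mlgwas.post_gwas import (DEFAULT_FLANK, annotate_candidate_genes,
                              call_significant, estimate_allele_effects,
                              export_manhattan_qq, extract_qtl_windows,
                              method_overlap_report)

from conftest import make_random_panel


def _table(positions, stats, sig, method="MLM", chrom="Chr01", threshold=0.05):
    n = len(positions)
    return AssociationTable(df=pd.DataFrame({
        "snp_id": [f"{chrom}_{p}" for p in positions],
        "chrom": [chrom] * n,
        "pos": positions,
        "method": [method] * n,
        "statistic": stats,
        "threshold": [threshold] * n,
        "significant": sig,
    }))


class TestCallSignificant:
    def test_nearby_snps_collapse_to_best(self):
        """Two significant SNPs 10 kb apart with a 150 kb flank: one peak."""
        t = _table([100_000, 110_000], [0.001, 0.0001], [True, True])
        peaks = call_significant(t, flank=150_000)
        assert len(peaks) == 1
        assert peaks["pos"].iloc[0] == 110_000  # smaller p wins

    def test_empty_when_nothing_passes(self):
        t = _table([1000, 2000], [0.5, 0.9], [False, False])
        assert len(call_significant(t)) == 0

    def test_matches_transitive_closure_oracle(self):
        """Peak grouping equals brute-force transitive clustering on a
        20-SNP toy."""
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 20, replace=False))
        stats = rng.uniform(1e-6, 0.04, 20)
        t = _table(list(pos), list(stats), [True] * 20)
        flank = 150_000
        peaks = call_significant(t, flank=flank)
        # oracle: union-find over pairs closer than flank
        parent = list(range(20))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(20), 2):
            if abs(pos[i] - pos[j]) < flank:
                parent[find(i)] = find(j)
        clusters = {}
        for i in range(20):
            clusters.setdefault(find(i), []).append(i)
        expected = sorted(
            pos[min((i for i in members), key=lambda i: (stats[i], pos[i]))]
            for members in clusters.values())
        assert sorted(peaks["pos"]) == expected


class TestWindows:
    def test_flank_arithmetic_and_clipping(self):
        peaks = pd.DataFrame({
            "snp_id": ["a", "b"], "chrom": ["Chr01", "Chr02"],
            "pos": [200_000, 100_000], "method": ["MLM", "MLM"],
            "statistic": [0.001, 0.002]})
        wins = extract_qtl_windows(peaks, flank=150_000,
                                   chrom_lengths={"Chr01": 10**7, "Chr02": 10**7})
        assert (wins[0].start, wins[0].end) == (50_000, 350_000)
        assert (wins[1].start, wins[1].end) == (1, 250_000)

    def test_default_flank_is_150kb(self):
        assert DEFAULT_FLANK == 150_000

    def test_merge_is_idempotent(self):
        peaks = pd.DataFrame({
            "snp_id": ["a", "b", "c"], "chrom": ["Chr01"] * 3,
            "pos": [500_000, 550_000, 5_000_000], "method": ["SVR"] * 3,
            "statistic": [80.0, 95.0, 70.0]})
        wins = extract_qtl_windows(peaks, flank=150_000)
        assert len(wins) == 2
        assert wins[0].peak_snp == "b"  # larger importance wins
        again = extract_qtl_windows(pd.DataFrame([{
            "snp_id": w.peak_snp, "chrom": w.chrom, "pos": w.peak_pos,
            "method": w.method, "statistic": w.peak_statistic} for w in wins]),
            flank=150_000)
        assert [(w.start, w.end) for w in again] == \
               [(w.peak_pos - 150_000, w.peak_pos + 150_000) for w in wins]


class TestCandidateGenes:
    def _window(self):
        return extract_qtl_windows(pd.DataFrame([{
            "snp_id": "peak", "chrom": "Chr19", "pos": 1_000_000,
            "method": "SVR", "statistic": 90.0}]), flank=150_000)

    def test_edge_distance_inclusion(self):
        """Gene edge 119 kb from the peak included; 151 kb away excluded;
        a gene containing the peak has distance 0 and sorts first."""
        genes = [
            GeneAnnotation("far", "Chr19", 1_151_000, 1_200_000),
            GeneAnnotation("near", "Chr19", 1_119_000, 1_140_000),
            GeneAnnotation("at_peak", "Chr19", 995_000, 1_005_000),
        ]
        w = annotate_candidate_genes(self._window(), genes)[0]
        ids = [g.gene_id for g in w.genes]
        assert "near" in ids and "far" not in ids
        assert ids[0] == "at_peak" and w.gene_distances[0] == 0
        assert w.gene_distances[ids.index("near")] == 119_000
        assert all(d <= 150_000 for d in w.gene_distances)

    def test_other_chromosome_excluded(self):
        genes = [GeneAnnotation("elsewhere", "Chr01", 1_000_000, 1_010_000)]
        w = annotate_candidate_genes(self._window(), genes)[0]
        assert w.genes == []


class TestAlleleEffects:
    def test_class_means_and_antisymmetry(self):
        panel = make_random_panel(40, 5, seed=2)
        panel.dosage[:, 1] = np.r_[np.zeros(20), np.full(20, 2.0)]
        blups = pd.Series(np.r_[np.full(20, 3.0), np.full(20, 3.4)],
                          index=panel.sample_ids)
        peaks = pd.DataFrame([{"snp_id": "m1", "chrom": "Chr01", "pos": 1,
                               "method": "MLM", "statistic": 0.001}])
        eff = estimate_allele_effects(panel, blups, peaks)[0]
        assert eff.effect == pytest.approx(0.4)
        assert (eff.n_ref, eff.n_alt) == (20, 20)
        # swap ref/alt labels == flip dosage: effect negates exactly
        panel.dosage[:, 1] = 2.0 - panel.dosage[:, 1]
        eff2 = estimate_allele_effects(panel, blups, peaks)[0]
        assert eff2.effect == pytest.approx(-eff.effect)

    def test_empty_class_reported_missing(self):
        panel = make_random_panel(10, 3, seed=3)
        panel.dosage[:, 0] = 2.0
        blups = pd.Series(np.arange(10, dtype=float), index=panel.sample_ids)
        peaks = pd.DataFrame([{"snp_id": "m0", "chrom": "Chr01", "pos": 1,
                               "method": "MLM", "statistic": 0.001}])
        eff = estimate_allele_effects(panel, blups, peaks)[0]
        assert eff.n_ref == 0 and np.isnan(eff.mean_ref)


class TestOverlapReport:
    def test_identical_sets_full_intersection(self):
        t1 = _table([100_000], [0.001], [True], method="MLM")
        t2 = _table([100_000], [90.0], [True], method="SVR", threshold=80.0)
        rep = method_overlap_report({"MLM": t1, "SVR": t2})
        assert len(rep) == 1
        assert rep["methods"].iloc[0] == "MLM+SVR" and rep["n_loci"].iloc[0] == 1

    def test_disjoint_sets_singletons(self):
        t1 = _table([100_000], [0.001], [True], method="MLM")
        t2 = _table([5_000_000], [90.0], [True], method="SVR", threshold=80.0)
        rep = method_overlap_report({"MLM": t1, "SVR": t2})
        assert set(rep["methods"]) == {"MLM", "SVR"}
        assert rep["n_loci"].sum() == 2  # counts partition the union

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(4)
        tables = {}
        for method, scale in (("MLM", None), ("RF", 80.0), ("SVR", 80.0)):
            pos = list(np.sort(rng.choice(np.arange(1, 10**7), 8, replace=False)))
            if scale is None:
                tables[method] = _table(pos, list(rng.uniform(1e-5, 0.04, 8)),
                                        [True] * 8, method=method)
            else:
                tables[method] = _table(pos, list(rng.uniform(81, 100, 8)),
                                        [True] * 8, method=method, threshold=scale)
        rep = method_overlap_report(tables, flank=150_000)
        pooled = pd.concat([call_significant(t, 150_000) for t in tables.values()])
        # clusters of the pooled peaks = union loci
        union = 0
        for chrom, grp in pooled.groupby("chrom"):
            pos = np.sort(grp["pos"].to_numpy())
            union += 1 + int((np.diff(pos) >= 150_000).sum())
        assert rep["n_loci"].sum() == union


class TestManhattanQq:
    def test_cumulative_offsets_and_qq(self, tmp_path):
        df1 = _table([100, 200], [0.01, 0.5], [True, False], chrom="Chr01").df
        df2 = _table([50], [0.3], [False], chrom="Chr02").df
        table = AssociationTable(df=pd.concat([df1, df2], ignore_index=True))
        out = export_manhattan_qq(table, str(tmp_path / "x"),
                                  chrom_lengths={"Chr01": 1000, "Chr02": 500})
        man = pd.read_csv(out["manhattan"], sep="\t")
        assert man["genome_pos"].tolist() == [100, 200, 1050]
        qq = pd.read_csv(out["qq"], sep="\t")
        assert len(qq) == 3
        assert (qq["observed_neglog10"].to_numpy()
                == np.sort(qq["observed_neglog10"])[::-1]).all()

    def test_qq_skipped_for_importance_methods(self, tmp_path):
        t = _table([100], [90.0], [True], method="RF", threshold=80.0)
        out = export_manhattan_qq(t, str(tmp_path / "rf"))
        assert "qq" not in out

    def test_uniform_pvalues_on_diagonal(self, tmp_path):
        rng = np.random.default_rng(5)
        m = 500
        pos = list(np.sort(rng.choice(np.arange(1, 10**6), m, replace=False)))
        t = _table(pos, list(rng.uniform(1e-4, 1.0, m)), [False] * m)
        out = export_manhattan_qq(t, str(tmp_path / "u"))
        qq = pd.read_csv(out["qq"], sep="\t")
        resid = qq["observed_neglog10"] - qq["expected_neglog10"]
        assert np.abs(resid[qq["expected_neglog10"] < 2]).max() < 0.5
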