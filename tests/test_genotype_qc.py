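"""QC filters, Markov imputation, kinship, PCA and LD machinery."""

import numpy as np
import pandas as pd
import pytest

from mlgwas.genotype_qc import (apply_snp_qc, compute_kinship, compute_snp_qc,
                                estimate_ld_decay, impute_markov,
                                pairwise_r2, pca_covariates)
from mlgwas.io_formats import GenotypePanel
from mlgwas.simdata import SimulationConfig, simulate_genotypes

from conftest import make_random_panel


def _panel_from_dosage(dosage, pos=None, chrom=None):
    n, p = dosage.shape
    return GenotypePanel(
        sample_ids=[f"S{i}" for i in range(n)],
        snp_ids=[f"m{j}" for j in range(p)],
        chrom=chrom if chrom is not None else ["Chr01"] * p,
        pos=pos if pos is not None else np.arange(1, p + 1) * 1000,
        ref_allele=["A"] * p,
        alt_allele=["G"] * p,
        dosage=np.asarray(dosage, dtype=float),
    )


class TestSnpQc:
    def test_maf_counting(self):
        """Counts (0:100, 1:20, 2:0) over 120 samples -> MAF 20/240, kept."""
        col = np.array([0] * 100 + [1] * 20, dtype=float)
        panel = _panel_from_dosage(col[:, None])
        rep = compute_snp_qc(panel)
        assert rep.df.loc[0, "maf"] == pytest.approx(20 / 240)
        assert rep.df.loc[0, "kept"]

    def test_thresholds_are_strict(self):
        """MAF 0.049 removed; het rate 0.51 removed; boundary values kept."""
        n = 1000
        low_maf = np.r_[np.ones(98), np.zeros(n - 98)]          # maf 0.049
        ok_maf = np.r_[np.ones(100), np.zeros(n - 100)]         # maf 0.050
        high_het = np.r_[np.ones(510), np.zeros(n - 510) + 2]   # het 0.51
        ok_het = np.r_[np.ones(500), np.zeros(n - 500) + 2]     # het 0.50
        panel = _panel_from_dosage(np.c_[low_maf, ok_maf, high_het, ok_het])
        rep = compute_snp_qc(panel)
        assert list(rep.df["kept"]) == [False, True, False, True]
        assert list(rep.df["reason"]) == ["low_maf", "pass", "high_het", "pass"]

    def test_all_missing_column_dropped(self):
        dosage = np.c_[np.full(10, np.nan), np.r_[np.ones(5), np.zeros(5)]]
        rep = compute_snp_qc(_panel_from_dosage(dosage))
        assert not rep.df.loc[0, "kept"] and rep.df.loc[0, "reason"] == "low_maf"

    def test_defaults_hold_on_simulated_panel(self):
        """Every retained SNP has MAF >= 0.05 and het <= 0.5 (invariant)."""
        panel = simulate_genotypes(SimulationConfig(
            n_individuals=120, n_snps=400, maf_range=(0.01, 0.5),
            missing_rate=0.05, seed=2))
        rep = compute_snp_qc(panel)
        kept = rep.df[rep.df["kept"]]
        assert (kept["maf"] >= 0.05).all() and (kept["het_rate"] <= 0.5).all()
        assert rep.df["kept"].sum() > 0


class TestImputeMarkov:
    def test_identity_when_complete(self, tiny_panel):
        complete = tiny_panel.take_snps([0, 1, 2])
        out = impute_markov(complete)
        np.testing.assert_array_equal(out.dosage, complete.sorted_by_position().dosage)

    def test_matches_correlated_neighbor(self):
        """Two perfectly correlated adjacent SNPs: missing call copies neighbor."""
        left = np.array([0, 0, 2, 2, 0, 2, 0, 2, 2, 0], dtype=float)
        right = left.copy()
        right[3] = np.nan
        out = impute_markov(_panel_from_dosage(np.c_[left, right]))
        assert out.dosage[3, 1] == left[3]
        # observed calls untouched
        mask = ~np.isnan(np.c_[left, right])
        np.testing.assert_array_equal(out.dosage[mask], np.c_[left, right][mask])

    def test_no_missing_remains_on_random_panel(self):
        panel = make_random_panel(50, 30, seed=3, missing_rate=0.15)
        out = impute_markov(panel)
        assert not np.isnan(out.dosage).any()
        obs = ~np.isnan(panel.dosage)
        np.testing.assert_array_equal(out.dosage[obs], panel.dosage[obs])

    def test_modal_fallback_single_snp_chromosome(self):
        col = np.array([2, 2, 2, 0, np.nan])[:, None]
        out = impute_markov(_panel_from_dosage(col))
        assert out.dosage[4, 0] == 2  # modal dosage


class TestKinship:
    def test_direct_formula_oracle(self):
        """Equals brute-force centered cross-product on a 4 x 6 toy matrix."""
        rng = np.random.default_rng(1)
        D = rng.binomial(2, 0.4, size=(4, 6)).astype(float)
        K = compute_kinship(_panel_from_dosage(D)).values
        p = D.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        W = D[:, poly] - 2 * p[poly]
        expected = W @ W.T / np.sum(2 * p[poly] * (1 - p[poly]))
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_duplicated_individual(self):
        """A copied individual's off-diagonal with its copy equals its diagonal."""
        base = make_random_panel(20, 50, seed=4)
        D = np.vstack([base.dosage, base.dosage[0:1]])
        K = compute_kinship(_panel_from_dosage(D)).values
        assert K[0, 20] == pytest.approx(K[0, 0], rel=1e-12)
        np.testing.assert_allclose(K, K.T, atol=0)

    def test_unrelated_mean_off_diagonal_near_zero(self):
        """Unrelated individuals: mean relatedness ~ 0.

        In-sample centering makes every row of K sum to (numerically)
        zero, so the mean off-diagonal equals -trace/(n(n-1)) = O(1/n)
        exactly; assert both the identity and the vanishing magnitude.
        """
        n = 100
        panel = make_random_panel(n, 500, seed=5)
        K = compute_kinship(panel).values
        np.testing.assert_allclose(K.sum(axis=1), np.zeros(n), atol=1e-9)
        off = K[np.triu_indices(n, k=1)]
        assert off.mean() == pytest.approx(-np.trace(K) / (n * (n - 1)), abs=1e-12)
        assert abs(off.mean()) < 2.0 / (n - 1)


class TestPca:
    def test_subpopulation_separation(self):
        panel = simulate_genotypes(SimulationConfig(
            n_individuals=80, n_snps=500, n_subpops=2, fst=0.3, seed=6))
        pc1 = pca_covariates(panel, 1)[:, 0]
        a, b = pc1[:40], pc1[40:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
               max(b.min(), a.min()) > min(b.max(), a.max()) or \
               (a.max() < b.min()) or (b.max() < a.min())

    def test_q_zero_and_orthogonality(self):
        panel = make_random_panel(30, 60, seed=7)
        assert pca_covariates(panel, 0).shape == (30, 0)
        scores = pca_covariates(panel, 4)
        gram = scores.T @ scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)),
                                   np.zeros((4, 4)), atol=1e-8)

    def test_deterministic_sign(self):
        panel = make_random_panel(30, 60, seed=8)
        np.testing.assert_array_equal(pca_covariates(panel, 3),
                                      pca_covariates(panel, 3))


class TestLd:
    def test_r2_extremes_and_bruteforce(self):
        rng = np.random.default_rng(9)
        a = rng.binomial(2, 0.5, 40).astype(float)
        b = 2.0 - a                       # perfectly anticorrelated -> r2 = 1
        c = rng.binomial(2, 0.5, 40).astype(float)
        D = np.c_[a, b, c, a, c]
        panel = _panel_from_dosage(D, pos=np.array([100, 200, 300, 400, 500]))
        pairs = pairwise_r2(panel, max_dist=1e6)
        got = {(r.pos1, r.pos2): r.r2 for r in pairs.itertuples()}
        assert got[(100, 200)] == pytest.approx(1.0)
        assert got[(100, 400)] == pytest.approx(1.0)
        for (p1, p2), r2 in got.items():
            j1 = [100, 200, 300, 400, 500].index(p1)
            j2 = [100, 200, 300, 400, 500].index(p2)
            expected = np.corrcoef(D[:, j1], D[:, j2])[0, 1] ** 2
            assert r2 == pytest.approx(expected, abs=1e-12)

    def test_r2_coding_symmetric(self):
        panel = make_random_panel(60, 10, seed=10)
        flipped = _panel_from_dosage(2.0 - panel.dosage, pos=panel.pos)
        a = pairwise_r2(panel, 1e7)
        b = pairwise_r2(flipped, 1e7)
        np.testing.assert_allclose(a["r2"], b["r2"], atol=1e-12)

    def test_decay_distance_recovers_construction(self):
        """Simulated LD half-length recovered within 25%."""
        L = 200_000.0
        panel = simulate_genotypes(SimulationConfig(
            n_individuals=200, n_snps=1500, n_chromosomes=5,
            chrom_length=5_000_000, ld_half_length=L, seed=11))
        pairs = pairwise_r2(panel, max_dist=1_500_000)
        curve = estimate_ld_decay(pairs, bin_width=25_000, r2_level=None)
        assert curve.crossed
        assert curve.decay_distance == pytest.approx(L, rel=0.25)

    def test_first_crossing_on_nonmonotone_input(self):
        pairs = pd.DataFrame({
            "dist": [5, 15, 25, 35], "r2": [0.9, 0.2, 0.6, 0.1],
            "chrom": "c", "pos1": 0, "pos2": 0})
        curve = estimate_ld_decay(pairs, bin_width=10, r2_level=0.5)
        assert curve.crossed and 5 < curve.decay_distance <= 15

    def test_never_crossing_flagged(self):
        pairs = pd.DataFrame({"dist": [5, 15], "r2": [0.9, 0.8],
                              "chrom": "c", "pos1": 0, "pos2": 0})
        curve = estimate_ld_decay(pairs, bin_width=10, r2_level=0.1)
        assert not curve.crossed and curve.decay_distance == 15
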