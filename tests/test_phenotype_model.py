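"""Mixed-model fits: outliers, REML components, BLUPs, heritability."""

import numpy as np
import pandas as pd
import pytest

from mlgwas.io_formats import PhenotypeTable
from mlgwas.phenotype_model import (VarianceComponents, detect_outliers,
                                    estimate_heritability, fit_multi_env_blup,
                                    trait_correlations)
from mlgwas.simdata import SimulationConfig, simulate_panel


def _long_table(values: dict) -> PhenotypeTable:
    """values: {(geno, env, block): y} -> table (env label 'L1:2018' style)."""
    rows = []
    for (g, env, b), v in values.items():
        loc, year = env.split(":")
        rows.append((g, loc, year, b, "t", v))
    return PhenotypeTable(records=pd.DataFrame(
        rows, columns=["sample_id", "location", "year", "block", "trait", "value"]))


class TestOutliers:
    def test_gross_outlier_flagged(self):
        vals = {("G%d" % i, "L1:2018", "B1"): 1.0 for i in range(3)}
        vals[("G3", "L1:2018", "B1")] = 100.0
        out = detect_outliers(_long_table(vals))
        assert out.records["value"].isna().sum() == 1
        assert out.records.loc[out.records["value"].isna(), "sample_id"].iloc[0] == "G3"

    def test_constant_trait_untouched(self):
        vals = {("G%d" % i, "L1:2018", "B1"): 5.0 for i in range(6)}
        out = detect_outliers(_long_table(vals))
        assert out.records["value"].notna().all()

    def test_null_flag_rate_below_2pct(self):
        rng = np.random.default_rng(0)
        vals = {("G%d" % i, f"L{e}:2018", "B1"): rng.normal()
                for i in range(500) for e in (1, 2)}
        out = detect_outliers(_long_table(vals))
        assert out.records["value"].isna().mean() < 0.02


def _dense_blup_oracle(df: pd.DataFrame, comps: VarianceComponents):
    """Direct GLS/BLUP via full covariance inversion (independent route)."""
    genos = sorted(df["sample_id"].unique())
    cells = sorted((df["environment"] + "/" + df["block"]).unique())
    n = len(df)
    X = np.ones((n, 1))
    if len(cells) > 1:
        X = np.hstack([X, pd.get_dummies(
            pd.Categorical(df["environment"] + "/" + df["block"], categories=cells),
            drop_first=True, dtype=float).to_numpy()])
    Zg = pd.get_dummies(pd.Categorical(df["sample_id"], categories=genos),
                        dtype=float).to_numpy()
    ge = sorted((df["sample_id"] + "/" + df["environment"]).unique())
    Zi = pd.get_dummies(pd.Categorical(df["sample_id"] + "/" + df["environment"],
                                       categories=ge), dtype=float).to_numpy()
    y = df["value"].to_numpy(dtype=float)
    V = (comps.sigma2_g * Zg @ Zg.T + comps.sigma2_int * Zi @ Zi.T
         + comps.sigma2_e * np.eye(n))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta
    blup = comps.sigma2_g * Zg.T @ Vi @ resid
    return pd.Series(blup, index=genos)


class TestBlupFit:
    def test_dense_mme_oracle_balanced(self):
        """Balanced 5 genotypes x 2 envs x 2 blocks: BLUPs match the dense
        GLS solution at the fitted components within 1e-6."""
        rng = np.random.default_rng(1)
        g_eff = rng.normal(0, 1, 5)
        vals = {}
        for i in range(5):
            for e in ("L1:2018", "L2:2018"):
                for b in ("B1", "B2"):
                    vals[(f"G{i}", e, b)] = g_eff[i] + rng.normal(0, 0.7)
        table = _long_table(vals)
        fit = fit_multi_env_blup(table, trait="t")
        df = table.for_trait("t")
        oracle = _dense_blup_oracle(df, fit.components)
        np.testing.assert_allclose(fit.blups.to_numpy(),
                                   oracle.reindex(fit.blups.index).to_numpy(),
                                   atol=1e-6)

    def test_no_signal_gives_zero_blups(self):
        sim = simulate_panel(SimulationConfig(
            n_individuals=60, n_snps=20, h2=0.0, seed=2))
        fit = fit_multi_env_blup(sim.phenotypes)
        resid_sd = np.sqrt(fit.components.sigma2_e)
        assert np.abs(fit.blups.to_numpy()).max() < 3 * resid_sd

    def test_blups_shrink_and_center(self):
        sim = simulate_panel(SimulationConfig(
            n_individuals=80, n_snps=20, h2=0.4, seed=3))
        fit = fit_multi_env_blup(sim.phenotypes)
        b = fit.blups.to_numpy()
        assert abs(b.sum()) < 1e-6 * len(b) * max(b.std(), 1e-9)
        # balanced data: |BLUP| <= |raw genotype mean deviation|
        df = sim.phenotypes.for_trait("trait")
        means = df.groupby("sample_id")["value"].mean().reindex(fit.blups.index)
        dev = (means - means.mean()).to_numpy()
        assert (np.abs(b) <= np.abs(dev) + 1e-8).all()

    def test_loglik_trace_monotone(self):
        sim = simulate_panel(SimulationConfig(
            n_individuals=50, n_snps=20, h2=0.5, seed=4))
        fit = fit_multi_env_blup(sim.phenotypes)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-10).all()

    def test_variance_recovery(self):
        """sigma2_g recovered within 25% (mean over replicates)."""
        est = []
        for s in range(10):
            sim = simulate_panel(SimulationConfig(
                n_individuals=120, n_snps=20, h2=0.5, gxe_sd=0.3, seed=100 + s))
            fit = fit_multi_env_blup(sim.phenotypes)
            est.append(fit.components.sigma2_g)
        assert np.mean(est) == pytest.approx(0.5, rel=0.25)

    def test_gxe_dropped_without_replication(self):
        vals = {(f"G{i}", e, "B1"): float(i)
                for i in range(6) for e in ("L1:2018", "L2:2018")}
        with pytest.warns(UserWarning, match="G x E"):
            fit = fit_multi_env_blup(_long_table(vals), trait="t")
        assert fit.components.sigma2_int == 0.0


class TestHeritability:
    @pytest.mark.parametrize("sg,se,expected", [(1.0, 1.0, 0.5), (0.0, 1.0, 0.0),
                                                (3.0, 1.0, 0.75)])
    def test_ratio(self, sg, se, expected):
        comps = VarianceComponents(sigma2_g=sg, sigma2_int=0.2, sigma2_e=se)
        assert estimate_heritability(comps) == pytest.approx(expected)

    def test_undefined_raises(self):
        comps = VarianceComponents(sigma2_g=0.0, sigma2_int=0.5, sigma2_e=0.0)
        with pytest.raises(ValueError):
            estimate_heritability(comps)

    def test_plot_basis_variant_larger(self):
        comps = VarianceComponents(sigma2_g=1.0, sigma2_int=0.5, sigma2_e=1.0)
        literal = estimate_heritability(comps)
        entry_mean = estimate_heritability(comps, plot_basis=True, n_env=4, n_rep=2)
        assert 0 <= literal <= entry_mean <= 1

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            sg, si, se = rng.uniform(0, 5, 3)
            h2 = estimate_heritability(
                VarianceComponents(sigma2_g=sg, sigma2_int=si, sigma2_e=se))
            assert 0.0 <= h2 <= 1.0


class TestTraitCorrelations:
    def _fits(self, seed=6):
        sim = simulate_panel(SimulationConfig(
            n_individuals=80, n_snps=20, h2=0.5, seed=seed))
        return fit_multi_env_blup(sim.phenotypes)

    def test_duplicate_and_negated(self):
        fit = self._fits()
        import copy
        neg = copy.deepcopy(fit)
        neg.blups = -fit.blups
        corr = trait_correlations({"a": fit, "b": fit, "c": neg})
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)

    def test_component_sum_sign_pattern(self):
        """A total built as the sum of a dominant and a minor, anticorrelated
        component correlates positively with the dominant part and
        negatively with the minor one (node-count trait structure)."""
        fit = self._fits()
        import copy
        rng = np.random.default_rng(7)
        rnp = copy.deepcopy(fit)          # dominant component
        nrnp = copy.deepcopy(fit)         # minor, anticorrelated component
        nrnp.blups = -0.25 * fit.blups + pd.Series(
            rng.normal(0, 0.1 * fit.blups.std(), len(fit.blups)),
            index=fit.blups.index)
        total = copy.deepcopy(fit)
        total.blups = rnp.blups + nrnp.blups
        corr = trait_correlations({"NP": total, "RNP": rnp, "NRNP": nrnp})
        assert corr.loc["NP", "RNP"] > 0.8
        assert corr.loc["NP", "NRNP"] < 0
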