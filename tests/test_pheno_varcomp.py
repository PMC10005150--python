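"""Variance components, heritability, BLUPs, G-by-E and correlations."""

import numpy as np
import pandas as pd
import pytest

from lupinqg import pheno_varcomp as pv
from lupinqg.pheno_varcomp import RCBDModel, VarianceComponents


def long_table(values, trait="t", env="e"):
    """values: lines x blocks array -> long-format records."""
    values = np.asarray(values, float)
    n, b = values.shape
    rows = [(f"L{i}", env, f"B{j}", trait, values[i, j])
            for i in range(n) for j in range(b)]
    return pd.DataFrame(rows, columns=["line", "env", "block",
                                       "trait", "value"])


class TestRCBD:
    def test_hand_anova_no_noise(self):
        # 3 lines x 2 blocks, line effects (-1, 0, 1), block effect +0.5
        base = np.array([[-1.0, -0.5], [0.0, 0.5], [1.0, 1.5]])
        vc = pv.fit_rcbd(long_table(base), "t", "e")
        # MS_error = 0; MS_genotype = 2 * var(line means) = 2; s2_g = MSG/2
        assert vc.s2_e == pytest.approx(0.0, abs=1e-12)
        assert vc.s2_g == pytest.approx(1.0, abs=1e-10)

    def test_all_values_equal_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            vc = pv.fit_rcbd(long_table(np.ones((4, 3))), "t", "e")
        assert vc.s2_g == 0.0 and vc.degenerate

    def test_single_block_rejected(self):
        with pytest.raises(ValueError, match="block"):
            pv.fit_rcbd(long_table(np.ones((4, 1))), "t", "e")

    def test_balanced_reml_equals_mean_squares(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, size=(30, 3)) + rng.normal(0, 1, 30)[:, None]
        model = RCBDModel(long_table(y), "t", "e")
        vc_ms = model._fit_balanced()
        model._long = long_table(y)
        vc_reml = model._fit_reml()
        assert vc_reml.s2_g == pytest.approx(vc_ms.s2_g, rel=1e-4, abs=1e-6)
        assert vc_reml.s2_e == pytest.approx(vc_ms.s2_e, rel=1e-4)

    def test_unbalanced_data_fall_back_to_reml(self):
        rng = np.random.default_rng(4)
        table = long_table(rng.normal(size=(20, 3))
                           + rng.normal(0, 2, 20)[:, None])
        table = table.drop(index=[0, 4, 10]).reset_index(drop=True)
        with pytest.warns(UserWarning, match="unbalanced"):
            res = RCBDModel(table, "t", "e").fit()
        assert res.vc.s2_g > 0 and not res.vc.balanced

    def test_simulation_recovery_unbiased(self):
        rng = np.random.default_rng(5)
        s2g_true, s2e_true = 2.0, 1.5
        est_g, est_e = [], []
        for _ in range(200):
            g = rng.normal(0, np.sqrt(s2g_true), 50)
            y = g[:, None] + rng.normal(0, np.sqrt(s2e_true), (50, 3))
            vc = pv.fit_rcbd(long_table(y), "t", "e")
            est_g.append(vc.s2_g)
            est_e.append(vc.s2_e)
        se_g = np.std(est_g) / np.sqrt(200)
        assert np.mean(est_g) == pytest.approx(s2g_true, abs=4 * se_g)
        assert np.mean(est_e) == pytest.approx(s2e_true, abs=0.05)


class TestDerived:
    def vc(self, s2_g, s2_e, n=3, m=10.0):
        return VarianceComponents(trait="t", environment="e", s2_g=s2_g,
                                  s2_e=s2_e, n_reps=n, mean=m,
                                  f_genotype=1.0, p_genotype=0.5)

    @pytest.mark.parametrize("s2g,m,expected", [
        (1.0, 100.0, 1.0), (0.0, 10.0, 0.0), (4.0, 10.0, 20.0)])
    def test_genetic_cv(self, s2g, m, expected):
        assert pv.genetic_cv(self.vc(s2g, 1.0, m=m)) == pytest.approx(expected)

    def test_genetic_cv_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            pv.genetic_cv(self.vc(1.0, 1.0, m=0.0))

    @pytest.mark.parametrize("s2g,s2e,n,expected", [
        (1.0, 0.0, 3, 1.0), (1.0, 3.0, 3, 0.5), (1.0, 1.0, 1, 0.5)])
    def test_heritability(self, s2g, s2e, n, expected):
        assert pv.heritability(self.vc(s2g, s2e, n)) == pytest.approx(expected)

    def test_heritability_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(pv.heritability(self.vc(0.0, 0.0)))

    def test_blup_shrinkage_arithmetic(self):
        vc = self.vc(1.0, 3.0, m=10.0)       # H2 = 0.5
        means = pd.Series([12.0, 10.0, 8.0], index=["a", "b", "c"])
        blups = pv.compute_blups_from_means(means, vc)
        assert list(blups.values) == [11.0, 10.0, 9.0]

    def test_blup_limits(self):
        means = pd.Series([12.0, 8.0], index=["a", "b"])
        full = pv.compute_blups_from_means(means, self.vc(1.0, 0.0))
        assert np.allclose(full.values, means)     # H2 = 1: line means
        none = pv.compute_blups_from_means(means, self.vc(0.0, 1.0))
        assert np.allclose(none.values, 10.0)      # H2 = 0: grand mean

    def test_blup_variance_never_exceeds_line_mean_variance(self, trial):
        for env in ("env1", "env2"):
            res = RCBDModel(trial.records, "grain_yield", env).fit()
            blups = res.blups()
            means = res.model.wide.mean(axis=1)
            assert blups.values.var() <= means.var() + 1e-12


class TestCrossEnv:
    def test_duplicate_environment_kills_gei(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(20, 3)) + rng.normal(0, 2, 20)[:, None]
        t1 = long_table(y, env="env1")
        t2 = long_table(y, env="env2")
        res = pv.cross_env_anova(pd.concat([t1, t2], ignore_index=True),
                                 "t", cross_of={f"L{i}": "X" for i in range(20)})
        assert res.anova.loc["GEI", "sum_sq"] == pytest.approx(0.0, abs=1e-18)

    def test_gei_null_rarely_significant(self, population, sim_config):
        from lupinqg import simpop
        arch = {"t": simpop.TraitArchitecture(
            name="t", env_means=(0.0, 0.0), genetic_sd=(1.0, 1.0),
            h2_true=(0.5, 0.5), rg_true=1.0)}
        hits = 0
        for rep in range(15):
            trial = simpop.simulate_trial(population, arch, sim_config,
                                          rng=np.random.default_rng(200 + rep))
            res = pv.cross_env_anova(trial.records, "t")
            hits += res.p_gei < 0.05
        assert hits <= 3

    def test_crossover_interaction_detected(self, population, sim_config):
        from lupinqg import simpop
        arch = {"t": simpop.TraitArchitecture(
            name="t", env_means=(0.0, 0.0), genetic_sd=(1.0, 1.0),
            h2_true=(0.6, 0.6), rg_true=-0.8)}
        hits = 0
        for rep in range(10):
            trial = simpop.simulate_trial(population, arch, sim_config,
                                          rng=np.random.default_rng(300 + rep))
            res = pv.cross_env_anova(trial.records, "t")
            hits += res.p_gei < 0.05
        assert hits >= 9

    def test_cross_partition_reports_mean_squares(self, trial):
        res = pv.cross_env_anova(trial.records, "grain_yield")
        for term in ("cross", "line(cross)", "cross x environment"):
            assert term in res.partition.index
            assert res.partition.loc[term, "mean_sq"] > 0

    def test_single_environment_trait_rejected(self, trial):
        one_env = trial.records[trial.records["env"] == "env1"]
        with pytest.raises(ValueError, match="single environment"):
            pv.cross_env_anova(one_env, "grain_yield")

    def test_cross_explains_more_than_line_within_cross(
            self, population, sim_config):
        # with differentiated founder pools the cross factor dominates the
        # within-cross term in the combined ANOVA
        from lupinqg import simpop
        arch = {"t": simpop.TraitArchitecture(
            name="t", env_means=(0.0, 0.0), genetic_sd=(1.0, 1.0),
            h2_true=(0.7, 0.7), rg_true=0.5, n_background_loci=300)}
        trial = simpop.simulate_trial(population, arch, sim_config,
                                      rng=np.random.default_rng(17))
        res = pv.cross_env_anova(trial.records, "t")
        assert res.partition.loc["cross", "mean_sq"] > \
            res.partition.loc["line(cross)", "mean_sq"]


class TestGeneticCorrelation:
    def test_identical_environments_give_unit_correlation(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(30, 3)) + rng.normal(0, 2, 30)[:, None]
        both = pd.concat([long_table(y, env="env1"),
                          long_table(y, env="env2")], ignore_index=True)
        rg = pv.genetic_correlation(both, "t", "env1", "env2")
        assert rg == pytest.approx(1.0)

    def test_permuted_lines_give_near_zero_correlation(self):
        rng = np.random.default_rng(9)
        hits = 0
        for rep in range(20):
            g = rng.normal(0, 2, 140)
            y1 = g[:, None] + rng.normal(size=(140, 3))
            y2 = rng.permutation(g)[:, None] + rng.normal(size=(140, 3))
            both = pd.concat([long_table(y1, env="env1"),
                              long_table(y2, env="env2")], ignore_index=True)
            rg = pv.genetic_correlation(both, "t", "env1", "env2")
            hits += abs(rg) < 0.2
        assert hits >= 18

    def test_zero_genetic_variance_flagged(self):
        rng = np.random.default_rng(10)
        y1 = rng.normal(size=(20, 3)) + rng.normal(0, 2, 20)[:, None]
        y2 = np.ones((20, 3)) * 5.0
        both = pd.concat([long_table(y1, env="env1"),
                          long_table(y2, env="env2")], ignore_index=True)
        with pytest.warns(UserWarning):
            assert np.isnan(pv.genetic_correlation(both, "t", "env1", "env2"))

    def test_symmetric_and_affine_invariant(self, trial):
        t = trial.records
        a = pv.genetic_correlation(t, "seed_weight", "env1", "env2")
        b = pv.genetic_correlation(t, "seed_weight", "env2", "env1")
        assert a == pytest.approx(b, abs=1e-12)
        scaled = t.copy()
        m = scaled["env"] == "env2"
        sw = scaled["trait"] == "seed_weight"
        scaled.loc[m & sw, "value"] = 100 + 7 * scaled.loc[m & sw, "value"]
        c = pv.genetic_correlation(scaled, "seed_weight", "env1", "env2")
        assert c == pytest.approx(a, abs=1e-9)


class TestPhenotypicCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(20, 3))
        t1 = long_table(y, trait="a")
        t2 = long_table(-y, trait="b")
        corr = pv.phenotypic_correlations(
            pd.concat([t1, t2], ignore_index=True), ["a", "b"], "e")
        r_ab = corr[(corr.trait1 == "a") & (corr.trait2 == "b")]["r"].iloc[0]
        r_aa = corr[(corr.trait1 == "a") & (corr.trait2 == "a")]["r"].iloc[0]
        assert r_aa == 1.0
        assert r_ab == pytest.approx(-1.0)

    def test_zero_variance_trait_flagged(self):
        y = np.random.default_rng(12).normal(size=(10, 3))
        t1 = long_table(y, trait="a")
        t2 = long_table(np.ones((10, 3)), trait="b")
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = pv.phenotypic_correlations(
                pd.concat([t1, t2], ignore_index=True), ["a", "b"], "e")
        assert corr["r"].isna().any()
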