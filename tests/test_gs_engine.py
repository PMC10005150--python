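"""Whole-genome regression models, kinship, and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from lupinqg import gs_engine as gs
from lupinqg import simpop
from lupinqg.geno_qc import GenotypeMatrix, genotype_matrix_from_population


def iid_gm(n, m, seed=0, p_range=(0.1, 0.5)):
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, m)
    doses = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return GenotypeMatrix(samples=np.array([f"s{i}" for i in range(n)]),
                          marker_ids=np.array([f"m{j}" for j in range(m)]),
                          chrom=np.ones(m, int), pos=np.arange(1, m + 1),
                          doses=doses)


@pytest.fixture(scope="module")
def polygenic():
    """140 x 2000 simulated panel with a polygenic trait, h2 = 0.5."""
    cfg = simpop.SimConfig(n_markers=2000, n_chromosomes=25, seed=5)
    pop = simpop.simulate_population(cfg)
    gm = genotype_matrix_from_population(pop)
    rng = np.random.default_rng(0)
    W = gm.doses.astype(float)
    beta = rng.normal(0, 1, 2000) * (rng.random(2000) < 0.2)
    g = (W - W.mean(0)) @ beta
    g = (g - g.mean()) / g.std()
    y = g + rng.normal(0, 1.0, 140)
    cross = np.array([s.split("_")[0] for s in gm.samples])
    return gm, y, g, cross


class TestKinship:
    def test_hand_computed_single_marker_kinship(self):
        # doses (0,1,2): p = 0.5, centering by 1, denominator 2p(1-p) = 0.5
        kin = gs.vanraden_g(np.array([[0.0], [1.0], [2.0]]))
        expected = np.array([[2.0, 0.0, -2.0],
                             [0.0, 0.0, 0.0],
                             [-2.0, 0.0, 2.0]])
        np.testing.assert_allclose(kin.matrix, expected)
        assert kin.denominator == pytest.approx(0.5)

    def test_identical_homozygous_samples_match_diagonal(self):
        rng = np.random.default_rng(1)
        hap = (rng.random(3000) < 0.4).astype(float) * 2
        other = (rng.random(3000) < 0.4).astype(float) * 2
        W = np.vstack([hap, hap, other])
        G = gs.vanraden_g(W).matrix
        assert G[0, 1] == pytest.approx(G[0, 0], rel=1e-10)
        assert G[0, 2] < G[0, 0]

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            gs.vanraden_g(np.full((4, 10), 2.0))

    def test_uniform_weights_reproduce_vanraden_exactly(self, polygenic):
        gm, *_ = polygenic
        plain = gs.vanraden_g(gm).matrix
        weighted = gs.vanraden_g(gm, weights=np.ones(gm.n_markers)).matrix
        np.testing.assert_allclose(plain, weighted, atol=1e-12)

    def test_pvalue_weights_mean_one_and_floored(self):
        p = np.array([1e-8, 0.5, 1.0, 0.9])
        d = gs.pvalue_weights(p)
        assert d.mean() >= 1.0 - 1e-9
        assert (d >= 1e-3).all()


class TestRRBLUP:
    def test_constant_phenotype_gives_zero_effects(self):
        gm = iid_gm(20, 50, seed=2)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = gs.RRBLUP().fit(np.ones(20), gm.doses.astype(float))
        assert np.allclose(res.q, 0.0)
        assert np.allclose(res.predict(gm.doses.astype(float)), 1.0)

    def test_single_marker_fixed_ridge_matches_closed_form(self):
        # 3 samples, 1 marker, lambda fixed at 1: ridge on the centered dose
        W = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1.0, 2.0, 4.0])
        res = gs.RRBLUP(fixed_delta=1.0).fit(y, W)
        # closed form: q = xc'(K + I)^-1 (y - mu 1) with mu from GLS
        xc = W[:, 0] - 1.0
        K = np.outer(xc, xc)
        V = K + np.eye(3)
        Vi = np.linalg.inv(V)
        mu = (np.ones(3) @ Vi @ y) / (np.ones(3) @ Vi @ np.ones(3))
        q = xc @ Vi @ (y - mu)
        assert res.mu == pytest.approx(mu, rel=1e-8)
        assert res.q[0] == pytest.approx(q, rel=1e-8)

    def test_prediction_equivalent_to_gblup_oracle(self, polygenic):
        gm, y, g, _ = polygenic
        W = gm.doses.astype(float)
        tr = np.arange(0, 110)
        te = np.arange(110, 140)
        res = gs.RRBLUP().fit(y[tr], W[tr])
        pred = res.predict(W[te])
        # independent G-BLUP route: kernel regression with the same ridge
        Wc = W - W[tr].mean(0)
        K = Wc @ Wc.T
        alpha = np.linalg.solve(K[np.ix_(tr, tr)] + res.delta * np.eye(110),
                                y[tr] - res.mu)
        oracle = res.mu + K[np.ix_(te, tr)] @ alpha
        assert np.corrcoef(pred, oracle)[0, 1] > 0.9999
        np.testing.assert_allclose(pred, oracle, rtol=1e-8, atol=1e-8)

    def test_variance_mapping_to_genomic_variance(self, polygenic):
        # sigma2_g = sigma2_q * 2 sum p(1-p) approximates the genetic
        # variance of a standardized polygenic signal
        gm, y, g, _ = polygenic
        res = gs.RRBLUP().fit(y, gm.doses.astype(float))
        kin = gs.vanraden_g(gm)
        s2g = res.sigma2_q * kin.denominator
        assert 0.3 < s2g < 3.0


class TestBayesianLasso:
    def test_constant_phenotype_flagged(self):
        gm = iid_gm(15, 30, seed=3)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = gs.BayesianLasso(iterations=50, burn_in=10).fit(
                np.full(15, 2.0), gm.doses.astype(float))
        assert np.allclose(res.q, 0.0)

    def test_sparser_shrinkage_than_rrblup_on_sparse_architecture(self):
        rng = np.random.default_rng(4)
        gm = iid_gm(140, 800, seed=5)
        W = gm.doses.astype(float)
        qtl = rng.choice(800, 10, replace=False)
        beta = np.zeros(800)
        beta[qtl] = rng.normal(0, 1.5, 10)
        g = (W - W.mean(0)) @ beta
        y = g + rng.normal(0, g.std() * 0.5, 140)
        bl = gs.BayesianLasso(iterations=1500, burn_in=300, seed=1).fit(y, W)
        rr = gs.RRBLUP().fit(y, W)
        null = np.setdiff1d(np.arange(800), qtl)
        # normalize by the top signal effect before comparing shrinkage
        m_bl = np.median(np.abs(bl.q[null])) / np.abs(bl.q[qtl]).max()
        m_rr = np.median(np.abs(rr.q[null])) / np.abs(rr.q[qtl]).max()
        assert m_bl < m_rr

    def test_chain_stability_across_seeds(self, polygenic):
        gm, y, g, cross = polygenic
        sub = np.arange(140)
        W = gm.doses.astype(float)[:, :800]
        tr, te = sub[:110], sub[110:]
        preds = []
        for seed in (1, 2):
            res = gs.BayesianLasso(iterations=10_000, burn_in=1_000,
                                   seed=seed).fit(y[tr], W[tr])
            preds.append(res.predict(W[te]))
        r1 = np.corrcoef(preds[0], y[te])[0, 1]
        r2 = np.corrcoef(preds[1], y[te])[0, 1]
        assert abs(r1 - r2) < 0.02


class TestRKHS:
    def test_identity_kernel_reverts_to_mean_for_held_out(self):
        rng = np.random.default_rng(6)
        y = rng.normal(5.0, 1.0, 60)
        res = gs.RKHSRegression(iterations=500, burn_in=100, seed=0).fit(
            y, np.eye(60))
        pred = res.predict(np.zeros((5, 60)))
        assert np.allclose(pred, res.mu)
        assert res.mu == pytest.approx(y.mean(), abs=0.3)

    def test_non_psd_kernel_rejected(self):
        G = np.diag([1.0, 1.0, -0.5])
        with pytest.raises(ValueError, match="PSD"):
            gs.RKHSRegression(iterations=100, burn_in=10).fit(
                np.zeros(3), G)

    def test_posterior_heritability_tracks_simulated_value(self, polygenic):
        gm, y, g, _ = polygenic
        kin = gs.vanraden_g(gm)
        ratios = []
        for seed in range(5):
            res = gs.RKHSRegression(iterations=2000, burn_in=400,
                                    seed=seed).fit(y, kin.matrix)
            ratios.append(res.sigma2_g / (res.sigma2_g + res.sigma2_e))
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.1)

    def test_agreement_with_rrblup_predictions(self, polygenic):
        gm, y, g, _ = polygenic
        W = gm.doses.astype(float)
        tr = np.arange(0, 110)
        te = np.arange(110, 140)
        kin = gs.vanraden_g(gm)
        rr = gs.RRBLUP().fit(y[tr], W[tr]).predict(W[te])
        rk = gs.RKHSRegression(iterations=3000, burn_in=500, seed=3).fit(
            y[tr], kin.matrix[np.ix_(tr, tr)]).predict(
                kin.matrix[np.ix_(te, tr)])
        assert np.corrcoef(rr, rk)[0, 1] > 0.99


class TestWGBLUP:
    def test_concentrated_weight_drives_predictions_by_qtl(self):
        gm = iid_gm(60, 100, seed=7)
        weights = np.full(100, 1e-3)
        weights[42] = 100.0
        G = gs.vanraden_g(gm, weights=weights).matrix
        W = gm.doses.astype(float)
        x = W[:, 42] - W[:, 42].mean()
        # kernel is essentially the rank-one similarity on marker 42
        denom = gs.vanraden_g(gm).denominator
        np.testing.assert_allclose(G, 100.0 * np.outer(x, x) / denom,
                                   atol=0.05 * np.abs(G).max())

    def test_no_leakage_from_test_fold_phenotypes(self, polygenic):
        gm, y, g, _ = polygenic
        tr = np.arange(0, 110)
        te = np.arange(110, 140)
        model = gs.WeightedGBLUP(iterations=300, burn_in=50, seed=0)
        k1 = model.weighted_kernel(y[tr], gm, tr)
        y_shuffled = y.copy()
        y_shuffled[te] = np.random.default_rng(8).permutation(y[te])
        k2 = model.weighted_kernel(y_shuffled[tr], gm, tr)
        np.testing.assert_array_equal(k1.matrix, k2.matrix)

    def test_scan_failure_falls_back_to_uniform_weights(self, polygenic):
        gm, y, *_ = polygenic

        def broken_engine(y_, gm_, cov):
            raise RuntimeError("scan exploded")

        model = gs.WeightedGBLUP(iterations=200, burn_in=50,
                                 association_engine=broken_engine)
        with pytest.warns(UserWarning, match="uniform weights"):
            kin = model.weighted_kernel(y[:100], gm, np.arange(100))
        np.testing.assert_allclose(kin.matrix, gs.vanraden_g(gm).matrix)


class TestCrossValidation:
    def test_pure_noise_gives_near_zero_ability(self, polygenic):
        gm, _, _, cross = polygenic
        y = np.random.default_rng(9).normal(size=140)
        config = gs.GSModelConfig(model="rrBLUP")
        run = gs.crossval_intra(y, gm, config, folds=5, repeats=3, seed=1,
                                cross_labels=cross)
        assert abs(run.mean_ability) < 0.25       # ~ 3 / sqrt(140)

    def test_noiseless_oligogenic_trait_recovered(self):
        # markers < samples: the training design has full column rank, so
        # the noiseless 5-marker signal is recovered essentially exactly
        gm = iid_gm(200, 60, seed=10)
        W = gm.doses.astype(float)
        y = W[:, [5, 15, 30, 45, 55]] @ np.array([1.0, -0.8, 0.6, 1.2, -1.0])
        config = gs.GSModelConfig(model="rrBLUP")
        run = gs.crossval_intra(y, gm, config, folds=5, repeats=2, seed=2)
        assert run.mean_ability > 0.95

    def test_fewer_samples_than_folds_rejected(self):
        gm = iid_gm(8, 30, seed=11)
        config = gs.GSModelConfig(model="rrBLUP")
        with pytest.raises(ValueError, match="folds"):
            gs.crossval_intra(np.zeros(8), gm, config, folds=10)

    def test_ability_bounded_by_root_heritability(self, polygenic):
        gm, y, g, cross = polygenic
        config = gs.GSModelConfig(model="rrBLUP")
        run = gs.crossval_intra(y, gm, config, folds=10, repeats=5, seed=3,
                                cross_labels=cross)
        se = np.std(run.abilities, ddof=1) / np.sqrt(len(run.abilities))
        assert run.mean_ability <= np.sqrt(0.5) + 3 * se

    def test_identical_environments_match_intra_ability(self, polygenic):
        gm, y, g, cross = polygenic
        config = gs.GSModelConfig(model="rrBLUP")
        intra = gs.crossval_intra(y, gm, config, folds=5, repeats=3,
                                  seed=4, cross_labels=cross)
        cross_run = gs.crossval_cross_env(y, y, gm, config, folds=5,
                                          repeats=3, seed=4,
                                          cross_labels=cross)
        assert cross_run.mean_ability == pytest.approx(
            intra.mean_ability, abs=0.1)

    def test_cross_env_ability_attenuates_with_genetic_correlation(
            self, polygenic):
        gm, _, g, cross = polygenic
        rng = np.random.default_rng(12)
        config = gs.GSModelConfig(model="rrBLUP")
        abilities = []
        for rg in (0.0, 0.5, 1.0):
            z = rng.normal(size=140)
            g2 = rg * g + np.sqrt(1 - rg ** 2) * (z - z.mean()) / z.std()
            y1 = g + rng.normal(0, 1, 140)
            y2 = g2 + rng.normal(0, 1, 140)
            run = gs.crossval_cross_env(y1, y2, gm, config, folds=5,
                                        repeats=3, seed=5,
                                        cross_labels=cross)
            abilities.append(run.mean_ability)
        assert abilities[0] < abilities[1] < abilities[2]
        assert abs(abilities[0]) < 0.25


class TestGrid:
    def test_single_cell_identical_to_direct_call(self, polygenic):
        gm, y, _, cross = polygenic
        ys = pd.Series(y, index=gm.samples, name="t@e")
        grid = gs.run_grid({"t@e": ys}, {0.30: gm}, cross_labels=cross,
                           models=("rrBLUP",), structure_flags=(False,),
                           folds=5, repeats=2, seed=11)
        ss = np.random.SeedSequence(11)
        cell_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31 - 1))
        config = gs.GSModelConfig(model="rrBLUP", structure_included=False,
                                  marker_missing_threshold=0.30, seed=11)
        direct = gs.crossval_intra(ys, gm, config, folds=5, repeats=2,
                                   seed=cell_seed, cross_labels=cross)
        assert grid["mean_ability"].iloc[0] == pytest.approx(
            direct.mean_ability, abs=1e-12)

    def test_grid_deterministic_under_master_seed(self, polygenic):
        gm, y, _, cross = polygenic
        ys = pd.Series(y, index=gm.samples, name="t@e")
        kwargs = dict(phenotypes={"t@e": ys}, gm_by_threshold={0.30: gm},
                      cross_labels=cross, models=("rrBLUP",),
                      structure_flags=(False, True), folds=5, repeats=2,
                      seed=7)
        a = gs.run_grid(**kwargs)
        b = gs.run_grid(**kwargs)
        pd.testing.assert_series_equal(a["mean_ability"], b["mean_ability"])

    def test_best_per_trait_has_one_row_per_trait_scenario(self, polygenic):
        gm, y, _, cross = polygenic
        ys = pd.Series(y, index=gm.samples)
        grid = gs.run_grid({"t@e1": ys, "t@e2": ys}, {0.30: gm},
                           cross_labels=cross, models=("rrBLUP",),
                           structure_flags=(False,),
                           cross_env_pairs={"t": ("t@e1", "t@e2")},
                           folds=5, repeats=1, seed=8)
        best = gs.best_per_trait(grid)
        assert len(best) == 3           # two intra keys + one cross-env
        means = gs.model_threshold_means(grid)
        assert "average" in means.columns


class TestConfig:
    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            gs.GSModelConfig(model="BayesZ")

    def test_iterations_must_exceed_burnin(self):
        with pytest.raises(ValueError, match="burn_in"):
            gs.GSModelConfig(iterations=100, burn_in=100)
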