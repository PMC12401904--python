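"""Genomic prediction models: rrBLUP, BayesB, multi-trait SVD, tree adapters."""

import numpy as np
import pandas as pd
import pytest

from inducergp.gp import (BayesBGP, MultiTraitGP, RidgeGP, TreeModelConfig,
                          fit_tree_model, geweke_z)

from conftest import random_genotypes


def trait_on(Z, qtl_sd, noise_sd, seed):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, qtl_sd, Z.shape[1])
    return Z @ u + rng.normal(0, noise_sd, Z.shape[0]), u


class TestRidgeGP:
    def test_constant_y(self):
        Z = random_genotypes(30, 50, seed=0).codes
        fit = RidgeGP(np.full(30, 7.5), Z).fit()
        assert fit.mu == pytest.approx(7.5)
        assert np.allclose(fit.u, 0.0)
        assert np.allclose(fit.predict(Z), 7.5)

    def test_gblup_equivalence(self, dh_family_50x500):
        """Marker model predictions equal GBLUP under the VanRaden kinship
        built from the same markers (independent covariance-form solve)."""
        from inducergp.genotypes import compute_kinship

        Z = dh_family_50x500.codes
        n = Z.shape[0]
        y, _ = trait_on(Z, 0.05, 1.0, seed=42)
        fit = RidgeGP(y, Z).fit()
        pred_rr = fit.predict(Z)
        K = compute_kinship(dh_family_50x500).values
        p = dh_family_50x500.major_allele_freq()
        c = float((2 * p * (1 - p)).sum())
        s2g, s2e = fit.sigma2_m * c, fit.sigma2_e
        V = s2g * K + s2e * np.eye(n)
        one = np.ones(n)
        mu = float(one @ np.linalg.solve(V, y) / (one @ np.linalg.solve(V, one)))
        pred_gb = mu + s2g * K @ np.linalg.solve(V, y - mu)
        assert np.corrcoef(pred_rr, pred_gb)[0, 1] > 0.9999
        assert np.abs(pred_rr - pred_gb).max() < 1e-6

    def test_lambda_recovery(self, dh_family_50x500):
        """Estimated variance ratio within a factor of 1.5 of truth
        (median over seeds) at genomic h2 = 0.5."""
        from inducergp.simulate import simulate_dh_family

        base = dh_family_50x500
        fam = simulate_dh_family(np.ones(base.n_markers), -np.ones(base.n_markers),
                                 300, base.markers, seed=21)
        Z = fam.codes
        ratios = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            u = rng.normal(0, 1, Z.shape[1])
            g = Z @ u
            g = (g - g.mean()) / g.std()          # genetic variance 1
            y = g + rng.normal(0, 1, Z.shape[0])  # residual variance 1
            fit = RidgeGP(y, Z).fit()
            # truth on the model's own scale: lam = s2e / s2m with
            # s2m = 1 / (sum of marker variances) at unit genetic variance
            lam_true = float((Z - Z.mean(0)).var(axis=0).sum())
            ratios.append(fit.lam / lam_true)
        med = float(np.median(ratios))
        assert 1 / 1.5 < med < 1.5

    def test_shrinkage_and_empty_fixed_reduction(self):
        Z = random_genotypes(60, 80, seed=1).codes
        y, _ = trait_on(Z, 0.1, 1.0, seed=2)
        plain = RidgeGP(y, Z).fit()
        empty = RidgeGP(y, Z, X=np.empty((60, 0))).fit()
        np.testing.assert_allclose(plain.u, empty.u)
        assert len(empty.b) == 0

    def test_fixed_snp_effect_recovered(self):
        Z = random_genotypes(200, 100, seed=3).codes
        x = Z[:, 0]
        rng = np.random.default_rng(4)
        y = 2.0 * x + rng.normal(0, 0.5, 200)
        fit = RidgeGP(y, Z[:, 1:], X=x, fixed_snp_ids=["S1"]).fit()
        assert fit.b[0] == pytest.approx(2.0, abs=0.15)
        assert fit.fixed_snp_ids == ["S1"]

    def test_predict_marker_mismatch(self):
        Z = random_genotypes(30, 40, seed=5).codes
        fit = RidgeGP(Z @ np.ones(40), Z).fit()
        with pytest.raises(ValueError, match="marker-set mismatch"):
            fit.predict(Z[:, :20])

    def test_all_zero_marker_row_predicts_mu_plus_fixed(self):
        Z = random_genotypes(50, 30, seed=6).codes
        y, _ = trait_on(Z, 0.2, 0.5, seed=7)
        fit = RidgeGP(y, Z).fit()
        gv = fit.predict(fit.z_means[None, :])  # centered row of zeros
        assert gv[0] == pytest.approx(fit.mu)

    def test_mme_augmentation_oracle(self, dh_family_50x500):
        """Held-out predictions equal the joint mixed-model solve that
        carries the held-out lines with unobserved phenotypes."""
        Z = dh_family_50x500.codes
        y, _ = trait_on(Z, 0.05, 1.0, seed=8)
        tr, te = np.arange(40), np.arange(40, 50)
        fit = RidgeGP(y[tr], Z[tr]).fit()
        pred = fit.predict(Z[te])
        # oracle: covariance-form BLUP of the held-out genetic values
        zm = Z[tr].mean(axis=0)
        Zc_tr, Zc_te = Z[tr] - zm, Z[te] - zm
        lam = fit.lam
        H = Zc_tr @ Zc_tr.T + lam * np.eye(len(tr))
        one = np.ones(len(tr))
        mu = float(one @ np.linalg.solve(H, y[tr]) / (one @ np.linalg.solve(H, one)))
        g_te = Zc_te @ Zc_tr.T @ np.linalg.solve(H, y[tr] - mu)
        np.testing.assert_allclose(pred, mu + g_te, atol=1e-8)


class TestBayesB:
    def test_ridge_limit_agrees_with_rrblup(self):
        """pi fixed at 0 with a common marker variance: posterior-mean
        effects track rrBLUP at r > 0.98 on a 50 x 200 fixture."""
        Z = random_genotypes(50, 200, seed=9).codes
        y, _ = trait_on(Z, np.sqrt(1 / 200), 1.0, seed=10)
        bb = BayesBGP(y, Z, burn_in=500, iterations=3000, fix_pi=0.0,
                      common_marker_variance=True).fit(seed=1)
        rr = RidgeGP(y, Z).fit()
        assert np.corrcoef(bb.u, rr.u)[0, 1] > 0.98

    def test_constant_y_inclusion_near_prior(self):
        Z = random_genotypes(40, 60, seed=11).codes
        bb = BayesBGP(np.full(40, 3.0), Z, burn_in=300, iterations=1500).fit(seed=2)
        assert bb.inclusion_prob.mean() < 0.15     # prior exclusion 0.95
        pred = bb.predict(Z)
        assert pred.std() < 0.15

    def test_major_qtl_has_top_inclusion(self):
        """One SNP carrying ~30% of variance: its posterior inclusion is
        the maximum across SNPs in most seeds."""
        hits = 0
        for seed in range(5):
            Z = random_genotypes(200, 150, seed=20 + seed).codes
            rng = np.random.default_rng(30 + seed)
            y = Z[:, 77] * 0.8 + rng.normal(0, 1.2, 200)
            bb = BayesBGP(y, Z, burn_in=400, iterations=2000).fit(seed=seed)
            hits += int(np.argmax(bb.inclusion_prob) == 77)
        assert hits >= 4

    def test_chain_seed_reproducible_and_stationary(self):
        Z = random_genotypes(60, 100, seed=12).codes
        y, _ = trait_on(Z, 0.08, 1.0, seed=13)
        a = BayesBGP(y, Z, burn_in=400, iterations=2000).fit(seed=3)
        b = BayesBGP(y, Z, burn_in=400, iterations=2000).fit(seed=3)
        np.testing.assert_array_equal(a.u, b.u)
        assert abs(geweke_z(a.s2e_chain)) < 3.0

    def test_bad_chain_settings_rejected(self):
        Z = random_genotypes(20, 10, seed=14).codes
        with pytest.raises(ValueError):
            BayesBGP(np.zeros(20), Z, burn_in=100, iterations=50)


class TestMultiTrait:
    def test_duplicated_traits_equal_single_trait(self):
        Z = random_genotypes(80, 120, seed=15).codes
        y, _ = trait_on(Z, 0.08, 0.7, seed=16)
        Y = pd.DataFrame({"a": y, "b": y, "c": y})
        mt = MultiTraitGP(Y, Z).fit()
        st = RidgeGP(y, Z).fit()
        ps = st.predict(Z)
        pm = mt.predict(Z)
        for col in Y.columns:
            assert np.corrcoef(pm[col], ps)[0, 1] > 0.9999

    def test_v_orthogonal_and_roundtrip(self):
        Z = random_genotypes(60, 80, seed=17).codes
        rng = np.random.default_rng(18)
        Y = pd.DataFrame({f"t{k}": Z @ rng.normal(0, 0.1, 80) +
                          rng.normal(0, 0.5, 60) for k in range(3)})
        mt = MultiTraitGP(Y, Z).fit()
        assert np.abs(mt.V.T @ mt.V - np.eye(3)).max() < 1e-8
        # back-transform consistency: Yhat V == Yhat* (scaled space)
        yhat_star = np.column_stack([f.predict(Z) for f in mt.fits])
        yhat_scaled = (mt.predict(Z).to_numpy() - mt.centers) / mt.scales
        np.testing.assert_allclose(yhat_scaled @ mt.V, yhat_star, atol=1e-8)

    def test_disjoint_qtl_no_harm(self):
        """Uncorrelated traits with disjoint QTL: MT predictive ability
        within +-0.05 of ST per trait (averaged over seeds)."""
        from inducergp.evaluation import predictive_ability

        diffs = []
        for seed in range(4):
            Z = random_genotypes(300, 200, seed=40 + seed).codes
            rng = np.random.default_rng(50 + seed)
            u1 = np.zeros(200); u1[:60] = rng.normal(0, 1, 60)
            u2 = np.zeros(200); u2[100:160] = rng.normal(0, 1, 60)
            mk = lambda u: (Z @ u - (Z @ u).mean()) / (Z @ u).std()
            Y = pd.DataFrame({"t1": mk(u1) + rng.normal(0, 1, 300),
                              "t2": mk(u2) + rng.normal(0, 1, 300)})
            tr, te = np.arange(240), np.arange(240, 300)
            mt = MultiTraitGP(Y.iloc[tr], Z[tr]).fit()
            pm = mt.predict(Z[te])
            for col in Y.columns:
                st = RidgeGP(Y[col].to_numpy()[tr], Z[tr]).fit()
                pa_st = predictive_ability(Y[col].iloc[te], st.predict(Z[te])).r
                pa_mt = predictive_ability(Y[col].iloc[te], pm[col]).r
                diffs.append(pa_mt - pa_st)
        assert abs(float(np.mean(diffs))) < 0.05

    def test_missing_values_and_single_trait_rejected(self):
        Z = random_genotypes(20, 30, seed=19).codes
        Y = pd.DataFrame({"a": np.ones(20), "b": np.ones(20)})
        Y.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete cases"):
            MultiTraitGP(Y, Z)
        with pytest.raises(ValueError, match="at least 2"):
            MultiTraitGP(Y[["a"]].fillna(0), Z)


class TestTreeModels:
    def test_constant_y_constant_predictions(self):
        Z = random_genotypes(40, 30, seed=21).codes
        est = fit_tree_model(np.full(40, 2.0), Z, TreeModelConfig(model="rf", trees=20))
        assert np.allclose(est.predict(Z), 2.0)

    def test_noiseless_additive_capacity(self):
        Z = random_genotypes(150, 40, seed=22).codes
        y = Z @ np.linspace(0.2, 1.0, 40)
        for model in ("rf", "xgboost"):
            cfg = TreeModelConfig(model=model, trees=100, tuning_budget=2, seed=1)
            est = fit_tree_model(y, Z, cfg)
            r = np.corrcoef(est.predict(Z), y)[0, 1]
            assert r > 0.95

    def test_qtl_ranks_first_in_importance(self):
        """Permutation importance puts the lone QTL SNP first in most seeds."""
        from sklearn.inspection import permutation_importance

        hits = 0
        for seed in range(5):
            Z = random_genotypes(150, 40, seed=60 + seed).codes
            rng = np.random.default_rng(70 + seed)
            y = Z[:, 13] * 1.5 + rng.normal(0, 0.8, 150)
            cfg = TreeModelConfig(model="rf", trees=150, tuning_budget=2, seed=seed)
            est = fit_tree_model(y, Z, cfg)
            imp = permutation_importance(est, Z, y, n_repeats=3,
                                         random_state=seed).importances_mean
            hits += int(np.argmax(imp) == 13)
        assert hits >= 4
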