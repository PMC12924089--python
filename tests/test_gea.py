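"""Genotype-environment association: latent-factor scan, RDA, core set."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ridgescape import gea
from ridgescape.genio import GenotypeMatrix
from ridgescape.popstruct import pca_genotypes

from conftest import standard_sim
from oracles import bh_stepup, rda_brute


class TestSelectPredictors:
    def setup_method(self):
        rng = np.random.default_rng(0)
        n = 200
        a = rng.normal(size=n)
        self.env = pd.DataFrame({
            "a": a, "a2": a + rng.normal(scale=0.05, size=n),   # |r| ~ 0.999
            "b": rng.normal(size=n), "c": rng.normal(size=n)})

    def test_perfectly_correlated_pair_keeps_higher_importance(self):
        sel = gea.select_predictors(self.env, {"a": 3.0, "a2": 2.0, "b": 1.0,
                                               "c": 0.5})
        assert "a" in sel.selected and "a2" not in sel.selected

    def test_weakly_correlated_all_selected(self):
        sel = gea.select_predictors(self.env[["a", "b", "c"]],
                                    {"a": 3.0, "b": 1.0, "c": 0.5})
        assert sel.selected == ["a", "b", "c"]

    def test_greedy_invariant_on_fixture(self):
        # the greedy rule: accept iff |r| < threshold with all accepted so far
        rng = np.random.default_rng(1)
        base = rng.normal(size=(100, 3))
        env = pd.DataFrame({
            "p0": base[:, 0], "p1": 0.8 * base[:, 0] + 0.6 * base[:, 1],
            "p2": base[:, 1], "p3": base[:, 2],
            "p4": 0.9 * base[:, 2] + 0.44 * base[:, 0],
            "p5": rng.normal(size=100)})
        imp = {f"p{i}": 6.0 - i for i in range(6)}
        sel = gea.select_predictors(env, imp, r_threshold=0.6)
        corr = env.corr().abs()
        # brute-force check of the invariant on the returned set
        for i, s in enumerate(sel.selected):
            for t in sel.selected[:i]:
                assert corr.loc[s, t] < 0.6
        # and that every rejected predictor violates it against an
        # earlier-accepted one of higher importance
        order = [k for k, _ in sorted(imp.items(), key=lambda kv: -kv[1])]
        for name in order:
            if name in sel.selected:
                continue
            accepted_before = [s for s in sel.selected if imp[s] > imp[name]]
            assert any(corr.loc[name, t] >= 0.6 for t in accepted_before)


class TestLFMM:
    def test_bh_matches_stepup_oracle(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074,
                      0.205, 0.212, 0.36])
        np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1],
                                   bh_stepup(p), atol=1e-12)

    def test_affine_env_rescaling_leaves_z_unchanged(self, planted_sim):
        gm, env = planted_sim["gm"], planted_sim["env"]
        x = env["bio12"].to_numpy()
        r1 = gea.lfmm_test(gm, x, K=4)
        r2 = gea.lfmm_test(gm, 3.7 * x - 11.0, K=4)
        np.testing.assert_allclose(r1.z, r2.z, atol=1e-6)
        r3 = gea.lfmm_test(gm, -x, K=4)
        np.testing.assert_allclose(r1.z, -r3.z, atol=1e-6)

    def test_locus_order_invariance(self, planted_sim):
        gm, env = planted_sim["gm"], planted_sim["env"]
        x = env["bio12"].to_numpy()
        perm = np.random.default_rng(0).permutation(gm.n_loci)
        gm_perm = GenotypeMatrix(gm.G[:, perm], gm.samples, gm.demes,
                                 ["sim1"] * gm.n_loci,
                                 np.arange(1, gm.n_loci + 1))
        r1 = gea.lfmm_test(gm, x, K=4)
        r2 = gea.lfmm_test(gm_perm, x, K=4)
        np.testing.assert_allclose(r1.z[perm, 0], r2.z[:, 0], atol=1e-8)

    def test_null_fdr_calibration(self):
        fracs = []
        for seed in range(10):
            sim = standard_sim(600 + seed, n_adaptive_loci=0)
            res = gea.lfmm_test(sim["gm"], sim["env"]["bio12"].to_numpy(), K=4)
            fracs.append(len(res.hits) / sim["gm"].n_loci)
        assert np.mean(fracs) <= 0.01

    def test_power_on_planted_clines(self):
        recalls = []
        for seed in range(10):
            sim = standard_sim(700 + seed)
            res = gea.lfmm_test(sim["gm"],
                                sim["env"][sim["config"].driver].to_numpy(), K=4)
            truth = set(sim["truth"].adaptive_locus_ids)
            recalls.append(len(res.hits & truth) / len(truth))
        assert np.mean(recalls) >= 0.8

    def test_k0_under_confounding_inflates(self):
        # env built to correlate r=0.7 with the leading structure axis
        sim = standard_sim(42, n_adaptive_loci=0, fst_target=0.15)
        gm = sim["gm"]
        scores, _ = pca_genotypes(gm, 1)
        pc1 = (scores[:, 0] - scores[:, 0].mean()) / scores[:, 0].std()
        rng = np.random.default_rng(1)
        env = 0.7 * pc1 + np.sqrt(1 - 0.49) * rng.standard_normal(gm.n_samples)
        raw_z = gea.lfmm_test(gm, env, K=0)
        assert raw_z.gif[0] > 1.2

    def test_constant_locus_flagged_p_one(self, small_sim):
        gm = small_sim["gm"]
        G = gm.G.copy()
        G[:, 0] = 2
        gm2 = GenotypeMatrix(G, gm.samples, gm.demes, list(gm.chrom), gm.pos)
        res = gea.lfmm_test(gm2, small_sim["env"]["bio12"].to_numpy(), K=2)
        assert res.p[0, 0] == 1.0

    def test_invalid_inputs(self, small_sim):
        gm, env = small_sim["gm"], small_sim["env"]
        with pytest.raises(ValueError):
            gea.lfmm_test(gm, np.ones(gm.n_samples), K=2)     # constant env
        with pytest.raises(ValueError):
            gea.lfmm_test(gm, env["bio12"].to_numpy(), K=gm.n_samples)


class TestFstContrast:
    def test_planted_candidates_more_differentiated(self, planted_sim):
        sim = planted_sim
        truth = set(sim["truth"].adaptive_locus_ids)
        f_c, f_r, p = gea.fst_contrast(
            sim["gm"], sim["env"][sim["config"].driver].to_numpy(), truth,
            n_extreme=5, seed=0)
        assert np.median(f_c) > np.median(f_r)
        assert p < 0.05

    def test_random_candidates_null_calibrated(self):
        sim = standard_sim(55, n_adaptive_loci=0)
        env = sim["env"]["bio12"].to_numpy()
        ids = np.asarray(sim["gm"].locus_ids)
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            cands = set(rng.choice(ids, size=50, replace=False))
            _, _, p = gea.fst_contrast(sim["gm"], env, cands, seed=seed)
            rejections += p < 0.05
        assert rejections <= 4   # <= 10% of 20 seeds, with slack for 20 draws

    def test_too_many_extremes_rejected(self, small_sim):
        gm = small_sim["gm"]
        with pytest.raises(ValueError):
            gea.fst_contrast(gm, np.arange(gm.n_samples), {"sim1:1"},
                             n_extreme=gm.n_samples)

    def test_empty_candidates_rejected(self, small_sim):
        with pytest.raises(ValueError):
            gea.fst_contrast(small_sim["gm"],
                             np.arange(small_sim["gm"].n_samples), set())


class TestRDA:
    def test_matches_brute_force_oracle(self):
        sim = standard_sim(66, n_demes=5, n_per_deme=4, n_neutral_loci=45,
                           n_adaptive_loci=5)
        gm, env = sim["gm"], sim["env"]
        preds = list(sim["config"].env_names)[:3]
        res = gea.rda_outliers(gm, env, preds, n_axes=3)
        Y = gm.G.astype(float)
        Y = Y - Y.mean(axis=0)
        X = env[preds].to_numpy(dtype=float)
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        eig_o, load_o = rda_brute(Y, X, 3)
        # eigenvalue spectra agree; loadings agree up to per-axis sign
        n = Y.shape[0]
        total = (Y ** 2).sum() / (n - 1)
        np.testing.assert_allclose(res.axis_var_frac[:3], eig_o / total,
                                   atol=1e-8)
        for k in range(3):
            s = np.sign(np.dot(res.loadings[:, k], load_o[:, k])) or 1.0
            np.testing.assert_allclose(res.loadings[:, k], s * load_o[:, k],
                                       atol=1e-8)

    def test_null_outlier_fraction_near_gaussian_tail(self):
        # expected ~ 2*Phi(-3.5)*n_axes ~ 0.14%, tolerance x3
        fracs = []
        for seed in range(10):
            sim = standard_sim(800 + seed, n_adaptive_loci=0)
            res = gea.rda_outliers(sim["gm"], sim["env"],
                                   list(sim["config"].env_names)[:3])
            fracs.append(res.outliers.mean())
        expected = 2 * stats.norm.sf(3.5) * 3
        assert np.mean(fracs) <= 3 * expected

    def test_single_predictor_matches_univariate_slopes(self, planted_sim):
        gm, env = planted_sim["gm"], planted_sim["env"]
        res = gea.rda_outliers(gm, env, ["bio12"], n_axes=1)
        x = env["bio12"].to_numpy()
        xc = x - x.mean()
        Y = gm.G.astype(float)
        Y = Y - Y.mean(axis=0)
        slopes = Y.T @ xc / (xc @ xc)
        rho = stats.spearmanr(res.loadings[:, 0], slopes).statistic
        assert abs(rho) > 0.95

    def test_rank_two_predictors_give_two_axes(self, small_sim):
        gm, env = small_sim["gm"], small_sim["env"]
        # two independent predictors -> exactly 2 constrained axes
        res = gea.rda_outliers(gm, env, ["bio12", "bio2"], n_axes=5)
        assert res.loadings.shape[1] == 2

    def test_collinear_predictors_rejected(self, small_sim):
        env = small_sim["env"].copy()
        env["dup"] = env["bio12"]
        with pytest.raises(ValueError, match="collinear"):
            gea.rda_outliers(small_sim["gm"], env, ["bio12", "dup"])


class TestCoreCandidates:
    def make_assoc(self, ids, hit_mask):
        m = len(ids)
        q = np.where(hit_mask, 0.001, 0.5)[:, None]
        z = np.where(hit_mask, 5.0, 0.1)[:, None]
        return gea.AssociationResult(ids, ["bio12"], z, q.copy(), q, 4,
                                     np.array([1.0]))

    def make_rda(self, ids, hit_mask):
        m = len(ids)
        lz = np.where(hit_mask, 5.0, 0.0)[:, None]
        return gea.RDAResult(ids, np.array([0.5]), lz, lz,
                             np.asarray(hit_mask), 3.5)

    def test_rda_all_hits_reduces_to_lfmm(self):
        ids = [f"sim1:{i}" for i in range(1, 11)]
        lf = self.make_assoc(ids, np.arange(10) < 3)
        rd = self.make_rda(ids, np.ones(10, bool))
        cand = gea.core_candidates(lf, rd)
        assert cand.core == lf.hits

    def test_disjoint_sets_empty_core(self):
        ids = [f"sim1:{i}" for i in range(1, 11)]
        lf = self.make_assoc(ids, np.arange(10) < 3)
        rd = self.make_rda(ids, np.arange(10) >= 5)
        assert gea.core_candidates(lf, rd).core == set()

    def test_mismatched_universes_rejected(self):
        lf = self.make_assoc([f"sim1:{i}" for i in range(1, 6)],
                             np.zeros(5, bool))
        rd = self.make_rda([f"sim2:{i}" for i in range(1, 6)],
                           np.zeros(5, bool))
        with pytest.raises(ValueError):
            gea.core_candidates(lf, rd)

    def test_planted_recovery_end_to_end(self):
        recalls, fdrs = [], []
        for seed in range(5):
            sim = standard_sim(300 + seed)
            preds = list(sim["config"].env_names)
            assoc = gea.lfmm_scan(sim["gm"], sim["env"], preds, K=4)
            rda = gea.rda_outliers(sim["gm"], sim["env"], preds)
            cand = gea.core_candidates(assoc, rda)
            truth = set(sim["truth"].adaptive_locus_ids)
            recalls.append(len(cand.core & truth) / len(truth))
            fdrs.append(len(cand.core - truth) / len(cand.core)
                        if cand.core else 0.0)
        assert np.mean(recalls) >= 0.7
        assert np.mean(fdrs) <= 0.2


def test_core_annotation_arithmetic():
    # printed annotation tallies: 4313 non-coding + 64 coding candidates
    assert round(gea.noncoding_percentage(), 1) == 98.5
    assert gea.noncoding_percentage({"noncoding": 1, "coding": 3}) == 25.0
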