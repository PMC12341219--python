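"""Hurdle model: responses, sampler calibration, diagnostics, and metrics."""

import numpy as np
import pandas as pd
import pytest

import darkamp.community_model as cm


class TestHurdleSplit:
    def test_presence_and_standardisation(self):
        ab = pd.DataFrame({"s1": [0.0, 10.0], "s2": [10.0, 100.0],
                           "s3": [100.0, 1000.0]}, index=["t1", "t2"])
        P, A = cm.hurdle_split(ab)
        assert P.loc["t1"].tolist() == [0, 1, 1]
        present = A.loc["t1"].dropna()
        assert present.mean() == pytest.approx(0.0, abs=1e-12)
        assert present.std(ddof=0) == pytest.approx(1.0)
        # absent cells are missing, not zero
        assert np.isnan(A.loc["t1", "s1"])

    def test_all_present_taxon_has_no_missing(self):
        ab = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [4.0]}, index=["t"])
        _, A = cm.hurdle_split(ab)
        assert not A.isna().any().any()

    def test_rare_taxon_dropped_from_abundance(self):
        ab = pd.DataFrame({"s1": [5.0, 5.0], "s2": [0.0, 5.0], "s3": [0.0, 5.0]},
                          index=["rare", "common"])
        _, A = cm.hurdle_split(ab, min_present=2)
        assert "rare" not in A.index

    def test_standardisation_matches_direct_computation(self):
        rng = np.random.default_rng(0)
        ab = pd.DataFrame(rng.lognormal(5, 2, (5, 30)) *
                          (rng.uniform(size=(5, 30)) > 0.3))
        _, A = cm.hurdle_split(ab)
        for t in A.index:
            logged = np.log(ab.loc[t][ab.loc[t] > 0])
            z = (logged - logged.mean()) / logged.std(ddof=0)
            np.testing.assert_allclose(A.loc[t].dropna(), z, rtol=1e-10)


class TestPsrf:
    def test_identical_chains_pass(self):
        rng = np.random.default_rng(1)
        draw = rng.standard_normal(200)
        chains = np.stack([draw, draw, draw, draw])
        assert cm.psrf(chains) == pytest.approx(1.0, abs=0.05)

    def test_separated_chains_fail(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.standard_normal(200),
                           rng.standard_normal(200) + 10.0])
        assert cm.psrf(chains) > 2.0

    def test_matches_textbook_formula(self):
        """Independent split-chain computation on stored toy chains."""
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((3, 100)) + np.array([[0.0], [0.2], [0.4]])
        got = cm.psrf(chains)
        splits = np.concatenate([chains[:, :50], chains[:, 50:]], axis=0)
        n = 50
        W = splits.var(axis=1, ddof=1).mean()
        B = n * splits.mean(axis=1).var(ddof=1)
        expect = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert got == pytest.approx(expect)

    def test_single_chain_raises(self):
        with pytest.raises(ValueError):
            cm.psrf(np.zeros((1, 100)))


class TestMetrics:
    def test_auc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(size=40) < 0.4
        score = rng.uniform(size=40)
        got = cm.auc(y, score)
        pos, neg = score[y], score[~y]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert got == pytest.approx(conc / (len(pos) * len(neg)))

    def test_auc_perfect_and_null(self):
        y = np.array([0, 0, 1, 1], dtype=bool)
        assert cm.auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        rng = np.random.default_rng(5)
        y = rng.uniform(size=4000) < 0.5
        assert cm.auc(y, rng.uniform(size=4000)) == pytest.approx(0.5, abs=0.05)

    def test_tjur_formula(self):
        y = np.array([1, 1, 0, 0], dtype=bool)
        p = np.array([0.9, 0.7, 0.3, 0.1])
        assert cm.tjur_r2(y, p) == pytest.approx(0.8 - 0.2)
        assert cm.tjur_r2(y, y.astype(float)) == 1.0


class TestSupportAndAssociations:
    def _posterior_from_B(self, B_draws, taxa=None):
        lam = {"species": np.zeros((len(B_draws), 1, B_draws.shape[2]))}
        chain = {"B": B_draws, "Lambda": lam}
        return cm.Posterior("presence", [chain], ["intercept", "season", "sex"],
                            taxa or [f"t{j}" for j in range(B_draws.shape[2])],
                            ["species"], np.zeros((1, B_draws.shape[2])))

    def test_all_positive_draws_called_positive(self):
        B = np.zeros((100, 3, 2))
        B[:, 1, 0] = 1.0  # season effect, taxon t0, always positive
        rng = np.random.default_rng(6)
        B[:, 1, 1] = rng.standard_normal(100)  # symmetric: no call
        sup = cm.fixed_effect_support(self._posterior_from_B(B))
        season = sup[sup.covariate == "season"].set_index("taxon")
        assert season.loc["t0", "call"] == "positive"
        assert season.loc["t1", "call"] == "none"

    def _posterior_from_lambda(self, lam_draws):
        T = lam_draws.shape[2]
        chain = {"B": np.zeros((lam_draws.shape[0], 3, T)),
                 "Lambda": {"species": lam_draws}}
        return cm.Posterior("presence", [chain], ["intercept", "season", "sex"],
                            [f"t{j}" for j in range(T)], ["species"],
                            np.zeros((1, T)))

    def test_identical_loadings_positive_association(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((200, 1, 1))
        lam = np.concatenate([base, base, -base], axis=2)
        edges, support = cm.residual_associations(
            self._posterior_from_lambda(lam), "species")
        pair = edges.set_index(["taxon_a", "taxon_b"])
        assert pair.loc[("t0", "t1"), "sign"] == "+"
        assert pair.loc[("t0", "t2"), "sign"] == "-"
        assert support.loc["t0", "t1"] == pytest.approx(1.0)

    def test_independent_taxa_rarely_supported(self):
        rng = np.random.default_rng(8)
        lam = rng.standard_normal((400, 2, 10)) * 0.1
        edges, _ = cm.residual_associations(
            self._posterior_from_lambda(lam), "species", prob=0.90)
        assert len(edges) <= 0.05 * (10 * 9 / 2) + 1

    def test_missing_level_raises(self):
        rng = np.random.default_rng(9)
        post = self._posterior_from_lambda(rng.standard_normal((10, 1, 3)))
        with pytest.raises(ValueError):
            cm.residual_associations(post, "site")


class TestVariancePartition:
    def test_pure_season_effect(self):
        B = np.zeros((50, 3, 1))
        B[:, 1, 0] = 2.0
        lam = {"species": np.zeros((50, 2, 1))}
        chain = {"B": B, "Lambda": lam}
        post = cm.Posterior("presence", [chain], ["intercept", "season", "sex"],
                            ["t0"], ["species"], np.zeros((1, 1)))
        X = np.column_stack([np.ones(100), np.arange(100) % 2, np.zeros(100)])
        vp = cm.variance_partition(post, X)
        assert vp.loc["t0", "season"] == pytest.approx(1.0)

    def test_equal_season_and_site_split(self):
        n = 200
        X = np.column_stack([np.ones(n), np.arange(n) % 2, np.zeros(n)])
        var_season = np.var(X[:, 1])
        B = np.zeros((50, 3, 1))
        B[:, 1, 0] = 1.0
        lam = {"site": np.full((50, 1, 1), np.sqrt(var_season))}
        chain = {"B": B, "Lambda": lam}
        post = cm.Posterior("presence", [chain], ["intercept", "season", "sex"],
                            ["t0"], ["site"], np.zeros((1, 1)))
        vp = cm.variance_partition(post, X)
        assert vp.loc["t0", "season"] == pytest.approx(0.5)
        assert vp.loc["t0", "site"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        inp, _ = cm.simulate_from_model(n_samples=120, n_taxa=6, seed=10)
        post = cm.fit(inp, "presence", n_factors=2, chains=2, retained=50,
                      thin=1, seed=10)
        vp = cm.variance_partition(post, inp.X)
        np.testing.assert_allclose(vp.sum(axis=1), 1.0, atol=1e-8)


class TestFit:
    def test_sign_flip_leaves_linear_predictor_unchanged(self):
        """Flipping a factor and its loadings is likelihood-invariant."""
        rng = np.random.default_rng(11)
        eta = rng.standard_normal((5, 2))
        lam = rng.standard_normal((2, 4))
        g = np.array([0, 1, 2, 3, 4, 0, 1])
        m1 = eta[g] @ lam
        m2 = (-eta)[g] @ (-lam)
        np.testing.assert_allclose(m1, m2)

    def test_presence_requires_complete_matrix(self):
        inp, _ = cm.simulate_from_model(n_samples=50, n_taxa=3, seed=12)
        inp.Y[0, 0] = np.nan
        with pytest.raises(ValueError):
            cm.fit(inp, "presence")

    def test_unknown_component_raises(self):
        inp, _ = cm.simulate_from_model(n_samples=50, n_taxa=3, seed=13)
        with pytest.raises(ValueError):
            cm.fit(inp, "component")

    def test_rmse_shrinks_with_sample_size(self):
        """Fixed-effect error decreases from n=150 to n=600."""
        rmse = {}
        for n in (150, 600):
            inp, truth = cm.simulate_from_model(n_samples=n, n_taxa=8, seed=14)
            post = cm.fit(inp, "presence", n_factors=2, chains=2,
                          retained=100, thin=1, seed=14)
            B = post.stacked("B").mean(axis=0)
            rmse[n] = float(np.sqrt(np.mean((B[1:] - truth["B"][1:]) ** 2)))
        assert rmse[600] < rmse[150]

    def test_two_seeded_runs_agree(self):
        """Independent seeded runs on fixed data sample the same posterior:
        chains pooled across runs still pass the PSRF check."""
        inp, _ = cm.simulate_from_model(n_samples=200, n_taxa=6, seed=15)
        posts = [cm.fit(inp, "presence", n_factors=2, chains=2, retained=250,
                        thin=10, seed=s) for s in (100, 200)]
        merged = cm.Posterior(
            "presence", posts[0].chains + posts[1].chains,
            posts[0].covariates, posts[0].taxa, posts[0].level_names,
            posts[0].pred_mean)
        ok, psrfs = cm.psrf_check(merged)
        assert float(psrfs.quantile(0.75)) <= 1.05


class TestEvaluate:
    def test_explanatory_beats_predictive_on_average(self):
        inp, _ = cm.simulate_from_model(n_samples=200, n_taxa=8, seed=16)
        post = cm.fit(inp, "presence", n_factors=2, chains=2, retained=100,
                      thin=1, seed=16)
        ev = cm.evaluate(post, inp, seed=16,
                         refit_kwargs={"n_factors": 2, "chains": 2,
                                       "retained": 100})
        assert ev.explanatory_AUC.mean() >= ev.predictive_AUC.mean()
        assert ev.explanatory_AUC.dropna().between(0, 1).all()
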