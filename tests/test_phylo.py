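"""Tree geometry, covariance transforms, and trait-evolution model fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import allomorph as am
from allomorph import phylo
from allomorph.errors import InsufficientDataError, TreeError


class TestTreeIO:
    def test_hand_tree_depths(self, hand_tree):
        depths = phylo.tip_depths(hand_tree)
        assert sorted(depths.index) == ["A", "B", "C"]
        assert np.allclose(depths.to_numpy(), 2.0)
        assert am.is_ultrametric(hand_tree)

    def test_prune_collapses_and_sums(self, hand_tree):
        pruned = am.prune_to(hand_tree, ["A", "C"])
        depths = phylo.tip_depths(pruned)
        assert sorted(depths.index) == ["A", "C"]
        assert depths["A"] == pytest.approx(2.0)  # 1 + 1 collapsed

    def test_prune_preserves_original(self, hand_tree):
        am.prune_to(hand_tree, ["A", "C"])
        assert len(list(hand_tree.leaf_node_iter())) == 3

    def test_roundtrip_preserves_depths(self, yule38):
        back = am.read_newick(am.write_newick(yule38))
        d0 = phylo.tip_depths(yule38).sort_index()
        d1 = phylo.tip_depths(back).sort_index()
        assert np.allclose(d0.to_numpy(), d1.to_numpy(), rtol=1e-9)

    def test_parse_errors(self):
        with pytest.raises(TreeError, match="parse"):
            am.read_newick("((A:1,B:1):1,C:2;")  # unmatched parenthesis
        with pytest.raises(TreeError, match="branch length"):
            am.read_newick("((A:1,B:1):1,C);")

    def test_prune_to_missing_or_too_few(self, hand_tree):
        with pytest.raises(TreeError, match="absent"):
            am.prune_to(hand_tree, ["A", "Z"])
        with pytest.raises(TreeError, match="fewer than 2"):
            am.prune_to(hand_tree, ["A"])


class TestVCV:
    def test_hand_tree_entries(self, hand_tree):
        C = am.vcv(hand_tree)
        assert C.loc["A", "A"] == pytest.approx(2.0)
        assert C.loc["A", "B"] == pytest.approx(1.0)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    def test_star_tree_is_scaled_identity(self):
        star = am.read_newick("(A:3,B:3,C:3,D:3);")
        C = am.vcv(star).to_numpy()
        assert np.allclose(C, 3.0 * np.eye(4))

    def test_matches_monte_carlo_covariance(self):
        """Empirical tip covariance over many replicated walks equals the
        analytic shared-path-length matrix within sampling error."""
        tree = am.simulate_yule_tree(6, seed=21, depth=5.0)
        C = am.vcv(tree).to_numpy()
        rng = np.random.default_rng(22)
        sims = phylo.simulate_mvn(C, 1.0, 0.0, 50_000, rng)
        emp = np.cov(sims.T)
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / 50_000)
        assert np.all(np.abs(emp - C) < 3.0 * se)


class TestTransforms:
    def test_lambda_identity_and_star(self, hand_tree):
        C = am.vcv(hand_tree)
        assert np.allclose(am.lambda_transform(C, 1.0).to_numpy(), C.to_numpy())
        zero = am.lambda_transform(C, 0.0).to_numpy()
        assert np.allclose(zero, np.diag(np.diag(C.to_numpy())))
        half = am.lambda_transform(C, 0.5)
        assert half.loc["A", "B"] == pytest.approx(0.5)
        assert half.loc["A", "A"] == pytest.approx(2.0)

    def test_delta_arithmetic_and_limit(self, hand_tree):
        C = am.vcv(hand_tree)
        assert np.allclose(am.delta_transform(C, 1.0).to_numpy(), C.to_numpy())
        two = am.delta_transform(C, 2.0)
        assert two.loc["A", "A"] == pytest.approx(4.0)
        assert two.loc["A", "B"] == pytest.approx(1.0)
        # large delta drives relative shared history toward zero (tip-dominated)
        big = am.delta_transform(C, 3.0)
        assert big.loc["A", "B"] / big.loc["A", "A"] < C.loc["A", "B"] / C.loc["A", "A"]

    def test_bounds_enforced(self, hand_tree):
        C = am.vcv(hand_tree)
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                am.lambda_transform(C, bad)
        for bad in (0.0, 3.5):
            with pytest.raises(ValueError):
                am.delta_transform(C, bad)

    def test_delta_requires_ultrametric(self):
        ragged = am.read_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(TreeError, match="ultrametric"):
            am.delta_transform(am.vcv(ragged), 2.0)


class TestLikelihood:
    def test_star_tree_reduces_to_iid_normal(self):
        star = am.read_newick("(A:1,B:1,C:1,D:1,E:1);")
        y = np.array([0.3, -0.1, 0.7, 0.2, -0.4])
        ll, s2, root = am.mvn_profile_loglik(y, am.vcv(star))
        mu, sig2 = y.mean(), y.var()
        iid_ll = float(np.sum(stats.norm.logpdf(y, mu, np.sqrt(sig2))))
        assert root == pytest.approx(mu, abs=1e-12)
        assert s2 == pytest.approx(sig2, abs=1e-12)
        assert ll == pytest.approx(iid_ll, abs=1e-10)

    def test_dense_mvn_oracle_four_tips(self):
        tree = am.read_newick("((A:1,B:1):2,(C:2,D:2):1);")
        C = am.vcv(tree)
        y = pd.Series([1.2, 0.9, -0.3, 0.1], index=["A", "B", "C", "D"])
        ll, s2, root = am.mvn_profile_loglik(y, C)
        dense = stats.multivariate_normal.logpdf(
            y.to_numpy(), mean=np.full(4, root), cov=s2 * C.to_numpy()
        )
        assert ll == pytest.approx(float(dense), abs=1e-10)

    def test_constant_trait_flagged_degenerate(self, yule38):
        from allomorph.errors import DegenerateDataError

        with pytest.raises(DegenerateDataError):
            am.mvn_profile_loglik(np.ones(38), am.vcv(yule38))


class TestFitModel:
    def test_identity_transforms_agree(self, yule38):
        y = am.simulate_trait(yule38, "BM", sigma2=0.01, root_state=2.0, seed=31)
        C = am.vcv(yule38)
        ll_bm = am.fit_model(y, C, "BM").loglik
        ll_l1 = am.mvn_profile_loglik(y, am.lambda_transform(C, 1.0))[0]
        ll_d1 = am.mvn_profile_loglik(y, am.delta_transform(C, 1.0))[0]
        assert ll_l1 == pytest.approx(ll_bm, abs=1e-8)
        assert ll_d1 == pytest.approx(ll_bm, abs=1e-8)
        # fitted models can only do better than BM (nesting)
        assert am.fit_model(y, C, "lambda").loglik >= ll_bm - 1e-8
        assert am.fit_model(y, C, "delta").loglik >= ll_bm - 1e-8

    def test_independent_reference_fit(self):
        """Frozen cross-check against an independent ML implementation.

        The same 12-tip tree and trait (deterministic generators) fitted with
        the lambda model in R (ape/phytools phylosig) give lambda = 0.9359938,
        logL = -13.3291788."""
        tree = am.simulate_yule_tree(12, seed=42, depth=50.0)
        y = am.simulate_trait(tree, "lambda", theta=0.6, sigma2=0.02, root_state=1.0, seed=43)
        fit = am.fit_model(y, tree, "lambda")
        assert fit.theta == pytest.approx(0.9359938, abs=2e-4)
        assert fit.loglik == pytest.approx(-13.3291788, abs=1e-6)

    def test_permuted_trait_loses_signal(self, yule38):
        y = am.simulate_trait(yule38, "BM", sigma2=0.01, seed=33)
        rng = np.random.default_rng(34)
        perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        assert am.fit_model(perm, yule38, "lambda").theta < 0.2

    def test_needs_four_tips(self, hand_tree):
        with pytest.raises(InsufficientDataError):
            am.fit_model(np.array([1.0, 2.0, 3.0]), hand_tree, "lambda")

    def test_boundary_optimum_flagged(self, yule38):
        y = am.simulate_trait(yule38, "BM", sigma2=0.01, seed=35)
        rng = np.random.default_rng(36)
        perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        fit = am.fit_model(perm, yule38, "lambda")
        if fit.theta in (0.0, 1.0):
            assert fit.at_bound


class TestBootstrapCI:
    def test_same_seed_identical(self):
        tree = am.simulate_yule_tree(8, seed=41, depth=10.0)
        y = am.simulate_trait(tree, "BM", sigma2=0.5, seed=42)
        ci1 = am.bootstrap_ci(y, tree, "lambda", n_sim=100, seed=7)
        ci2 = am.bootstrap_ci(y, tree, "lambda", n_sim=100, seed=7)
        assert ci1 == ci2

    def test_small_nsim_warns(self):
        tree = am.simulate_yule_tree(8, seed=43, depth=10.0)
        y = am.simulate_trait(tree, "BM", sigma2=0.5, seed=44)
        with pytest.warns(UserWarning, match="n_sim"):
            am.bootstrap_ci(y, tree, "lambda", n_sim=50, seed=7)

    def test_coverage_of_true_lambda(self):
        """Bootstrap intervals cover the generating lambda at close to the
        nominal rate (finite-sample slack allowed)."""
        tree = am.simulate_yule_tree(64, seed=900, depth=110.0)
        C = am.vcv(tree)
        Ct = phylo._lambda_arr(C.to_numpy(), 0.5)
        covered = 0
        n_rep = 30
        for rep in range(n_rep):
            y = phylo.simulate_mvn(Ct, 0.01, 0.0, 1, np.random.default_rng(910 + rep))[0]
            lo, hi = am.bootstrap_ci(y, C, "lambda", n_sim=100, seed=950 + rep)
            covered += lo <= 0.5 <= hi
        assert covered / n_rep >= 0.85
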