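"""Continuous-trait models: BM ASR vs GLS oracle, jump MCMC, PGLS."""

import numpy as np
import pytest
import statsmodels.api as sm

import carapace as cp
from carapace import simulate as sim
from carapace.traitmodels import (
    ContinuousASRResults,
    ancestral_lifespans,
    branch_changes,
    mcse_median,
)

from conftest import random_traits, random_trees


def gls_asr_oracle(tree, traits):
    """Joint-ML ancestral states by direct linear algebra.

    Minimises sum over branches of (z_child − z_parent)^2 / t — the Brownian
    log-density up to constants — over internal node values, via the
    branch-weighted graph Laplacian.  Independent of the message-passing
    implementation.
    """
    n = tree.n_nodes
    internal = [v for v in range(n) if tree.children[v]]
    idx = {v: i for i, v in enumerate(internal)}
    x = np.zeros(n)
    for i in tree.tip_ids:
        x[i] = traits.values[tree.labels[i]]
    A = np.zeros((len(internal), len(internal)))
    b = np.zeros(len(internal))
    for c in range(n):
        if c == tree.root:
            continue
        p = tree.parent[c]
        w = 1.0 / tree.branch_length[c]
        pi, ci = idx.get(p), idx.get(c)
        if pi is not None:
            A[pi, pi] += w
        if ci is not None:
            A[ci, ci] += w
        if pi is not None and ci is not None:
            A[pi, ci] -= w
            A[ci, pi] -= w
        elif pi is not None:
            b[pi] += w * x[c]
        elif ci is not None:
            b[ci] += w * x[p]
    z = np.linalg.solve(A, b)
    est = x.copy()
    for v, i in idx.items():
        est[v] = z[i]
    # GLS rate: quadratic form with Brownian covariance at the GLS root mean
    tips = tree.tip_labels
    V = tree.shared_path_matrix(tips)
    xv = traits.array_for(tips)
    ones = np.ones(len(tips))
    Vi = np.linalg.inv(V)
    mu = (ones @ Vi @ xv) / (ones @ Vi @ ones)
    sigma2 = float((xv - mu) @ Vi @ (xv - mu)) / len(tips)
    var = np.zeros(n)
    Ainv = np.linalg.inv(A)
    for v, i in idx.items():
        var[v] = sigma2 * Ainv[i, i]
    return est, var, sigma2


class TestBrownianASR:
    def test_symmetric_cherry_root(self, cherry):
        res = cp.BrownianMotionASR(
            cherry, cp.TraitTable({"A": 0.0, "B": 2.0}, "x", "log2")
        ).fit()
        assert res.estimates[cherry.root] == pytest.approx(1.0)

    def test_asymmetric_cherry_matches_gls_weighting(self):
        # 1/t-precision-weighted mean: (0/1 + 2/3)/(1 + 1/3) = 0.5
        t = cp.parse_newick("(A:1,B:3);")
        res = cp.BrownianMotionASR(
            t, cp.TraitTable({"A": 0.0, "B": 2.0}, "x", "log2")
        ).fit()
        assert res.estimates[t.root] == pytest.approx(0.5)

    def test_constant_trait_degenerate(self, small_tree):
        res = cp.BrownianMotionASR(
            small_tree,
            cp.TraitTable({"A": 5.0, "B": 5.0, "C": 5.0}, "x", "log2"),
        ).fit()
        assert np.allclose(res.estimates, 5.0)
        assert res.sigma2 == 0.0

    def test_missing_tip_error(self, small_tree):
        with pytest.raises(ValueError, match="missing trait values: C"):
            cp.BrownianMotionASR(
                small_tree, cp.TraitTable({"A": 1.0, "B": 2.0}, "x", "log2")
            ).fit()

    def test_requires_log2_scale(self, small_tree):
        with pytest.raises(ValueError, match="log2"):
            cp.BrownianMotionASR(
                small_tree,
                cp.TraitTable({"A": 1.0, "B": 2.0, "C": 3.0}, "x", "linear"),
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_gls_oracle_on_random_trees(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        for tree in random_trees(5, seed=seed + 1):
            traits = random_traits(tree, rng)
            res = cp.BrownianMotionASR(tree, traits).fit()
            est, var, sigma2 = gls_asr_oracle(tree, traits)
            assert np.allclose(res.estimates, est, atol=1e-8)
            assert np.allclose(res.variances, var, atol=1e-8)
            assert res.sigma2 == pytest.approx(sigma2, abs=1e-10)

    def test_tip_estimates_exact_and_zero_variance(self, yule16):
        traits, _ = sim.sim_traits(yule16, 0.01, seed=9)
        res = cp.BrownianMotionASR(yule16, traits).fit()
        for i in yule16.tip_ids:
            assert res.estimates[i] == traits.values[yule16.labels[i]]
            assert res.variances[i] == 0.0


class TestJumpModel:
    def test_same_seed_bit_identical(self, yule16):
        traits, _ = sim.sim_traits(yule16, 0.01, seed=5)
        fit = lambda: cp.JumpDiffusionASR(yule16, traits, nu=2.0).fit(
            iterations=1500, burn_in=500, seed=11
        )
        a, b = fit(), fit()
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.c_samples, b.c_samples)

    def test_gaussian_limit_matches_bm(self, yule16):
        traits, _ = sim.sim_traits(yule16, 0.01, seed=6)
        bm = cp.BrownianMotionASR(yule16, traits).fit()
        res = cp.JumpDiffusionASR(yule16, traits, nu=200.0).fit(
            iterations=12000, burn_in=4000, seed=3
        )
        internal = ~yule16.is_tip
        diff = np.abs(res.estimates[internal] - bm.estimates[internal])
        se = mcse_median(res.samples)[internal]
        assert np.all(diff <= 2.0 * se)

    def test_planted_jump_recovered(self):
        tree, branch, traits, _ = sim.planted_jump_scenario(seed=1)
        res = cp.JumpDiffusionASR(tree, traits, nu=2.0).fit(
            iterations=6000, burn_in=2000, seed=2
        )
        incs = {
            v: np.median(res.samples[:, v] - res.samples[:, tree.parent[v]])
            for v in range(tree.n_nodes)
            if v != tree.root
        }
        assert max(incs, key=lambda v: abs(incs[v])) == branch

    def test_invalid_nu_and_iterations(self, yule16):
        traits, _ = sim.sim_traits(yule16, 0.01, seed=5)
        with pytest.raises(ValueError, match="nu"):
            cp.JumpDiffusionASR(yule16, traits, nu=0.0)
        with pytest.raises(ValueError, match="burn_in"):
            cp.JumpDiffusionASR(yule16, traits).fit(iterations=10, burn_in=10)


class TestPGLS:
    def test_star_tree_equals_ols(self, star_tree):
        rng = np.random.Generator(np.random.PCG64(0))
        x = {lab: float(rng.normal()) for lab in star_tree.tip_labels}
        y = {lab: 2 * x[lab] + float(rng.normal(0, 0.1))
             for lab in star_tree.tip_labels}
        fit = cp.PGLS(
            star_tree,
            cp.TraitTable(x, "x", "log2"),
            cp.TraitTable(y, "y", "log2"),
        ).fit()
        labs = fit.species
        X = sm.add_constant(np.array([x[l] for l in labs]))
        ols = sm.OLS(np.array([y[l] for l in labs]), X).fit()
        assert fit.intercept == pytest.approx(ols.params[0], abs=1e-8)
        assert fit.slope == pytest.approx(ols.params[1], abs=1e-8)

    def test_exact_linear_relation(self, small_tree):
        x = {"A": 1.0, "B": 2.0, "C": 3.0}
        y = {k: 2 * v + 1 for k, v in x.items()}
        fit = cp.PGLS(
            small_tree, cp.TraitTable(x, "x", "log2"),
            cp.TraitTable(y, "y", "log2"),
        ).fit()
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.sigma2_resid == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_two_tips_rejected(self, cherry):
        with pytest.raises(ValueError, match="n < 3"):
            cp.PGLS(
                cherry, cp.TraitTable({"A": 1.0, "B": 2.0}, "x", "log2"),
                cp.TraitTable({"A": 1.0, "B": 2.0}, "y", "log2"),
            )

    def test_residuals_are_observed_minus_fitted(self, yule16):
        size, _ = sim.sim_traits(yule16, 0.01, seed=1)
        life, _ = sim.sim_lifespans(yule16, size, 0.5, 4.0, 0.002, seed=2)
        fit = cp.PGLS(yule16, size, life).fit()
        obs = life.array_for(fit.species)
        assert np.allclose(fit.residuals, obs - fit.fitted, atol=1e-12)


class TestAncestralLifespans:
    def test_zero_residuals_pure_surface(self, small_tree):
        x = {"A": 1.0, "B": 2.0, "C": 3.0}
        y = {k: 0.5 * v + 3.0 for k, v in x.items()}
        xt = cp.TraitTable(x, "size", "log2")
        pgls = cp.PGLS(small_tree, xt, cp.TraitTable(y, "life", "log2")).fit()
        asr = cp.BrownianMotionASR(small_tree, xt).fit()
        out = ancestral_lifespans(small_tree, pgls, asr)
        assert np.allclose(
            out["log2_lifespan"], 3.0 + 0.5 * asr.estimates, atol=1e-10
        )

    def test_beta_zero_reduces_to_direct_bm(self, yule16):
        # with a flat regression surface the fitted-plus-residual rule is
        # algebraically BM ASR applied to the lifespans themselves
        from carapace.traitmodels import PGLSResults

        size, _ = sim.sim_traits(yule16, 0.01, seed=3)
        rng = np.random.Generator(np.random.PCG64(4))
        life = cp.TraitTable(
            {lab: float(rng.normal(4, 0.5)) for lab in yule16.tip_labels},
            "life", "log2",
        )
        species = yule16.tip_labels
        obs = life.array_for(species)
        pgls = PGLSResults(
            model=None, intercept=4.0, slope=0.0, sigma2_resid=float(obs.var()),
            residuals=obs - 4.0, fitted=np.full(len(obs), 4.0),
            cov_params=np.eye(2), species=species,
        )
        out = ancestral_lifespans(yule16, pgls, cp.BrownianMotionASR(
            yule16, size).fit())
        direct = cp.BrownianMotionASR(yule16, life).fit()
        assert np.allclose(out["log2_lifespan"], direct.estimates, atol=1e-8)

    def test_tips_reproduce_observations(self, yule16):
        size, _ = sim.sim_traits(yule16, 0.01, seed=5)
        life, _ = sim.sim_lifespans(yule16, size, 0.5, 4.0, 0.002, seed=6)
        pgls = cp.PGLS(yule16, size, life).fit()
        out = ancestral_lifespans(
            yule16, pgls, cp.BrownianMotionASR(yule16, size).fit()
        )
        for _, row in out[out["is_tip"]].iterrows():
            assert row["log2_lifespan"] == pytest.approx(
                life.values[row["label"]], abs=1e-12
            )


class TestBranchChanges:
    def test_trivial_and_percent_convention(self, yule16):
        traits, _ = sim.sim_traits(yule16, 0.01, seed=7)
        res = cp.BrownianMotionASR(yule16, traits).fit()
        bc = branch_changes(yule16, res)
        # percent change reporting: 100 -> 486 is a 386% increase
        assert 100.0 * (2.0 ** np.log2(486 / 100) - 1.0) == pytest.approx(386.0)
        zero = bc[np.isclose(bc["delta_log2"], 0.0)]
        assert np.allclose(zero["percent_change"], 0.0)
        assert np.allclose(zero["rate_multiplier"], 0.0)

    def test_rate_multiplier_calibration(self, cherry):
        # delta^2 = sigma2 * t  =>  r = 1 by definition
        est = np.array([0.0, 1.0, -1.0])
        asr = ContinuousASRResults(None, cherry, est, np.zeros(3), sigma2=1.0)
        bc = branch_changes(cherry, asr)
        assert np.allclose(bc["rate_multiplier"], 1.0)

    def test_telescoping_along_root_paths(self, yule16):
        traits, _ = sim.sim_traits(yule16, 0.01, seed=8)
        res = cp.BrownianMotionASR(yule16, traits).fit()
        bc = branch_changes(yule16, res).set_index("child_id")
        for tip in yule16.tip_ids:
            total, v = 0.0, int(tip)
            while v != yule16.root:
                total += bc.loc[v, "delta_log2"]
                v = int(yule16.parent[v])
            assert total == pytest.approx(
                res.estimates[tip] - res.estimates[yule16.root], abs=1e-10
            )

    def test_mean_rate_multiplier_identity_and_truth_calibration(self):
        # reconstructed states: mean r_b is exactly n/(2n-2) (the minimised
        # quadratic form equals n * sigma2_hat); true histories: mean ~ 1
        means_rec, means_true = [], []
        for rep in range(50):
            tree = sim.sim_tree(16, seed=rep + 1)
            traits, truth = sim.sim_traits(tree, 0.01, seed=100 + rep)
            res = cp.BrownianMotionASR(tree, traits).fit()
            means_rec.append(branch_changes(tree, res)["rate_multiplier"].mean())
            true_asr = ContinuousASRResults(
                None, tree, truth.node_values, np.zeros(tree.n_nodes),
                sigma2=0.01,
            )
            means_true.append(
                branch_changes(tree, true_asr)["rate_multiplier"].mean()
            )
        assert np.allclose(means_rec, 16 / 30, atol=1e-9)
        assert 0.7 <= np.median(means_true) <= 1.3

    def test_zero_length_branch_with_jump_flagged(self):
        t = cp.parse_newick("((A:0.0,B:1.0):1.0,C:2.0);")
        est = np.array([0.0, 0.0, 3.0, 0.0, 0.0])
        asr = ContinuousASRResults(None, t, est, np.zeros(5), sigma2=1.0)
        with pytest.warns(UserWarning, match="zero-length"):
            bc = branch_changes(t, asr)
        assert np.isinf(
            bc.set_index("child_id").loc[t.node_id("A"), "rate_multiplier"]
        )
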