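"""End-to-end validation workloads.

Each function here recomputes, from scratch and from a single seed, one of
the quantitative checks the package is judged by: in-text arithmetic
(neoplasia prevalence, dose bookkeeping), agreement between the fast
implementations and slow independent oracles (exhaustive state enumeration,
closed-form GLS, OLS, exact combinatorics), parameter and planted-structure
recovery on synthetic data, analytic identities of the risk statistic, and
null calibration of the tests.  The oracles in this module are deliberately
naive (brute-force enumeration, dense linear algebra, exact rationals) and
share no code with the implementations they check.

Problem sizes follow the package's standard study conditions: recovery runs
use 16–200 tips and 20–50 replicates; calibration uses 500–1,000 null
simulations.
"""

from __future__ import annotations

import itertools
import math
import zlib
from fractions import Fraction

import numpy as np
import pandas as pd

from . import assay, enrichment
from . import simulate as sim
from .cancer_risk import branch_ricr, intrinsic_risk, neoplasia_prevalence, ricr_pipeline
from .duplication import (
    BinaryCharacterMatrix,
    TwoStateMarkovModel,
    TwoStateResults,
    _transition_matrix,
    count_events,
    filter_reliable,
    marginal_posteriors,
)
from .io import RunConfig, TraitTable
from .traitmodels import PGLS, BrownianMotionASR, JumpDiffusionASR

__all__ = [
    "prevalence_check",
    "dose_checks",
    "oracle_checks",
    "recovery_checks",
    "identity_checks",
    "calibration_checks",
]


def _seeds(seed: int, tag: str, n: int) -> list[int]:
    """Independent 31-bit streams derived from (seed, workload tag)."""
    ss = np.random.SeedSequence([seed, zlib.crc32(tag.encode()) % 2**31])
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint64)]


# ---------------------------------------------------------------------------
# in-text arithmetic


def prevalence_check() -> dict:
    """Zoo-necropsy neoplasia prevalence: 6 neoplasms in 490 turtles."""
    return {"turtle_neoplasia_prevalence_pct": neoplasia_prevalence(6, 490)}


def dose_checks() -> dict:
    """Reagent addition halves each printed nominal dose (μM)."""
    out = {}
    for drug, nominal in (("tunicamycin", 50.0), ("etoposide", 1000.0),
                          ("paraquat", 5000.0)):
        plate = assay.build_plate(["spA"], drug)
        wells = plate.wells
        final = wells.loc[(wells["nominal_uM"] == nominal)
                          & (wells["role"] == "treatment"), "final_uM"]
        out[f"{drug}_24h_final_uM"] = float(final.iloc[0])
    return out


# ---------------------------------------------------------------------------
# independent oracles


def _enum_likelihood_and_posteriors(tree, pi1, s, char):
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    pi = [1.0 - pi1, pi1]
    total = 0.0
    mass1 = {v: 0.0 for v in internal}
    for states in itertools.product([0, 1], repeat=len(internal)):
        assign = dict(zip(internal, states))
        lik = pi[assign[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            P = _transition_matrix(pi1, s, tree.branch_length[v])
            ps = assign[tree.parent[v]]
            if tree.children[v]:
                lik *= P[ps, assign[v]]
            elif tree.labels[v] in char:
                lik *= P[ps, char[tree.labels[v]]]
        total += lik
        for i, v in enumerate(internal):
            if states[i] == 1:
                mass1[v] += lik
    return total, {v: m / total for v, m in mass1.items()}


def _gls_reconstruction(tree, traits):
    """Joint-ML ancestral states via the branch-weighted Laplacian."""
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
    return est


def oracle_checks(seed: int) -> dict:
    """Fast implementations vs brute-force/closed-form oracles."""
    out = {}

    # pruning likelihood & marginal posteriors vs exhaustive enumeration
    rng = np.random.Generator(np.random.PCG64(_seeds(seed, "enum", 1)[0]))
    lik_err = post_err = 0.0
    for k, s0 in enumerate(_seeds(seed, "enum-trees", 50)):
        tree = sim.sim_tree(int(3 + k % 3), seed=s0, root_age=50.0)
        pi1 = float(rng.uniform(0.1, 0.9))
        s = float(rng.uniform(0.005, 0.1))
        char = {lab: int(rng.integers(0, 2)) for lab in tree.tip_labels}
        exact, post = _enum_likelihood_and_posteriors(tree, pi1, s, char)
        table = pd.DataFrame({lab: [char[lab]] for lab in tree.tip_labels},
                             index=["g"])
        model = TwoStateMarkovModel(tree, BinaryCharacterMatrix(table))
        lik_err = max(lik_err, abs(math.exp(model.loglik(pi1, s)) - exact))
        fit = TwoStateResults(model, pi1, s, 0.0, "optimized")
        got = marginal_posteriors(fit, tree, char)
        post_err = max(post_err,
                       max(abs(got[v] - p) for v, p in post.items()))
    out["pruning_vs_enumeration_max_abs_err"] = lik_err
    out["posteriors_vs_enumeration_max_abs_err"] = post_err

    # BM ASR vs closed-form GLS reconstruction on random trees <= 8 tips
    bm_err = 0.0
    for k, s0 in enumerate(_seeds(seed, "bm-gls", 20)):
        tree = sim.sim_tree(int(3 + k % 6), seed=s0, root_age=50.0)
        traits = TraitTable(
            {lab: float(rng.normal()) for lab in tree.tip_labels},
            "x", "log2")
        res = BrownianMotionASR(tree, traits).fit()
        bm_err = max(bm_err, float(np.max(np.abs(
            res.estimates - _gls_reconstruction(tree, traits)))))
    out["bm_asr_vs_gls_max_abs_err"] = bm_err

    # PGLS on a star tree vs OLS
    import statsmodels.api as sm

    labels = [f"s{i}" for i in range(12)]
    parent = np.array([-1] + [0] * 12)
    bl = np.array([np.nan] + [3.0] * 12)
    from .trees import Phylogeny

    star = Phylogeny(parent, bl, [None] + labels)
    xs = {lab: float(rng.normal()) for lab in labels}
    ys = {lab: 1.5 * xs[lab] + float(rng.normal(0, 0.2)) for lab in labels}
    fit = PGLS(star, TraitTable(xs, "x", "log2"),
               TraitTable(ys, "y", "log2")).fit()
    X = sm.add_constant(np.array([xs[l] for l in fit.species]))
    ols = sm.OLS(np.array([ys[l] for l in fit.species]), X).fit()
    out["pgls_star_vs_ols_max_abs_err"] = float(max(
        abs(fit.intercept - ols.params[0]), abs(fit.slope - ols.params[1])))

    # permutation p vs exhaustive enumeration, groups of 3 (integer-exact)
    mism = 0
    for s0 in _seeds(seed, "perm", 20):
        r2 = np.random.Generator(np.random.PCG64(s0))
        t, c = r2.normal(1, 1, 3), r2.normal(0, 1, 3)
        est = assay.mean_difference(t, c, n_boot=50, seed=s0)
        pooled = np.concatenate([t, c])
        obs = t.mean() - c.mean()
        hits = sum(
            abs(pooled[list(i)].mean()
                - np.delete(pooled, list(i)).mean()) >= abs(obs) - 1e-12
            for i in itertools.combinations(range(6), 3))
        mism += est.p_value != hits / 20
    out["permutation_vs_enumeration_mismatches"] = mism

    # BCa with forced z0 = 0, a = 0 vs direct percentile of same draws
    s0 = _seeds(seed, "bca", 1)[0]
    r2 = np.random.Generator(np.random.PCG64(s0))
    t, c = r2.normal(1, 1, 10), r2.normal(0, 1, 10)
    est = assay.mean_difference(t, c, n_boot=2000, seed=s0,
                                force_percentile=True)
    r3 = np.random.Generator(np.random.PCG64(s0))
    boot = (t[r3.integers(0, 10, size=(2000, 10))].mean(axis=1)
            - c[r3.integers(0, 10, size=(2000, 10))].mean(axis=1))
    lo, hi = np.quantile(boot, [0.025, 0.975])
    out["bca_forced_vs_percentile_max_abs_err"] = float(
        max(abs(est.ci_low - lo), abs(est.ci_high - hi)))

    # ORA p-values vs exact rational combinatorics, N <= 20
    ora_err = 0.0
    for s0 in _seeds(seed, "ora", 20):
        r2 = np.random.Generator(np.random.PCG64(s0))
        N = int(r2.integers(5, 21))
        K = int(r2.integers(1, N + 1))
        n = int(r2.integers(1, N + 1))
        genes = [f"g{i}" for i in range(N)]
        term = set(r2.choice(genes, size=K, replace=False))
        fg = set(r2.choice(genes, size=n, replace=False))
        coll = enrichment.GeneSetCollection(
            {"t": term}, {"t": False}, set(genes))
        k = len(fg & term)
        exact_hg = sum(
            Fraction(math.comb(K, j) * math.comb(N - K, n - j),
                     math.comb(N, n))
            for j in range(k, min(n, K) + 1))
        p = Fraction(K, N)
        exact_bn = sum(
            math.comb(n, j) * p**j * (1 - p) ** (n - j)
            for j in range(k, n + 1))
        hg = enrichment.hypergeom_ora(fg, coll)["p_raw"].iloc[0]
        bn = enrichment.binomial_ora(fg, coll)["p_raw"].iloc[0]
        ora_err = max(ora_err, abs(hg - float(exact_hg)),
                      abs(bn - float(exact_bn)))
    out["ora_vs_rational_max_abs_err"] = ora_err
    return out


# ---------------------------------------------------------------------------
# parameter and planted-structure recovery


def recovery_checks(seed: int, jump_iterations: int = 6000,
                    jump_burn_in: int = 2000) -> dict:
    out = {}

    # Brownian rate: 50 Yule trees of 200 tips at sigma2 = 1
    ests = []
    for s0 in _seeds(seed, "bm-rate", 50):
        tree = sim.sim_tree(200, seed=s0, root_age=1.0)
        traits, _ = sim.sim_traits(tree, 1.0, seed=s0 + 1)
        ests.append(BrownianMotionASR(tree, traits).fit().sigma2)
    out["bm_sigma2_median_at_truth_1"] = float(np.median(ests))

    # two-state (pi1, s): 16 tips, 500 characters, 20 replicates
    pi_est, s_est = [], []
    for s0 in _seeds(seed, "two-state", 20):
        tree = sim.sim_tree(16, seed=s0, root_age=10.0)
        truth = TwoStateResults.__new__(TwoStateResults)
        truth.pi1, truth.pi0, truth.s = 0.3, 0.7, 0.1
        counts, _ = sim.sim_binary_histories(tree, truth, 500, seed=s0 + 1)
        from .duplication import encode_copy_number

        fit = TwoStateMarkovModel(tree, encode_copy_number(counts)).fit()
        pi_est.append(fit.pi1)
        s_est.append(fit.s)
    out["two_state_pi1_median_at_truth_0.3"] = float(np.median(pi_est))
    out["two_state_s_median_at_truth_0.1"] = float(np.median(s_est))

    # PGLS slope: 200 tips, 30 replicates, truth beta = 0.5
    betas = []
    for s0 in _seeds(seed, "pgls-beta", 30):
        tree = sim.sim_tree(200, seed=s0)
        size, _ = sim.sim_traits(tree, 0.01, seed=s0 + 1)
        life, _ = sim.sim_lifespans(tree, size, 0.5, 4.0, 0.002, seed=s0 + 2)
        betas.append(PGLS(tree, size, life).fit().slope)
    out["pgls_beta_median_at_truth_0.5"] = float(np.median(betas))

    # planted 8-SD jump: fraction of 20 replicates whose jump branch shows
    # the largest posterior median increment
    hits = 0
    for s0 in _seeds(seed, "jump", 20):
        tree, branch, traits, _ = sim.planted_jump_scenario(seed=s0)
        res = JumpDiffusionASR(tree, traits, nu=2.0).fit(
            iterations=jump_iterations, burn_in=jump_burn_in, seed=s0 + 7)
        incs = {
            v: float(np.median(res.samples[:, v]
                               - res.samples[:, tree.parent[v]]))
            for v in range(tree.n_nodes) if v != tree.root
        }
        hits += max(incs, key=lambda v: abs(incs[v])) == branch
    out["planted_jump_recovery_rate"] = hits / 20.0

    # giant lineage: stem branch carries the largest decreased-RICR change
    hits = 0
    for s0 in _seeds(seed, "giant", 20):
        tree, branch, size, life = sim.giant_lineage_scenario(seed=s0)
        cfg = RunConfig(model="jump", mcmc_iterations=4000,
                        mcmc_burn_in=1500, seed=s0 + 3)
        res = ricr_pipeline(tree, size, life, cfg)
        r = res["ricr"].set_index("child_id")
        hits += int(r["decreased_ricr_log2"].idxmax()) == branch
    out["giant_lineage_stem_recovery_rate"] = hits / 20.0

    # per-branch duplication counts: Spearman truth vs inferred, 20 reps
    from scipy.stats import spearmanr

    from .duplication import encode_copy_number

    rhos = []
    truth = TwoStateResults.__new__(TwoStateResults)
    truth.pi1, truth.pi0, truth.s = 0.3, 0.7, 0.001
    for s0 in _seeds(seed, "spearman", 20):
        tree = sim.sim_tree(16, seed=s0)
        counts, tr = sim.sim_binary_histories(tree, truth, 200, seed=s0 + 1)
        mat = encode_copy_number(counts)
        fit = TwoStateMarkovModel(tree, mat).fit()
        post = filter_reliable(fit.posteriors(), mat)
        ev = count_events(post, tree).set_index("child_id")
        true_counts = tr.events[tr.events["event"] == "duplication"].groupby(
            "child_id").size()
        tc = np.array([true_counts.get(i, 0) for i in ev.index])
        rhos.append(spearmanr(tc, ev["duplications"].to_numpy()).statistic)
    out["duplication_count_spearman_median"] = float(np.median(rhos))
    return out


# ---------------------------------------------------------------------------
# analytic identities


def identity_checks(seed: int) -> dict:
    out = {}
    base = intrinsic_risk(10.0, 5.0)
    doubled = intrinsic_risk(20.0, 5.0)
    out["k_lifespan_doubling_factor"] = float(
        2.0 ** (doubled["log2_K"] - base["log2_K"]))

    s0 = _seeds(seed, "identity", 1)[0]
    tree = sim.sim_tree(16, seed=s0)
    size, _ = sim.sim_traits(tree, 0.005, seed=s0 + 1, root_value=8.0)
    life, _ = sim.sim_lifespans(tree, size, 0.4, 3.0, 0.001, seed=s0 + 2)
    lin = lambda t, nm, u: TraitTable(
        {sp: 2.0**v for sp, v in t.values.items()}, nm, "linear", u)
    res = ricr_pipeline(tree, lin(size, "size", "mm"), lin(life, "life", "yr"))
    ln = res["lifespans"]["log2_lifespan"].to_numpy()
    merged = res["ricr"].merge(res["size_changes"], on="child_id")
    dL = np.array([ln[c] - ln[tree.parent[c]] for c in merged["child_id"]])
    out["ricr_decomposition_max_abs_err"] = float(np.max(np.abs(
        merged["delta_ricr_log2"] - (6.0 * dL + merged["delta_log2"]))))

    tele = 0.0
    r = res["ricr"].set_index("child_id")
    log2K = res["node_log2K"]
    for tip in tree.tip_ids:
        total, v = 0.0, int(tip)
        while v != tree.root:
            total += r.loc[v, "delta_ricr_log2"]
            v = int(tree.parent[v])
        tele = max(tele, abs(total - (log2K[tip] - log2K[tree.root])))
    out["ricr_telescoping_max_abs_err"] = float(tele)
    return out


# ---------------------------------------------------------------------------
# null calibration


def calibration_checks(seed: int, n_null: int = 1000,
                       n_cover: int = 500) -> dict:
    out = {}
    rates = []
    for s0 in _seeds(seed, "ora-null", n_null):
        coll, fg, _ = sim.sim_annotations(200, 10, 20, 30, seed=s0)
        rows = enrichment.hypergeom_ora(fg, coll)
        rates.append(float((rows["p_raw"] <= 0.05).mean()))
    out["ora_null_false_positive_rate"] = float(np.mean(rates))

    rng = np.random.Generator(np.random.PCG64(_seeds(seed, "cover", 1)[0]))
    cover = 0
    for k in range(n_cover):
        a, b = rng.normal(size=10), rng.normal(size=10)
        est = assay.mean_difference(a, b, n_boot=1000, n_perm=1, seed=seed + k)
        cover += est.ci_low <= 0.0 <= est.ci_high
    out["bca_95ci_coverage"] = cover / n_cover
    return out
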