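"""Two-state duplication model: encoding, likelihood, posteriors, events."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import carapace as cp
from carapace import simulate as sim
from carapace.duplication import (
    BinaryCharacterMatrix,
    TwoStateMarkovModel,
    TwoStateResults,
    _transition_matrix,
)

from conftest import random_trees


def enumeration_likelihood(tree, pi1, s, char):
    """Total likelihood by brute-force sum over internal state assignments.

    ``char`` maps tip label -> state (missing tips omitted).
    """
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    pi = [1.0 - pi1, pi1]
    total = 0.0
    per_assignment = {}
    for states in itertools.product([0, 1], repeat=len(internal)):
        assign = dict(zip(internal, states))
        lik = pi[assign[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            P = _transition_matrix(pi1, s, tree.branch_length[v])
            parent_state = assign[tree.parent[v]]
            if tree.children[v]:
                lik *= P[parent_state, assign[v]]
            else:
                lab = tree.labels[v]
                if lab in char:
                    lik *= P[parent_state, char[lab]]
                # missing tip: sum over states = 1, no factor
        per_assignment[states] = lik
        total += lik
    return total, per_assignment, internal


def enumeration_posteriors(tree, pi1, s, char):
    """Marginal P(state=1) per internal node from the same enumeration."""
    total, per, internal = enumeration_likelihood(tree, pi1, s, char)
    post = {}
    for i, v in enumerate(internal):
        post[v] = sum(l for st, l in per.items() if st[i] == 1) / total
    return post


def model_with(tree, pi1, s, table):
    m = TwoStateMarkovModel(tree, BinaryCharacterMatrix(table))
    return m, TwoStateResults(m, pi1, s, 0.0, "optimized")


class TestEncoding:
    def test_rule(self):
        counts = cp.CopyNumberMatrix(pd.DataFrame(
            {"A": [1, 1, 0], "B": [3, 1, 2]},
            index=pd.Index(["g1", "g2", "g3"], name="gene")))
        enc = cp.encode_copy_number(counts)
        assert enc.table.loc["g1", "A"] == 0 and enc.table.loc["g1", "B"] == 1
        assert (enc.table.loc["g2"] == 0).all()
        # absence is missing, not state 0
        assert pd.isna(enc.table.loc["g3", "A"])
        assert enc.table.loc["g3", "B"] == 1

    def test_absence_as_state0_switch(self):
        counts = cp.CopyNumberMatrix(pd.DataFrame(
            {"A": [0], "B": [2]}, index=pd.Index(["g"], name="gene")))
        enc = cp.encode_copy_number(counts, absence_as_state0=True)
        assert enc.table.loc["g", "A"] == 0


class TestLikelihood:
    def test_two_tip_hand_example(self):
        # e^{-s t} = 0.5 on both pendant branches, pi = (.5, .5), tips (0, 1):
        # 0.5*(0.75*0.25) + 0.5*(0.25*0.75) = 0.09375 ... doubled = 0.1875
        t = cp.parse_newick("(A:1,B:1);")
        table = pd.DataFrame({"A": [0], "B": [1]}, index=["g"])
        model, _ = model_with(t, 0.5, math.log(2.0), table)
        assert math.exp(model.loglik(0.5, math.log(2.0))) == pytest.approx(
            0.1875, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_pruning_equals_enumeration(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        for tree in random_trees(10, max_tips=5, min_tips=4, seed=seed + 1):
            pi1 = float(rng.uniform(0.1, 0.9))
            s = float(rng.uniform(0.005, 0.1))
            char = {lab: int(rng.integers(0, 2)) for lab in tree.tip_labels}
            if rng.random() < 0.3:  # drop one tip to exercise missing data
                char.pop(tree.tip_labels[0])
            table = pd.DataFrame(
                {lab: [char.get(lab, pd.NA)] for lab in tree.tip_labels},
                index=["g"],
            )
            model, _ = model_with(tree, pi1, s, table)
            exact, _, _ = enumeration_likelihood(tree, pi1, s, char)
            assert math.exp(model.loglik(pi1, s)) == pytest.approx(
                exact, abs=1e-10
            )

    def test_fit_deterministic(self, yule16):
        truth = TwoStateResults.__new__(TwoStateResults)
        truth.pi1, truth.pi0, truth.s = 0.3, 0.7, 0.003
        counts, _ = sim.sim_binary_histories(yule16, truth, 80, seed=3)
        mat = cp.encode_copy_number(counts)
        f1 = TwoStateMarkovModel(yule16, mat).fit()
        f2 = TwoStateMarkovModel(yule16, mat).fit()
        assert (f1.pi1, f1.s, f1.loglik) == (f2.pi1, f2.s, f2.loglik)

    def test_rate_matrix_invariants(self):
        res = TwoStateResults(None, 0.3, 0.05, 0.0, "optimized")
        Q = res.Q
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert np.allclose(np.array([0.7, 0.3]) @ Q, 0.0)
        for t in (0.0, 1.0, 50.0, 1e4):
            P = res.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.all(P >= 0)


class TestModelSelection:
    def test_tie_broken_to_fewer_parameters(self):
        a = TwoStateResults(None, 0.5, 0.1, -100.0, "equal")
        b = TwoStateResults(None, 0.4, 0.1, -100.0, "optimized")
        a.model = b.model = type("M", (), {"tree": None, "matrix": None})()
        best, table = cp.select_model([a, b])
        assert best.freq_mode == "equal"

    def test_aic_arithmetic(self):
        shared = type("M", (), {"tree": None, "matrix": None})()
        a = TwoStateResults(None, 0.4, 0.1, -100.0, "optimized")
        b = TwoStateResults(None, 0.5, 0.1, -103.0, "equal")
        a.model = b.model = shared
        best, table = cp.select_model([a, b])
        assert best.freq_mode == "optimized"
        assert sorted(table["aic"]) == [204.0, 208.0]

    def test_single_fit_rejected(self):
        a = TwoStateResults(None, 0.5, 0.1, -1.0, "equal")
        with pytest.raises(ValueError, match=">= 2"):
            cp.select_model([a])


class TestPosteriors:
    @pytest.mark.parametrize("seed", range(5))
    def test_match_enumeration(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed + 50))
        for tree in random_trees(10, max_tips=5, min_tips=3, seed=seed + 9):
            pi1 = float(rng.uniform(0.1, 0.9))
            s = float(rng.uniform(0.005, 0.1))
            char = {lab: int(rng.integers(0, 2)) for lab in tree.tip_labels}
            fit = TwoStateResults(None, pi1, s, 0.0, "optimized")
            got = cp.marginal_posteriors(fit, tree, char)
            want = enumeration_posteriors(tree, pi1, s, char)
            for v, p in want.items():
                assert got[v] == pytest.approx(p, abs=1e-10)

    def test_symmetric_quartet_root_is_half(self):
        t = cp.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        fit = TwoStateResults(None, 0.5, 0.05, 0.0, "optimized")
        got = cp.marginal_posteriors(fit, t, {"A": 0, "B": 1, "C": 0, "D": 1})
        assert got[t.root] == pytest.approx(0.5, abs=1e-12)

    def test_all_zero_tips_pull_towards_zero(self):
        rng = np.random.Generator(np.random.PCG64(7))
        for tree in random_trees(5, max_tips=6, seed=13):
            pi1 = float(rng.uniform(0.2, 0.8))
            fit = TwoStateResults(None, pi1, 0.02, 0.0, "optimized")
            got = cp.marginal_posteriors(
                fit, tree, {lab: 0 for lab in tree.tip_labels})
            internal = [v for v in range(tree.n_nodes) if tree.children[v]]
            for v in internal:
                assert 1.0 - got[v] >= (1.0 - pi1) - 1e-12

    def test_posteriors_normalised_and_tips_observed(self, yule16):
        truth = TwoStateResults.__new__(TwoStateResults)
        truth.pi1, truth.pi0, truth.s = 0.3, 0.7, 0.002
        counts, _ = sim.sim_binary_histories(yule16, truth, 40, seed=21)
        mat = cp.encode_copy_number(counts)
        fit = TwoStateMarkovModel(yule16, mat).fit()
        post = fit.posteriors()
        assert ((post["p_state1"] >= -1e-12) &
                (post["p_state1"] <= 1 + 1e-12)).all()
        tips = post[post["is_observed_tip"]]
        assert set(tips["p_state1"].round(12).unique()) <= {0.0, 1.0}


class TestReliability:
    def make_post(self, p1, node_id=5, gene="g", tip=False):
        return pd.DataFrame({
            "gene": [gene], "node_id": [node_id], "p_state1": [p1],
            "assigned": [int(p1 >= 0.5)], "is_observed_tip": [tip],
        })

    def make_matrix(self, freq1, n=20):
        k = int(round(freq1 * n))
        data = {f"s{i}": [1 if i < k else 0] for i in range(n)}
        return BinaryCharacterMatrix(pd.DataFrame(data, index=["g"]))

    def test_rule_instantiation(self):
        # tip frequency of state 1 = 0.25; BPP 0.60 >= 0.25 -> reliable
        out = cp.filter_reliable(self.make_post(0.60), self.make_matrix(0.25))
        assert bool(out["reliable"].iloc[0])

    def test_majority_state_can_be_unreliable(self):
        # state 0 frequency 0.90; BPP 0.55 < 0.90 -> unreliable
        out = cp.filter_reliable(self.make_post(0.45), self.make_matrix(0.10))
        assert not bool(out["reliable"].iloc[0])

    def test_boundary_equality_is_reliable(self):
        # BPP exactly equals the observed state frequency ("greater or equal")
        out = cp.filter_reliable(self.make_post(0.75), self.make_matrix(0.75))
        assert bool(out["reliable"].iloc[0])


class TestEvents:
    def test_all_zero_gene_no_events(self, yule16):
        table = pd.DataFrame({lab: [0] for lab in yule16.tip_labels},
                             index=["g"])
        mat = BinaryCharacterMatrix(table)
        fit = TwoStateMarkovModel(yule16, mat, "equal")
        res = TwoStateResults(fit, 0.5, 0.001, 0.0, "equal")
        post = cp.filter_reliable(res.posteriors(), mat)
        ev = cp.count_events(post, yule16)
        assert ev["duplications"].sum() == 0 and ev["losses"].sum() == 0

    def test_singleton_duplication_on_pendant_branch(self, yule16):
        carrier = yule16.tip_labels[0]
        table = pd.DataFrame(
            {lab: [1 if lab == carrier else 0] for lab in yule16.tip_labels},
            index=["g"])
        mat = BinaryCharacterMatrix(table)
        fit = TwoStateMarkovModel(yule16, mat, "optimized")
        res = TwoStateResults(fit, 0.1, 0.002, 0.0, "optimized")
        post = cp.filter_reliable(res.posteriors(), mat)
        ev = cp.count_events(post, yule16).set_index("child_id")
        pendant = yule16.node_id(carrier)
        assert ev.loc[pendant, "duplications"] == 1
        assert ev["duplications"].sum() == 1

    def test_no_double_counting(self, yule16):
        truth = TwoStateResults.__new__(TwoStateResults)
        truth.pi1, truth.pi0, truth.s = 0.3, 0.7, 0.002
        counts, _ = sim.sim_binary_histories(yule16, truth, 60, seed=31)
        mat = cp.encode_copy_number(counts)
        fit = TwoStateMarkovModel(yule16, mat).fit()
        post = cp.filter_reliable(fit.posteriors(), mat)
        ev = cp.count_events(post, yule16)
        # recount transitions directly from the reliable argmax states
        piv_s = post.pivot(index="gene", columns="node_id", values="assigned")
        piv_r = post.pivot(index="gene", columns="node_id", values="reliable")
        tipset = set(int(i) for i in yule16.tip_ids)
        obs = post.pivot(index="gene", columns="node_id",
                         values="is_observed_tip")
        manual = 0
        for v in range(yule16.n_nodes):
            if v == yule16.root:
                continue
            p = int(yule16.parent[v])
            for g in piv_s.index:
                r_v = piv_r.loc[g, v] and (v not in tipset or obs.loc[g, v])
                r_p = piv_r.loc[g, p]
                if r_v and r_p and piv_s.loc[g, p] == 0 and piv_s.loc[g, v] == 1:
                    manual += 1
        assert int(ev["duplications"].sum()) == manual

    def test_requires_reliability_flags(self, yule16):
        table = pd.DataFrame({lab: [0] for lab in yule16.tip_labels},
                             index=["g"])
        mat = BinaryCharacterMatrix(table)
        fit = TwoStateMarkovModel(yule16, mat, "equal")
        res = TwoStateResults(fit, 0.5, 0.001, 0.0, "equal")
        with pytest.raises(ValueError, match="filter_reliable"):
            cp.count_events(res.posteriors(), yule16)


class TestRateTree:
    def test_arithmetic_and_round_trip(self, small_tree):
        counts = pd.DataFrame({
            "child_id": [1, 2, 3, 4],
            "duplications": [10, 0, 2, 4],
            "branch_my": [5.0, 1.0, 1.0, 2.0],
        })
        rt = cp.rate_tree(counts, small_tree)
        assert rt.branch_length[1] == pytest.approx(2.0)
        back = cp.parse_newick(rt.to_newick())
        assert back.labels == small_tree.labels

    def test_zero_events_zero_lengths(self, small_tree):
        counts = pd.DataFrame({
            "child_id": [1, 2, 3, 4],
            "duplications": [0, 0, 0, 0],
            "branch_my": [5.0, 1.0, 1.0, 2.0],
        })
        rt = cp.rate_tree(counts, small_tree)
        nonroot = np.arange(rt.n_nodes) != rt.root
        assert np.allclose(rt.branch_length[nonroot], 0.0)
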