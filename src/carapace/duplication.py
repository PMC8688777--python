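"""Ancestral reconstruction of gene duplications on a species tree.

Copy numbers are collapsed to a binary character per gene (0 = single copy,
1 = two or more copies; absence and unassessed cells are missing data) and
modelled with a two-state reversible continuous-time Markov chain with
stationary frequencies (pi0, pi1) and exchange rate s — the binary-trait
analogue of the GTR model for morphological characters, with frequencies
either fixed equal or optimized by maximum likelihood ("FO").

The chain's transition probabilities have the closed form

    P01(t) = pi1 * (1 - exp(-s t))      P00(t) = pi0 + pi1 * exp(-s t)
    P10(t) = pi0 * (1 - exp(-s t))      P11(t) = pi1 + pi0 * exp(-s t)

Likelihoods are computed by Felsenstein pruning vectorised across genes;
ancestral states are empirical-Bayes marginal posteriors (inside–outside
message passing with pi as the root prior).  A node reconstruction is kept
only when its posterior probability (BPP) is at least the observed tip
frequency of the assigned state for that gene; per-branch duplication (0→1)
and loss (1→0) events are counted from reliable argmax states at both
endpoints.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io import CopyNumberMatrix
from .trees import Phylogeny

__all__ = [
    "BinaryCharacterMatrix",
    "encode_copy_number",
    "TwoStateMarkovModel",
    "TwoStateResults",
    "select_model",
    "marginal_posteriors",
    "filter_reliable",
    "count_events",
    "rate_tree",
]

MISSING = -1


class BinaryCharacterMatrix:
    """Genes × species states in {0, 1, missing}."""

    def __init__(self, table: pd.DataFrame):
        self.table = table.astype("Int64")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)

    def states_for(self, species: list[str]) -> np.ndarray:
        """Integer array (n_genes, len(species)); missing encoded as -1."""
        sub = self.table.reindex(columns=species)
        return sub.fillna(MISSING).to_numpy(dtype=np.int64)

    def tip_state_frequencies(self) -> pd.DataFrame:
        """Per gene: observed frequency of each state among non-missing tips."""
        s = self.states_for(self.species)
        obs = s != MISSING
        n = obs.sum(axis=1)
        ones = ((s == 1) & obs).sum(axis=1)
        with np.errstate(invalid="ignore"):
            f1 = np.where(n > 0, ones / np.maximum(n, 1), np.nan)
        return pd.DataFrame({"gene": self.genes, "freq0": 1 - f1, "freq1": f1})


def encode_copy_number(counts: CopyNumberMatrix,
                       absence_as_state0: bool = False) -> BinaryCharacterMatrix:
    """Collapse copy counts to binary duplication characters.

    1 copy → state 0; ≥ 2 copies → state 1; 0 copies (gene absent) and
    unassessed cells → missing, unless ``absence_as_state0`` is set (then
    0 copies is treated as the single-copy state).
    """
    t = counts.table
    out = pd.DataFrame(index=t.index, columns=t.columns, dtype="Int64")
    out[t == 1] = 0
    out[t >= 2] = 1
    if absence_as_state0:
        out[t == 0] = 0
    return BinaryCharacterMatrix(out)


def _transition_matrix(pi1: float, s: float, t: float) -> np.ndarray:
    e = np.exp(-s * t)
    pi0 = 1.0 - pi1
    return np.array(
        [
            [pi0 + pi1 * e, pi1 * (1.0 - e)],
            [pi0 * (1.0 - e), pi1 + pi0 * e],
        ]
    )


class TwoStateResults:
    """Fitted two-state Markov duplication model."""

    def __init__(self, model, pi1, s, loglik, freq_mode):
        self.model = model
        self.pi1 = float(pi1)
        self.pi0 = 1.0 - self.pi1
        self.s = float(s)
        self.loglik = float(loglik)
        self.freq_mode = freq_mode
        self.k = 1 if freq_mode == "equal" else 2

    @property
    def Q(self) -> np.ndarray:
        """Rate matrix with rows summing to zero and pi Q = 0."""
        return np.array(
            [
                [-self.s * self.pi1, self.s * self.pi1],
                [self.s * self.pi0, -self.s * self.pi0],
            ]
        )

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    def transition_matrix(self, t: float) -> np.ndarray:
        return _transition_matrix(self.pi1, self.s, t)

    def posteriors(self) -> pd.DataFrame:
        """Marginal state posteriors for every gene at every node."""
        return self.model._posteriors(self)

    def summary(self) -> str:
        return "\n".join(
            [
                f"Two-state duplication model ({self.freq_mode} frequencies)",
                f"  genes: {len(self.model.matrix.genes)}, "
                f"tips: {self.model.tree.n_tips}",
                f"  pi = ({self.pi0:.4f}, {self.pi1:.4f}), s = {self.s:.6g} /My",
                f"  log-likelihood: {self.loglik:.4f}   AIC: {self.aic:.2f} "
                f"(k={self.k})",
            ]
        )


class TwoStateMarkovModel:
    """Joint ML fit of one two-state model across all gene characters."""

    def __init__(self, tree: Phylogeny, matrix: BinaryCharacterMatrix,
                 freq_mode: str = "optimized"):
        if freq_mode not in ("optimized", "equal"):
            raise ValueError("freq_mode must be 'optimized' or 'equal'")
        if not matrix.genes:
            raise ValueError("need at least one character")
        bl = tree.branch_length[np.arange(tree.n_nodes) != tree.root]
        if not np.any(bl > 0):
            raise ValueError("tree has no positive branch lengths")
        self.tree = tree
        self.matrix = matrix
        self.freq_mode = freq_mode
        missing_sp = set(matrix.species) - set(tree.tip_labels)
        if missing_sp:
            warnings.warn(
                f"species in matrix but not tree are ignored: {sorted(missing_sp)}",
                stacklevel=2,
            )
        self._states = matrix.states_for(tree.tip_labels)  # (n_genes, n_tips)
        self._tip_ids = tree.tip_ids

    # -- likelihood machinery (vectorised over genes) ----------------------

    def _tip_partials(self) -> np.ndarray:
        """(n_nodes, n_genes, 2) conditional likelihoods initialised at tips."""
        n_genes = self._states.shape[0]
        L = np.ones((self.tree.n_nodes, n_genes, 2))
        for k, tip in enumerate(self._tip_ids):
            st = self._states[:, k]
            L[tip, st == 0] = [1.0, 0.0]
            L[tip, st == 1] = [0.0, 1.0]
        return L

    def _upward(self, pi1: float, s: float):
        """Pruning pass; returns per-node partials, child messages, loglik."""
        tree = self.tree
        L = self._tip_partials()
        n_genes = L.shape[1]
        logscale = np.zeros(n_genes)
        msgs: dict[int, np.ndarray] = {}
        for v in tree.postorder():
            for c in tree.children[v]:
                P = _transition_matrix(pi1, s, tree.branch_length[c])
                msg = L[c] @ P.T  # msg[g, i] = sum_j P[i, j] L[c][g, j]
                msgs[c] = msg
                L[v] = L[v] * msg
            if tree.children[v]:
                scale = L[v].sum(axis=1)
                scale = np.where(scale > 0, scale, 1.0)
                L[v] /= scale[:, None]
                logscale += np.log(scale)
        pi = np.array([1.0 - pi1, pi1])
        root_lik = L[tree.root] @ pi
        loglik = float(np.sum(np.log(np.maximum(root_lik, 1e-300)) + logscale))
        return L, msgs, loglik

    def loglik(self, pi1: float, s: float) -> float:
        return self._upward(pi1, s)[2]

    def fit(self) -> TwoStateResults:
        """Maximise the summed pruning log-likelihood over (pi1, s)."""
        if self.freq_mode == "equal":
            x0 = np.array([np.log(0.1)])

            def neg(x):
                return -self.loglik(0.5, np.exp(x[0]))
        else:
            x0 = np.array([0.0, np.log(0.1)])

            def neg(x):
                pi1 = 1.0 / (1.0 + np.exp(-x[0]))
                return -self.loglik(pi1, np.exp(x[1]))

        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(-12, 12)] * x0.size)
        if not res.success and "ABNORMAL" in str(res.message):
            raise RuntimeError(f"two-state optimiser failed: {res.message}")
        if self.freq_mode == "equal":
            pi1, s = 0.5, float(np.exp(res.x[0]))
        else:
            pi1 = float(1.0 / (1.0 + np.exp(-res.x[0])))
            s = float(np.exp(res.x[1]))
        states = self._states[self._states != MISSING]
        if states.size and (states == states.flat[0]).all():
            warnings.warn(
                "all characters constant and identical: MLE lies on the "
                "boundary (s → 0)", stacklevel=2,
            )
        return TwoStateResults(self, pi1, s, -res.fun, self.freq_mode)

    def _posteriors(self, fit: TwoStateResults) -> pd.DataFrame:
        """Inside–outside marginal posteriors for all genes and nodes."""
        tree = self.tree
        L, msgs, _ = self._upward(fit.pi1, fit.s)
        n_genes = L.shape[1]
        pi = np.array([fit.pi0, fit.pi1])
        A = np.zeros_like(L)  # outside messages
        post = np.zeros_like(L)
        for v in tree.preorder():
            if v == tree.root:
                A[v] = pi
            else:
                p = tree.parent[v]
                B = A[p].copy()
                for sib in tree.children[p]:
                    if sib != v:
                        B *= msgs[sib]
                P = _transition_matrix(fit.pi1, fit.s, tree.branch_length[v])
                A[v] = B @ P
            pr = A[v] * L[v]
            tot = pr.sum(axis=1, keepdims=True)
            post[v] = pr / np.where(tot > 0, tot, 1.0)

        # observed tips are point masses by construction of L; assemble table
        rows = []
        genes = self.matrix.genes
        is_tip = tree.is_tip
        tip_index = {int(t): k for k, t in enumerate(self._tip_ids)}
        for v in range(tree.n_nodes):
            for g in range(n_genes):
                p1 = post[v, g, 1]
                observed = bool(
                    is_tip[v] and self._states[g, tip_index[v]] != MISSING
                )
                rows.append((genes[g], v, p1, int(p1 >= 0.5), observed))
        return pd.DataFrame(
            rows, columns=["gene", "node_id", "p_state1", "assigned", "is_observed_tip"]
        )


def select_model(fits: list[TwoStateResults]) -> tuple[TwoStateResults, pd.DataFrame]:
    """AIC model selection among fits of the same data.

    AIC = 2k − 2 lnL with k = 1 (equal frequencies) or 2 (optimized); the
    lowest AIC wins, ties broken toward fewer parameters.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 models to select among")
    first = fits[0].model
    for f in fits[1:]:
        if f.model.tree is not first.tree or f.model.matrix is not first.matrix:
            if not f.model.matrix.table.equals(first.matrix.table):
                raise ValueError("model fits are not on identical data")
    table = pd.DataFrame(
        {
            "freq_mode": [f.freq_mode for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
        }
    )
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].k))
    return fits[order[0]], table.iloc[order].reset_index(drop=True)


def marginal_posteriors(fit: TwoStateResults, tree: Phylogeny,
                        character: dict[str, int]) -> np.ndarray:
    """P(state = 1) at every node for a single gene character.

    ``character`` maps species → state in {0, 1}; unlisted tips are missing.
    """
    table = pd.DataFrame(
        {sp: [character.get(sp, pd.NA)] for sp in tree.tip_labels},
        index=["_char"],
    )
    model = TwoStateMarkovModel(tree, BinaryCharacterMatrix(table),
                                freq_mode=fit.freq_mode)
    res = TwoStateResults(model, fit.pi1, fit.s, 0.0, fit.freq_mode)
    df = model._posteriors(res)
    return df.sort_values("node_id")["p_state1"].to_numpy()


def filter_reliable(posteriors: pd.DataFrame,
                    matrix: BinaryCharacterMatrix) -> pd.DataFrame:
    """Flag reliable reconstructions.

    An internal-node reconstruction is reliable iff the posterior
    probability of its argmax state is at least that state's observed
    frequency among the gene's non-missing tips.  Observed tips are reliable
    point assignments; missing tips are unreliable.
    """
    freqs = matrix.tip_state_frequencies().set_index("gene")
    out = posteriors.copy()
    bpp = np.where(out["assigned"] == 1, out["p_state1"], 1.0 - out["p_state1"])
    thr = np.where(
        out["assigned"] == 1,
        freqs.loc[out["gene"], "freq1"].to_numpy(),
        freqs.loc[out["gene"], "freq0"].to_numpy(),
    )
    out["bpp"] = bpp
    out["reliable"] = (bpp >= thr) | out["is_observed_tip"]
    return out


def count_events(posteriors: pd.DataFrame, tree: Phylogeny) -> pd.DataFrame:
    """Per-branch duplication (0→1) and loss (1→0) counts.

    A gene contributes a duplication on branch b iff the parent's assigned
    state is 0, the child's is 1, and both reconstructions are reliable
    (tips count via their observed states; missing tips never count).
    Requires the ``reliable`` column from :func:`filter_reliable`.
    """
    if "reliable" not in posteriors.columns:
        raise ValueError("run filter_reliable() before count_events()")
    is_tip = tree.is_tip
    piv_state = posteriors.pivot(index="gene", columns="node_id", values="assigned")
    rel = posteriors.copy()
    # unobserved tips must not anchor events
    tip_missing = rel["node_id"].map(lambda v: bool(is_tip[v])) & ~rel[
        "is_observed_tip"
    ]
    rel.loc[tip_missing, "reliable"] = False
    piv_rel = rel.pivot(index="gene", columns="node_id", values="reliable")
    rows = []
    for v in tree.preorder():
        if v == tree.root:
            continue
        p = tree.parent[v]
        ok = piv_rel[v].astype(bool) & piv_rel[p].astype(bool)
        dup = int(((piv_state[p] == 0) & (piv_state[v] == 1) & ok).sum())
        loss = int(((piv_state[p] == 1) & (piv_state[v] == 0) & ok).sum())
        t = tree.branch_length[v]
        rows.append(
            {
                "child_id": int(v),
                "label": tree.labels[v] or "",
                "duplications": dup,
                "losses": loss,
                "branch_my": t,
                "dup_rate_per_my": dup / t if t > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def rate_tree(counts: pd.DataFrame, tree: Phylogeny) -> Phylogeny:
    """Tree whose branch lengths are duplication rates (events per My)."""
    rates = np.zeros(tree.n_nodes)
    zero_time = False
    for _, row in counts.iterrows():
        v = int(row["child_id"])
        if row["branch_my"] > 0:
            rates[v] = row["duplications"] / row["branch_my"]
        else:
            zero_time = True
            rates[v] = 0.0
    if zero_time:
        warnings.warn("zero-time branches assigned rate 0", stacklevel=2)
    return tree.with_branch_lengths(rates)
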