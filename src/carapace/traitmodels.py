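"""Continuous-trait evolution models on phylogenies.

Three statsmodels-style model classes:

* :class:`BrownianMotionASR` — maximum-likelihood Brownian-motion ancestral
  state reconstruction by two-pass (tip-to-root, root-to-tip) Gaussian
  message passing, equivalent to the GLS closed form.
* :class:`JumpDiffusionASR` — a heavy-tailed relaxation of Brownian motion in
  which per-branch increments are Student-t distributed with ``nu`` degrees
  of freedom, permitting rare large jumps; fitted by MCMC.  ``nu → ∞``
  recovers Brownian motion.
* :class:`PGLS` — phylogenetic generalized least squares with a Brownian
  covariance matrix (V[i, j] = shared path length from the root).

plus :func:`ancestral_lifespans` (PGLS regression surface evaluated at
reconstructed ancestral sizes, with Brownian-reconstructed residuals) and
:func:`branch_changes` (per-branch deltas, percent changes and rate
multipliers).

Traits enter on log2 scale; all branch lengths are in millions of years, so
the Brownian rate sigma2 is in squared log2-trait units per My.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import TraitTable
from .trees import Phylogeny

__all__ = [
    "BrownianMotionASR",
    "JumpDiffusionASR",
    "PGLS",
    "ContinuousASRResults",
    "PGLSResults",
    "ancestral_lifespans",
    "branch_changes",
    "mcse_median",
]


def mcse_median(samples: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Monte-Carlo standard error of the posterior median per column.

    Batch-means MCSE of the mean, inflated by sqrt(pi/2) (the Gaussian
    efficiency of the median relative to the mean), which accounts for the
    autocorrelation of Metropolis chains at the batch scale.
    """
    samples = np.atleast_2d(samples)
    n = samples.shape[0] // n_batches * n_batches
    if n < n_batches:
        raise ValueError("too few samples for batch-means MCSE")
    batches = samples[:n].reshape(n_batches, -1, samples.shape[1]).mean(axis=1)
    return batches.std(axis=0, ddof=1) / math.sqrt(n_batches) * math.sqrt(
        math.pi / 2.0
    )

_INF = float("inf")


def _tip_values(tree: Phylogeny, traits: TraitTable) -> np.ndarray:
    """Per-node array with trait values at tips and NaN at internal nodes."""
    vals = np.full(tree.n_nodes, np.nan)
    missing = []
    for i in tree.tip_ids:
        lab = tree.labels[i]
        if lab in traits.values:
            vals[i] = traits.values[lab]
        else:
            missing.append(lab)
    if missing:
        raise ValueError(f"tips missing trait values: {', '.join(sorted(missing))}")
    return vals


def _combine(messages):
    """Precision-weighted combination of (mean, var) Gaussian messages.

    var = 0 denotes a point mass, var = inf a flat message.
    """
    finite = [(m, v) for m, v in messages if v < _INF]
    for m, v in finite:
        if v == 0.0:
            return m, 0.0
    if not finite:
        return 0.0, _INF
    w = [1.0 / v for _, v in finite]
    W = sum(w)
    return sum(wi * mi for wi, (mi, _) in zip(w, finite)) / W, 1.0 / W


class ContinuousASRResults:
    """Ancestral reconstruction of a continuous trait.

    Attributes
    ----------
    estimates : ndarray, shape (n_nodes,)
        Point estimate per node (log2 trait units); tip entries equal the
        observed tip values exactly.
    variances : ndarray
        Conditional variance per node (BM; zero at tips), or posterior
        variance of the retained samples (jump model).
    sigma2 : float
        ML Brownian rate (BM) or posterior-median squared scale (jump).
    samples : ndarray or None
        Retained MCMC samples, shape (n_retained, n_nodes) (jump model only).
    """

    def __init__(self, model, tree, estimates, variances, sigma2, loglik=None,
                 samples=None, nu=None, scale=None):
        self.model = model
        self.tree = tree
        self.estimates = estimates
        self.variances = variances
        self.sigma2 = sigma2
        self.loglik = loglik
        self.samples = samples
        self.nu = nu
        self.scale = scale

    @property
    def model_tag(self) -> str:
        return "bm" if self.samples is None else "jump"

    def to_frame(self) -> pd.DataFrame:
        t = self.tree
        return pd.DataFrame(
            {
                "node_id": np.arange(t.n_nodes),
                "label": [lab or "" for lab in t.labels],
                "estimate": self.estimates,
                "variance": self.variances,
                "is_tip": t.is_tip,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Continuous-trait ASR ({self.model_tag})",
            f"  nodes: {self.tree.n_nodes} ({self.tree.n_tips} tips)",
            f"  sigma2: {self.sigma2:.6g} (log2-units^2 per My)",
        ]
        if self.loglik is not None:
            lines.append(f"  log-likelihood: {self.loglik:.4f}")
        if self.samples is not None:
            lines.append(f"  retained samples: {self.samples.shape[0]} (nu={self.nu})")
        lines.append(f"  root estimate: {self.estimates[self.tree.root]:.4f}")
        return "\n".join(lines)


class BrownianMotionASR:
    """ML Brownian-motion ancestral reconstruction of a log2-scale trait."""

    def __init__(self, tree: Phylogeny, traits: TraitTable):
        if traits.scale != "log2":
            raise ValueError("traits must be on log2 scale (use TraitTable.to_log2())")
        self.tree = tree
        self.traits = traits
        self._x = _tip_values(tree, traits)
        bl = tree.branch_length[np.arange(tree.n_nodes) != tree.root]
        if not np.any(bl > 0):
            raise ValueError("all branch lengths are zero; BM rate is unidentifiable")

    def fit(self) -> ContinuousASRResults:
        tree = self.tree
        n = tree.n_nodes
        n_tips = tree.n_tips
        up_m = np.zeros(n)
        up_v = np.zeros(n)  # in units of t (sigma2 factored out)
        Q = 0.0  # quadratic form (x - mu)' C^-1 (x - mu) at sigma2 = 1
        logdet = 0.0  # sum over contrasts of log(V_i), plus log v_root

        for v in tree.postorder():
            if not tree.children[v]:
                up_m[v], up_v[v] = self._x[v], 0.0
                continue
            msgs = [
                (up_m[c], up_v[c] + tree.branch_length[c]) for c in tree.children[v]
            ]
            # fold children in pairwise, accumulating independent contrasts
            m, var = msgs[0]
            for m2, v2 in msgs[1:]:
                V = var + v2
                if V > 0:
                    Q += (m - m2) ** 2 / V
                    logdet += math.log(V)
                    m, var = _combine([(m, var), (m2, v2)])
                else:
                    if m != m2:
                        raise ValueError(
                            "zero-length cherry with conflicting tip values"
                        )
                    # point mass; no contrast information
            up_m[v], up_v[v] = m, var
        root_v = up_v[tree.root]
        if root_v > 0:
            logdet += math.log(root_v)
        sigma2 = Q / n_tips

        # downward pass: message from above each node, then marginal combine
        down_m = np.zeros(n)
        down_v = np.zeros(n)
        est = np.zeros(n)
        var_t = np.zeros(n)  # marginal variance in units of t
        for v in tree.preorder():
            if v == tree.root:
                down_m[v], down_v[v] = 0.0, _INF
            else:
                p = tree.parent[v]
                sibs = [
                    (up_m[c], up_v[c] + tree.branch_length[c])
                    for c in tree.children[p]
                    if c != v
                ]
                am, av = _combine(sibs + [(down_m[p], down_v[p])])
                down_m[v], down_v[v] = am, av + tree.branch_length[v]
            m, var = _combine([(up_m[v], up_v[v]), (down_m[v], down_v[v])])
            est[v], var_t[v] = m, var

        est[tree.tip_ids] = self._x[tree.tip_ids]  # exact by construction
        variances = sigma2 * var_t
        if sigma2 == 0.0:
            loglik = _INF if n_tips > 1 else 0.0  # degenerate constant trait
        else:
            loglik = -0.5 * (
                n_tips * math.log(2 * math.pi * sigma2) + logdet + n_tips
            )
        return ContinuousASRResults(
            self, tree, est, variances, sigma2, loglik=loglik
        )


class JumpDiffusionASR:
    """Heavy-tailed trait-evolution model permitting large jumps.

    Per-branch increments are Student-t with ``nu`` degrees of freedom and
    scale ``c * sqrt(t_b)``; small ``nu`` (default 2) gives heavy tails so a
    single branch can absorb a large trait jump without inflating the global
    rate.  Ancestral node states and the scale ``c`` are sampled by
    random-walk Metropolis MCMC (flat priors on states, Jeffreys prior on
    ``c``); proposal scales adapt during burn-in only, thinning is fixed
    at 10.
    """

    THIN = 10

    def __init__(self, tree: Phylogeny, traits: TraitTable, nu: float = 2.0):
        if nu <= 0:
            raise ValueError("nu must be > 0")
        self.tree = tree
        self.traits = traits
        self.nu = float(nu)
        self._x = _tip_values(tree, traits)
        bl = np.where(
            np.arange(tree.n_nodes) == tree.root, np.nan, tree.branch_length
        )
        if np.nanmin(bl) <= 0:
            warnings.warn(
                "zero-length branches replaced by 1e-8 My for the jump model",
                stacklevel=2,
            )
        self._t = np.maximum(np.nan_to_num(bl, nan=1.0), 1e-8)

    def fit(self, iterations: int = 6000, burn_in: int = 2000,
            seed: int = 0) -> ContinuousASRResults:
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        tree, nu = self.tree, self.nu
        rng = np.random.Generator(np.random.PCG64(seed))
        internal = [int(v) for v in tree.preorder() if tree.children[v]]
        sqrt_t = np.sqrt(self._t)

        # initialise at the BM solution
        bm = BrownianMotionASR(tree, self.traits).fit()
        z = bm.estimates.copy()
        c = math.sqrt(bm.sigma2) if bm.sigma2 > 0 else 1e-3
        log_c = math.log(c)

        def inc_logpdf_sum(deltas_over_s):
            # Student-t log density up to constants shared across states
            return -0.5 * (nu + 1.0) * np.sum(np.log1p(deltas_over_s**2 / nu))

        def local_logp(v, zv, c):
            """log target terms involving node v's state."""
            s = 0.0
            if v != tree.root:
                d = (zv - z[tree.parent[v]]) / (c * sqrt_t[v])
                s += -0.5 * (nu + 1.0) * math.log1p(d * d / nu)
            for ch in tree.children[v]:
                d = (z[ch] - zv) / (c * sqrt_t[ch])
                s += -0.5 * (nu + 1.0) * math.log1p(d * d / nu)
            return s

        def full_logp(c):
            """all increment terms + scale normalisation + Jeffreys prior."""
            nonroot = np.flatnonzero(tree.parent >= 0)
            d = (z[nonroot] - z[tree.parent[nonroot]]) / (c * sqrt_t[nonroot])
            return (
                inc_logpdf_sum(d)
                - nonroot.size * math.log(c)
                - math.log(c)  # Jeffreys
            )

        step = {v: math.sqrt(max(bm.variances[v], bm.sigma2, 1e-6)) for v in internal}
        step_c = 0.3
        acc = {v: 0 for v in internal}
        acc_c = 0

        # subtree-translation move: shifting every internal node of a subtree
        # by delta changes only the stem increment and the edges from moved
        # nodes to their (fixed) tip children — it lets a planted jump
        # relocate onto a stem branch in one proposal instead of node by node
        nonroot_internal = [v for v in internal if v != tree.root]
        sub_nodes: dict[int, list[int]] = {}
        sub_tip_edges: dict[int, list[int]] = {}
        for v in nonroot_internal:
            moved = []
            stack = [v]
            while stack:
                u = stack.pop()
                if tree.children[u]:
                    moved.append(u)
                    stack.extend(tree.children[u])
            sub_nodes[v] = moved
            sub_tip_edges[v] = [
                c for u in moved for c in tree.children[u] if not tree.children[c]
            ]
        step_sub = {v: step[v] for v in nonroot_internal}
        acc_sub = {v: 0 for v in nonroot_internal}

        def edge_logp(child, child_val, parent_val, c):
            d = (child_val - parent_val) / (c * sqrt_t[child])
            return -0.5 * (nu + 1.0) * math.log1p(d * d / nu)
        n_retained = (iterations - burn_in) // self.THIN
        samples = np.empty((n_retained, tree.n_nodes))
        c_samples = np.empty(n_retained)
        k = 0
        ADAPT_BLOCK = 50

        for it in range(iterations):
            for v in internal:
                prop = z[v] + step[v] * rng.standard_normal()
                cur = local_logp(v, z[v], c)
                new = local_logp(v, prop, c)
                if math.log(rng.random()) < new - cur:
                    z[v] = prop
                    acc[v] += 1
            for v in nonroot_internal:
                delta = step_sub[v] * rng.standard_normal()
                cur = edge_logp(v, z[v], z[tree.parent[v]], c)
                new = edge_logp(v, z[v] + delta, z[tree.parent[v]], c)
                for tip in sub_tip_edges[v]:
                    cur += edge_logp(tip, z[tip], z[tree.parent[tip]], c)
                    new += edge_logp(tip, z[tip], z[tree.parent[tip]] + delta, c)
                if math.log(rng.random()) < new - cur:
                    for u in sub_nodes[v]:
                        z[u] += delta
                    acc_sub[v] += 1
            # scale update on log c
            prop_lc = log_c + step_c * rng.standard_normal()
            cur = full_logp(math.exp(log_c)) + log_c  # + log|Jacobian|
            new = full_logp(math.exp(prop_lc)) + prop_lc
            if math.log(rng.random()) < new - cur:
                log_c = prop_lc
                acc_c += 1
            c = math.exp(log_c)
            # adapt during burn-in only
            if it < burn_in and (it + 1) % ADAPT_BLOCK == 0:
                for v in internal:
                    rate = acc[v] / ADAPT_BLOCK
                    step[v] *= math.exp(0.5 * (rate - 0.44))
                    acc[v] = 0
                for v in nonroot_internal:
                    rate = acc_sub[v] / ADAPT_BLOCK
                    step_sub[v] *= math.exp(0.5 * (rate - 0.25))
                    acc_sub[v] = 0
                step_c *= math.exp(0.5 * (acc_c / ADAPT_BLOCK - 0.44))
                acc_c = 0
            if it >= burn_in and (it - burn_in) % self.THIN == 0 and k < n_retained:
                samples[k] = z
                c_samples[k] = c
                k += 1

        est = np.median(samples, axis=0)
        est[tree.tip_ids] = self._x[tree.tip_ids]
        variances = np.var(samples, axis=0, ddof=1) if n_retained > 1 else np.zeros(
            tree.n_nodes
        )
        self._check_convergence(samples[:, tree.root])
        c_med = float(np.median(c_samples))
        sigma2 = c_med**2 * (nu / (nu - 2.0)) if nu > 2 else c_med**2
        res = ContinuousASRResults(
            self, tree, est, variances, sigma2,
            samples=samples, nu=nu, scale=c_med,
        )
        res.c_samples = c_samples
        return res

    @staticmethod
    def _check_convergence(chain: np.ndarray, threshold: float = 1.2) -> None:
        """Split-chain potential scale reduction on the root state."""
        m = chain.size // 2
        if m < 10:
            return
        halves = chain[: 2 * m].reshape(2, m)
        W = halves.var(axis=1, ddof=1).mean()
        B = m * halves.mean(axis=1).var(ddof=1)
        if W <= 0:
            return
        rhat = math.sqrt(((m - 1) / m * W + B / m) / W)
        if rhat > threshold:
            warnings.warn(
                f"jump-model MCMC may not have converged (split R-hat {rhat:.2f})",
                stacklevel=2,
            )


class PGLSResults:
    """Fitted phylogenetic regression y = beta0 + beta * x + phylo residual."""

    def __init__(self, model, intercept, slope, sigma2_resid, residuals,
                 fitted, cov_params, species):
        self.model = model
        self.intercept = float(intercept)
        self.slope = float(slope)
        self.sigma2_resid = float(sigma2_resid)
        self.residuals = residuals
        self.fitted = fitted
        self.cov_params = cov_params
        self.species = species
        self.method = "ML"

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        se = np.sqrt(np.diag(self.cov_params))
        return "\n".join(
            [
                "PGLS (Brownian covariance, ML scale)",
                f"  n tips: {len(self.species)}",
                f"  intercept: {self.intercept:.6g} (SE {se[0]:.3g})",
                f"  slope:     {self.slope:.6g} (SE {se[1]:.3g})",
                f"  sigma2_resid: {self.sigma2_resid:.6g}",
            ]
        )


class PGLS:
    """Phylogenetic generalized least squares under Brownian covariance."""

    def __init__(self, tree: Phylogeny, x: TraitTable, y: TraitTable):
        common = [lab for lab in tree.tip_labels
                  if lab in x.values and lab in y.values]
        if set(common) != set(tree.tip_labels):
            raise ValueError("x and y must be observed for every tip in the tree")
        if len(common) < 3:
            raise ValueError(f"n < 3: PGLS needs at least 3 tips, got {len(common)}")
        self.tree = tree
        self.species = common
        self.x = x.array_for(common)
        self.y = y.array_for(common)

    @classmethod
    def from_dataframe(cls, tree: Phylogeny, df: pd.DataFrame,
                       x: str, y: str, species_col: str = "species") -> "PGLS":
        xt = TraitTable(dict(zip(df[species_col], df[x])), trait=x, scale="log2")
        yt = TraitTable(dict(zip(df[species_col], df[y])), trait=y, scale="log2")
        return cls(tree, xt, yt)

    def fit(self) -> PGLSResults:
        V = self.tree.shared_path_matrix(self.species)
        X = sm.add_constant(self.x, has_constant="add")
        try:
            gls = sm.GLS(self.y, X, sigma=V).fit()
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular Brownian covariance (duplicate zero-length tips?); "
                "consider jittering branch lengths"
            ) from exc
        resid = self.y - gls.fittedvalues
        n = len(self.y)
        Vi_r = np.linalg.solve(V, resid)
        sigma2 = float(resid @ Vi_r) / n
        cov = gls.normalized_cov_params * sigma2
        return PGLSResults(
            self, gls.params[0], gls.params[1], sigma2, resid,
            np.asarray(gls.fittedvalues), cov, self.species,
        )


def ancestral_lifespans(tree: Phylogeny, pgls: PGLSResults,
                        size_asr: ContinuousASRResults,
                        method: str = "fitted_plus_residual") -> pd.DataFrame:
    """Ancestral log2 lifespans from the PGLS surface at reconstructed sizes.

    Default rule: node lifespan = PGLS fitted value at the node's
    reconstructed size plus the Brownian reconstruction of the tip residuals
    at that node, so tip values reproduce the observed lifespans exactly.
    ``method='fitted_only'`` drops the residual term.
    """
    if size_asr.tree is not tree and size_asr.tree.n_nodes != tree.n_nodes:
        raise ValueError("size ASR node set does not match the tree")
    if method not in ("fitted_plus_residual", "fitted_only"):
        raise ValueError(f"unknown method {method!r}")
    fitted = pgls.intercept + pgls.slope * size_asr.estimates
    if method == "fitted_only":
        resid_est = np.zeros(tree.n_nodes)
    else:
        resid_table = TraitTable(
            dict(zip(pgls.species, pgls.residuals)),
            trait="pgls_residual", scale="log2",
        )
        if np.allclose(pgls.residuals, 0.0):
            resid_est = np.zeros(tree.n_nodes)
        else:
            resid_est = BrownianMotionASR(tree, resid_table).fit().estimates
    est = fitted + resid_est
    return pd.DataFrame(
        {
            "node_id": np.arange(tree.n_nodes),
            "label": [lab or "" for lab in tree.labels],
            "log2_lifespan": est,
            "is_tip": tree.is_tip,
        }
    )


def branch_changes(tree: Phylogeny, asr: ContinuousASRResults) -> pd.DataFrame:
    """Per-branch trait deltas, percent changes and rate multipliers.

    delta is child minus parent estimate in log2 units; percent change is
    100 * (2**delta - 1) on the linear scale; the rate multiplier
    r_b = (delta^2 / t_b) / sigma2 expresses how much faster than the global
    rate the branch would have had to evolve to produce its delta.
    """
    rows = []
    sigma2 = asr.sigma2
    if sigma2 <= 0:
        warnings.warn("sigma2 = 0: rate multipliers undefined, reported as NaN",
                      stacklevel=2)
    for v in tree.preorder():
        if v == tree.root:
            continue
        delta = asr.estimates[v] - asr.estimates[tree.parent[v]]
        t = tree.branch_length[v]
        pct = 100.0 * (2.0**delta - 1.0)
        if sigma2 <= 0:
            r = math.nan
        elif t > 0:
            r = (delta**2 / t) / sigma2
        elif delta == 0.0:
            r = 0.0
        else:
            warnings.warn(
                f"zero-length branch above node {v} with nonzero delta; "
                "rate multiplier reported as +inf",
                stacklevel=2,
            )
            r = _INF
        rows.append(
            {
                "child_id": int(v),
                "label": tree.labels[v] or "",
                "delta_log2": delta,
                "percent_change": pct,
                "rate_multiplier": r,
                "branch_my": t,
            }
        )
    return pd.DataFrame(rows)
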