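"""Synthetic data with known ground truth for every pipeline stage.

Generators emulate the study's data shapes: a time-calibrated Yule
phylogeny (default root age 210 My, the approximate crown-turtle depth),
Brownian body-size evolution with optional planted jumps on designated
branches, lifespans linear in log2 size with Brownian phylogenetic
residuals, binary duplication histories under the two-state Markov model
(with every true 0→1 event recorded per branch), annotation universes with
planted foreground enrichment, and 96-well kinetic luminescence series with
Hill-type dose-dependent apoptotic amplitude, logistic onset kinetics,
multiplicative lognormal noise and a no-cell background column.

Every generator is reproducible bit-for-bit from (parameters, seed).
"""

from __future__ import annotations

import dataclasses

import dendropy
import numpy as np
import pandas as pd

from .assay import CHANNELS, TIME_GRID, KineticSeries, PlateSpec
from .duplication import TwoStateResults
from .enrichment import GeneSetCollection
from .io import CopyNumberMatrix, TraitTable
from .trees import Phylogeny, parse_newick

__all__ = [
    "SimulationTruth",
    "sim_tree",
    "sim_traits",
    "sim_lifespans",
    "sim_binary_histories",
    "sim_annotations",
    "sim_plate",
    "pick_plantable_branch",
    "planted_jump_scenario",
    "giant_lineage_scenario",
]

DEFAULT_ROOT_AGE = 210.0  # My


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth accompanying a generated dataset."""

    seed: int
    node_values: np.ndarray | None = None
    jump_branches: dict | None = None
    events: pd.DataFrame | None = None
    planted_terms: dict | None = None
    effects: dict | None = None
    params: dict | None = None


def sim_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0,
             root_age: float = DEFAULT_ROOT_AGE) -> Phylogeny:
    """Yule (pure-birth) tree rescaled so the root sits at ``root_age`` My."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.Generator(np.random.PCG64(seed))
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=_DendropyRng(rng),
    )
    # the simulator stops at the instant of the nth birth; append the final
    # Yule waiting interval so pendant branches have positive length
    extra = rng.exponential(1.0 / (n_tips * birth_rate))
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:03d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree = parse_newick(dtree.as_string(schema="newick").strip())
    depth = tree.depths()[tree.tip_ids].max()
    scaled = tree.branch_length * (root_age / depth)
    return tree.with_branch_lengths(scaled)


class _DendropyRng:
    """Adapter exposing the stdlib-random surface dendropy needs, backed by
    a numpy Generator so tree simulation shares the package's seeding."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def uniform(self, a, b):
        return a + (b - a) * self._rng.random()

    def random(self):
        return self._rng.random()

    def expovariate(self, lambd):
        return self._rng.exponential(1.0 / lambd)

    def sample(self, population, k):
        population = list(population)
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        seq = list(seq)
        return seq[int(self._rng.integers(0, len(seq)))]

    def shuffle(self, x):
        self._rng.shuffle(x)

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def gauss(self, mu, sigma):
        return mu + sigma * self._rng.standard_normal()


def sim_traits(tree: Phylogeny, sigma2: float, jumps=None, seed: int = 0,
               root_value: float = 0.0,
               trait: str = "log2_size") -> tuple[TraitTable, SimulationTruth]:
    """Brownian trait evolution with optional planted jumps.

    ``jumps`` is a list of (branch_child_id, offset) pairs added to the
    Gaussian increment on those branches.  Values are on log2 scale with
    root at ``root_value``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    jumps = dict(jumps or [])
    for b in jumps:
        if not 0 <= b < tree.n_nodes or b == tree.root:
            raise ValueError(f"jump branch {b} not a non-root node of the tree")
    rng = np.random.Generator(np.random.PCG64(seed))
    vals = np.zeros(tree.n_nodes)
    vals[tree.root] = root_value
    for v in tree.preorder():
        if v == tree.root:
            continue
        t = tree.branch_length[v]
        inc = rng.normal(0.0, np.sqrt(sigma2 * t)) if sigma2 > 0 else 0.0
        vals[v] = vals[tree.parent[v]] + inc + jumps.get(v, 0.0)
    table = TraitTable(
        {tree.labels[i]: float(vals[i]) for i in tree.tip_ids},
        trait=trait, scale="log2",
    )
    truth = SimulationTruth(
        seed=seed, node_values=vals, jump_branches=jumps,
        params={"sigma2": sigma2, "root_value": root_value},
    )
    return table, truth


def pick_plantable_branch(tree: Phylogeny, min_length: float = 20.0) -> int:
    """A branch on which a planted jump is statistically identifiable.

    Candidates are internal stem branches that are not children of the root
    (with a flat root prior, a jump on a root-child stem is indistinguishable
    from an opposite jump on its sibling) and subtend between 3 tips and half
    the tree.  Among those, prefer branches of at least ``min_length`` My —
    near-zero-duration branches make any increment model place the change on
    a longer neighbour — falling back to the longest candidate.
    """
    base = [
        int(v)
        for v in tree.preorder()
        if v != tree.root
        and tree.parent[v] != tree.root
        and tree.children[v]
        and 3 <= len(tree.tips_below(v)) <= max(tree.n_tips // 2, 3)
    ]
    if not base:
        raise ValueError("tree has no suitable internal branch for planting")
    long_enough = [v for v in base if tree.branch_length[v] >= min_length]
    if long_enough:
        return long_enough[0]
    return max(base, key=lambda v: tree.branch_length[v])


def planted_jump_scenario(n_tips: int = 16, sigma2: float = 0.01,
                          jump_sd_multiple: float = 8.0, seed: int = 0,
                          root_age: float = DEFAULT_ROOT_AGE):
    """Brownian trait data with one large jump on a known internal branch.

    The jump magnitude is ``jump_sd_multiple`` times the root-to-tip
    Brownian standard deviation sqrt(sigma2 * root_age) — the scale on which
    a jump stands clear of the background drift accumulated across the whole
    tree depth.  Returns (tree, branch_id, trait_table, truth).
    """
    tree = sim_tree(n_tips, seed=seed, root_age=root_age)
    branch = pick_plantable_branch(tree)
    jump = jump_sd_multiple * np.sqrt(sigma2 * root_age)
    traits, truth = sim_traits(tree, sigma2, jumps=[(branch, jump)],
                               seed=seed + 1)
    return tree, branch, traits, truth


def giant_lineage_scenario(n_tips: int = 16, seed: int = 0,
                           size_jump_log2: float = 2.0,
                           lifespan_jump_log2: float = 1.0,
                           sigma2_size: float = 0.0005,
                           resid_sigma2: float = 1e-4,
                           beta: float = 0.3, intercept: float = 3.0,
                           root_size_mm: float = 300.0):
    """A clade evolving giant size and long lifespan on a known stem branch.

    Tips below the chosen stem carry +``size_jump_log2`` log2 size and
    +``lifespan_jump_log2`` log2 lifespan (total, including the allometric
    share beta × size jump) over a quiet Brownian background, emulating a
    Galapagos-tortoise-like lineage.  The stem is chosen to dominate its
    child branches in duration so the attribution of the change is
    identifiable.  Returns (tree, branch_id, size_table, lifespan_table)
    with both tables on linear scale.
    """
    tree = sim_tree(n_tips, seed=seed)
    base = [
        int(v) for v in tree.preorder()
        if v != tree.root and tree.parent[v] != tree.root
        and tree.children[v]
        and 3 <= len(tree.tips_below(v)) <= max(tree.n_tips // 2, 3)
    ]
    if not base:
        raise ValueError("no plantable stem branch")

    def ratio(v):
        return tree.branch_length[v] / max(
            tree.branch_length[c] for c in tree.children[v]
        )

    good = [v for v in base if ratio(v) >= 1.2 and tree.branch_length[v] >= 20]
    branch = good[0] if good else max(base, key=ratio)
    size, _ = sim_traits(tree, sigma2_size, jumps=[(branch, size_jump_log2)],
                         seed=seed + 1, root_value=float(np.log2(root_size_mm)))
    life, _ = sim_lifespans(tree, size, beta=beta, intercept=intercept,
                            resid_sigma2=resid_sigma2, seed=seed + 2)
    extra = lifespan_jump_log2 - beta * size_jump_log2
    below = set(tree.tips_below(branch))
    life_vals = {
        sp: v + (extra if sp in below else 0.0) for sp, v in life.values.items()
    }
    size_linear = TraitTable(
        {sp: float(2.0**v) for sp, v in size.values.items()},
        trait="carapace_mm", scale="linear", units="mm",
    )
    life_linear = TraitTable(
        {sp: float(2.0**v) for sp, v in life_vals.items()},
        trait="lifespan_yr", scale="linear", units="years",
    )
    return tree, branch, size_linear, life_linear


def sim_lifespans(tree: Phylogeny, size_table: TraitTable, beta: float,
                  intercept: float, resid_sigma2: float,
                  seed: int = 0) -> tuple[TraitTable, SimulationTruth]:
    """log2 lifespan = intercept + beta · log2 size + Brownian residual."""
    size = size_table.to_log2()
    resid_table, resid_truth = sim_traits(
        tree, resid_sigma2, seed=seed, trait="residual"
    )
    values = {
        sp: intercept + beta * size.values[sp] + resid_table.values[sp]
        for sp in size.values
    }
    table = TraitTable(values, trait="log2_lifespan", scale="log2")
    truth = SimulationTruth(
        seed=seed,
        node_values=resid_truth.node_values,
        params={"beta": beta, "intercept": intercept,
                "resid_sigma2": resid_sigma2},
    )
    return table, truth


def sim_binary_histories(tree: Phylogeny, model: TwoStateResults, n_genes: int,
                         seed: int = 0) -> tuple[CopyNumberMatrix, SimulationTruth]:
    """Simulate two-state histories gene by gene, recording true events.

    State paths evolve branch-by-branch with exponential waiting times
    (rate s·pi1 out of state 0, s·pi0 out of state 1); every realised 0→1
    transition is logged with its branch.  Emitted copy counts are 1 for
    state 0 and 2 for state 1.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    rates = {0: model.s * model.pi1, 1: model.s * model.pi0}
    events = []
    counts = np.zeros((n_genes, tree.n_tips), dtype=np.int64)
    tip_col = {int(t): k for k, t in enumerate(tree.tip_ids)}
    order = tree.preorder()
    for g in range(n_genes):
        state = np.zeros(tree.n_nodes, dtype=np.int64)
        state[tree.root] = int(rng.random() < model.pi1)
        for v in order:
            if v == tree.root:
                continue
            s = state[tree.parent[v]]
            remaining = tree.branch_length[v]
            while True:
                rate = rates[s]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait >= remaining:
                    break
                remaining -= wait
                s = 1 - s
                if s == 1:
                    events.append({"gene": f"g{g + 1}", "child_id": int(v),
                                   "event": "duplication"})
                else:
                    events.append({"gene": f"g{g + 1}", "child_id": int(v),
                                   "event": "loss"})
            state[v] = s
        for t, k in tip_col.items():
            counts[g, k] = 1 + state[t]
    table = pd.DataFrame(
        counts, index=[f"g{g + 1}" for g in range(n_genes)],
        columns=[tree.labels[t] for t in tree.tip_ids],
    )
    truth = SimulationTruth(
        seed=seed,
        events=pd.DataFrame(events, columns=["gene", "child_id", "event"]),
        params={"pi1": model.pi1, "s": model.s, "n_genes": n_genes},
    )
    return CopyNumberMatrix(table), truth


def sim_annotations(universe_size: int, n_terms: int, term_size: int,
                    n_foreground: int, planted=None, labelled_frac: float = 0.2,
                    seed: int = 0) -> tuple[GeneSetCollection, set, SimulationTruth]:
    """Annotation universe with optionally planted foreground enrichment.

    Terms are uniform draws from the universe; the foreground is a uniform
    draw except each planted (term, excess) receives ``excess`` extra
    members from that term.  A ``labelled_frac`` share of terms carries the
    cancer/aging label (planted terms first).
    """
    planted = dict(planted or {})
    rng = np.random.Generator(np.random.PCG64(seed))
    genes = [f"gene{i + 1}" for i in range(universe_size)]
    universe = set(genes)
    terms = {}
    for t in range(n_terms):
        members = rng.choice(universe_size, size=term_size, replace=False)
        terms[f"term{t + 1}"] = {genes[i] for i in members}
    fg_idx = rng.choice(universe_size, size=n_foreground, replace=False)
    foreground = {genes[i] for i in fg_idx}
    for term, excess in planted.items():
        pool = sorted(terms[term] - foreground)
        take = min(excess, len(pool))
        extra = rng.choice(len(pool), size=take, replace=False)
        foreground |= {pool[i] for i in extra}
    n_label = max(int(round(labelled_frac * n_terms)), len(planted))
    labelled = list(planted) + [
        t for t in terms if t not in planted
    ][: max(0, n_label - len(planted))]
    labels = {t: t in labelled for t in terms}
    truth = SimulationTruth(
        seed=seed, planted_terms=planted,
        params={"universe_size": universe_size, "n_terms": n_terms,
                "term_size": term_size, "n_foreground": n_foreground},
    )
    return GeneSetCollection(terms, labels, universe), foreground, truth


def _hill(c: float, emax: float, ec50: float, h: float) -> float:
    if c <= 0:
        return 0.0
    return emax * c**h / (ec50**h + c**h)


def _onset(t: np.ndarray, onset_h: float, rate: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rate * (t - onset_h)))


def sim_plate(plate: PlateSpec, effects: dict, baseline: float = 100.0,
              noise_cv: float = 0.05, onset_h: float = 8.0,
              onset_rate: float = 0.4,
              seed: int = 0) -> tuple[dict[str, KineticSeries], SimulationTruth]:
    """Kinetic luminescence series for a plate.

    ``effects`` maps (species, drug) → dict(emax=..., ec50=..., hill=...).
    Treatment wells follow baseline + Hill(dose) · logistic(t) with
    multiplicative lognormal noise (CV = ``noise_cv``); vehicle and no-cell
    wells are baseline + noise.  The fluorescence (necrosis) channel is
    emitted at baseline as a pass-through.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    sigma = np.sqrt(np.log1p(noise_cv**2))
    out = {}
    effects_used = {}
    for ch in CHANNELS:
        cols = {}
        for _, w in plate.wells.iterrows():
            mean = np.full(TIME_GRID.size, baseline)
            if (
                ch == "luminescence"
                and w["role"] == "treatment"
                and (w["species"], w["drug"]) in effects
            ):
                e = effects[(w["species"], w["drug"])]
                amp = _hill(w["final_uM"], e["emax"], e["ec50"],
                            e.get("hill", 1.0))
                mean = baseline + amp * _onset(TIME_GRID, onset_h, onset_rate)
                effects_used[(w["species"], w["drug"])] = e
            if noise_cv > 0:
                noise = np.exp(
                    rng.normal(-0.5 * sigma**2, sigma, size=TIME_GRID.size)
                )
            else:
                noise = 1.0
            cols[w["well"]] = mean * noise
        out[ch] = KineticSeries(
            pd.DataFrame(cols, index=pd.Index(TIME_GRID, name="time_h")), ch
        )
    truth = SimulationTruth(
        seed=seed,
        effects={f"{sp}|{dr}": e for (sp, dr), e in effects_used.items()},
        params={"baseline": baseline, "noise_cv": noise_cv,
                "onset_h": onset_h, "onset_rate": onset_rate},
    )
    return out, truth
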