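"""Over-representation analysis of duplicated-gene sets.

Given a foreground gene set (duplicates on a lineage) and an annotation
collection with a background universe, each term is tested for
over-representation with an upper-tail hypergeometric test (Enrichr-style)
or an upper-tail binomial test (Panther-style).  "Enriched" means raw
p <= alpha (default 0.05); Benjamini–Hochberg adjusted values are always
reported alongside.  Lineage-level comparisons of the proportion of
cancer/aging-labelled enriched terms use a two-sided permutation test on
group means, exact (full enumeration of label partitions) whenever feasible.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("carapace")

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeom_ora",
    "binomial_ora",
    "adjust_bh",
    "category_proportion",
    "permutation_proportion_test",
]


@dataclasses.dataclass
class GeneSetCollection:
    """Annotation terms over a background universe.

    ``labels[term]`` marks whether the term is cancer/aging-related (a
    curated input annotation, not computed).
    """

    terms: dict[str, set[str]]
    labels: dict[str, bool]
    universe: set[str]

    def __post_init__(self):
        self.terms = {t: set(g) & self.universe for t, g in self.terms.items()}
        missing = set(self.terms) - set(self.labels)
        if missing:
            raise ValueError(f"terms without labels: {sorted(missing)}")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT-style file: term <TAB> label(0/1) <TAB> gene1 <TAB> gene2 ...

    The universe is the union of all term gene sets.
    """
    terms: dict[str, set[str]] = {}
    labels: dict[str, bool] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = set(g for g in parts[2:] if g)
            labels[parts[0]] = parts[1].strip() in ("1", "true", "True")
    universe = set().union(*terms.values()) if terms else set()
    return GeneSetCollection(terms, labels, universe)


def _restrict_foreground(foreground, collection) -> set[str]:
    fg = set(foreground)
    dropped = fg - collection.universe
    if dropped:
        logger.info("dropped %d foreground genes outside the universe", len(dropped))
    fg &= collection.universe
    if not fg:
        raise ValueError("foreground is empty after restriction to the universe")
    return fg


def _ora(foreground, collection, test: str) -> pd.DataFrame:
    fg = _restrict_foreground(foreground, collection)
    N = len(collection.universe)
    n = len(fg)
    rows = []
    for term, genes in collection.terms.items():
        K = len(genes)
        k = len(fg & genes)
        if test == "hypergeometric":
            # P(X >= k) with X ~ Hypergeom(N, K, n)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            p = float(stats.binom.sf(k - 1, n, K / N))
        p = min(p, 1.0)
        fe = (k / n) / (K / N) if K > 0 else math.nan
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_raw": p,
                "fold_enrichment": fe,
                "log2_fe": math.log2(fe) if k > 0 and fe > 0 else math.nan,
                "label": collection.labels[term],
                "test": test,
            }
        )
    df = pd.DataFrame(rows).sort_values(["p_raw", "term"]).reset_index(drop=True)
    return adjust_bh(df)


def hypergeom_ora(foreground, collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per term."""
    return _ora(foreground, collection, "hypergeometric")


def binomial_ora(foreground, collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail binomial over-representation per term (success prob K/N)."""
    return _ora(foreground, collection, "binomial")


def adjust_bh(rows: pd.DataFrame) -> pd.DataFrame:
    """Benjamini–Hochberg step-up adjustment over ``p_raw``."""
    if rows.empty:
        raise ValueError("no rows to adjust")
    out = rows.copy()
    out["p_adjusted"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    return out


def category_proportion(rows: pd.DataFrame, alpha: float = 0.05,
                        use_adjusted: bool = False) -> tuple[float, list[str]]:
    """Proportion of enriched terms carrying the cancer/aging label.

    Enriched means p_raw <= alpha by default (matching the reported
    "enriched with P<=0.05" convention); set ``use_adjusted`` to use BH
    values instead.  Returns (proportion, enriched term list); proportion is
    0.0 with a warning when nothing is enriched.
    """
    col = "p_adjusted" if use_adjusted else "p_raw"
    enriched = rows[rows[col] <= alpha]
    if enriched.empty:
        warnings.warn("no enriched terms", stacklevel=2)
        return 0.0, []
    prop = float(enriched["label"].mean())
    return prop, enriched["term"].tolist()


def permutation_proportion_test(group_a, group_b, n_perm: int = 5000,
                                seed: int = 0) -> dict:
    """Two-sided permutation test on the difference of group mean proportions.

    The statistic is mean(A) − mean(B); the p-value is the fraction of
    group-label reassignments whose |statistic| is at least the observed
    (no add-one correction, so an empty tail prints 0.0).  All C(nA+nB, nA)
    partitions are enumerated when that count does not exceed
    max(n_perm, 20000); otherwise ``n_perm`` seeded reshuffles are drawn.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size + b.size < 3:
        raise ValueError("total group size < 3: no nontrivial permutations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    p, exact, used = _perm_pvalue(pooled, na, observed, n_perm, seed)
    return {
        "observed_difference": observed,
        "p_value": p,
        "n_perm": used,
        "exact": exact,
        "seed": seed,
        "group_sizes": [int(na), int(b.size)],
    }


def _perm_pvalue(pooled: np.ndarray, na: int, observed: float,
                 n_perm: int, seed: int, cap: int = 20000):
    """Shared permutation engine: exact enumeration when feasible."""
    n = pooled.size
    tol = 1e-12
    if math.comb(n, na) <= max(n_perm, cap):
        total = hits = 0
        for idx in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            stat = pooled[mask].mean() - pooled[~mask].mean()
            hits += abs(stat) >= abs(observed) - tol
            total += 1
        return hits / total, True, total
    rng = np.random.Generator(np.random.PCG64(seed))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        stat = pooled[perm[:na]].mean() - pooled[perm[na:]].mean()
        hits += abs(stat) >= abs(observed) - tol
    return hits / n_perm, False, n_perm
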