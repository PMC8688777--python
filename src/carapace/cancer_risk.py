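"""Intrinsic cancer risk on a phylogeny.

Under a multistage model of carcinogenesis, the expected lifetime cancer
risk of a species scales with the number of cells at risk and (steeply) with
the time available for mutations to accumulate; here the intrinsic risk
statistic is K = size × lifespan^6 with lifespan in years and size the
supplied body-size proxy (carapace length by default).  Because observed
cancer prevalence is roughly constant across species, per-branch increases
in K imply compensating evolved reductions in realized risk; the per-branch
relative intrinsic cancer risk (RICR) change is log2(K_child / K_parent),
reported alongside the field's "X-log2 decreased RICR" reporting convention in
which a positive log2 change in K is phrased as the log2 reduction in
realized risk needed to hold prevalence constant.

All arithmetic is carried out in log space (log2 K = 6·log2 L + log2 S) to
avoid overflow; linear K is reported where representable.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RunConfig, TraitTable
from .traitmodels import (
    PGLS,
    BrownianMotionASR,
    JumpDiffusionASR,
    ancestral_lifespans,
    branch_changes,
)
from .trees import Phylogeny

__all__ = ["intrinsic_risk", "branch_ricr", "ricr_pipeline", "neoplasia_prevalence"]

LIFESPAN_EXPONENT = 6


def intrinsic_risk(lifespan: float, size: float) -> dict:
    """Intrinsic cancer risk K = size × lifespan^6 for one node.

    Parameters are on the linear scale (years; size proxy units).  Returns
    ``{"log2_K": ..., "K": ...}`` where ``K`` is NaN when not representable
    in double precision.
    """
    if not (np.isfinite(lifespan) and np.isfinite(size)):
        raise ValueError("lifespan and size must be finite")
    if lifespan <= 0 or size <= 0:
        raise ValueError("lifespan and size must be > 0")
    log2K = LIFESPAN_EXPONENT * math.log2(lifespan) + math.log2(size)
    K = 2.0**log2K if log2K < 1023 else math.nan
    return {"log2_K": log2K, "K": K}


def branch_ricr(tree: Phylogeny, node_log2K: np.ndarray) -> pd.DataFrame:
    """Per-branch log2 change in intrinsic risk.

    ``delta_ricr_log2`` is log2(K_child) − log2(K_parent); the conventional
    ``decreased_ricr_log2`` equals it when positive (an increase in expected
    risk implies an equal-magnitude evolved decrease in realized risk) and
    is zero otherwise.
    """
    node_log2K = np.asarray(node_log2K, dtype=float)
    if node_log2K.size != tree.n_nodes or not np.all(np.isfinite(node_log2K)):
        bad = np.flatnonzero(~np.isfinite(node_log2K))
        raise ValueError(
            f"log2 K missing/non-finite at node(s) {bad.tolist()}"
            if node_log2K.size == tree.n_nodes
            else "node K table does not cover every node"
        )
    rows = []
    for v in tree.preorder():
        if v == tree.root:
            continue
        p = tree.parent[v]
        delta = node_log2K[v] - node_log2K[p]
        rows.append(
            {
                "child_id": int(v),
                "label": tree.labels[v] or "",
                "log2K_parent": node_log2K[p],
                "log2K_child": node_log2K[v],
                "delta_ricr_log2": delta,
                "decreased_ricr_log2": delta if delta > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def ricr_pipeline(tree: Phylogeny, size_table: TraitTable,
                  lifespan_table: TraitTable, config: RunConfig | None = None,
                  out_dir=None) -> dict:
    """Full intrinsic-cancer-risk analysis.

    Size ASR (Brownian or jump model per config) → PGLS of log2 lifespan on
    log2 size → ancestral lifespans → per-node K → per-branch RICR changes.
    Returns a dict with the fitted objects and result tables; if ``out_dir``
    is given, writes TSV/JSON outputs with a config echo.
    """
    config = config or RunConfig()
    size_log2 = size_table.to_log2()
    life_log2 = lifespan_table.to_log2()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"ricr_pipeline stage {name!r} failed: {exc}") from exc

    if config.model == "jump":
        size_asr = stage("size_asr", lambda: JumpDiffusionASR(
            tree, size_log2).fit(
                iterations=config.mcmc_iterations,
                burn_in=config.mcmc_burn_in,
                seed=config.seed,
        ))
    else:
        size_asr = stage("size_asr", lambda: BrownianMotionASR(tree, size_log2).fit())
    pgls = stage("pgls", lambda: PGLS(tree, size_log2, life_log2).fit())
    life_nodes = stage(
        "ancestral_lifespans", lambda: ancestral_lifespans(tree, pgls, size_asr)
    )
    log2K = (
        LIFESPAN_EXPONENT * life_nodes["log2_lifespan"].to_numpy()
        + size_asr.estimates
    )
    risk = stage("branch_ricr", lambda: branch_ricr(tree, log2K))
    changes = stage("branch_changes", lambda: branch_changes(tree, size_asr))

    result = {
        "size_asr": size_asr,
        "pgls": pgls,
        "lifespans": life_nodes,
        "node_log2K": log2K,
        "ricr": risk,
        "size_changes": changes,
        "config": config.echo(),
    }
    if out_dir is not None:
        _write_bundle(tree, result, Path(out_dir))
    return result


def _write_bundle(tree: Phylogeny, result: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    asr = result["size_asr"]
    nodes = asr.to_frame()
    nodes["log2_lifespan"] = result["lifespans"]["log2_lifespan"]
    nodes["log2_K"] = result["node_log2K"]
    nodes.to_csv(out_dir / "nodes.tsv", sep="\t", index=False)
    merged = result["size_changes"].merge(
        result["ricr"][["child_id", "delta_ricr_log2", "decreased_ricr_log2"]],
        on="child_id",
    )
    merged.to_csv(out_dir / "branches.tsv", sep="\t", index=False)
    # tree with rate multipliers as branch lengths, for visualisation
    rates = np.zeros(tree.n_nodes)
    for _, row in result["size_changes"].iterrows():
        r = row["rate_multiplier"]
        rates[int(row["child_id"])] = r if np.isfinite(r) else 0.0
    (out_dir / "rate_tree.nwk").write_text(
        tree.with_branch_lengths(rates).to_newick() + "\n"
    )
    top = merged.nlargest(10, "decreased_ricr_log2")[
        ["child_id", "label", "decreased_ricr_log2", "percent_change",
         "rate_multiplier"]
    ]
    summary = {
        "config": result["config"],
        "top_decreased_ricr_branches": top.to_dict(orient="records"),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))


def neoplasia_prevalence(n_neoplasms: int, n_necropsies: int) -> float:
    """Observed neoplasia prevalence as a percentage (e.g. 6/490 → ~1.2%)."""
    if n_necropsies <= 0 or n_neoplasms < 0 or n_neoplasms > n_necropsies:
        raise ValueError("need 0 <= n_neoplasms <= n_necropsies, n_necropsies > 0")
    return 100.0 * n_neoplasms / n_necropsies
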