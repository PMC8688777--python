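"""Rooted, time-calibrated phylogenies.

The :class:`Phylogeny` container stores a rooted tree as flat arrays indexed
by deterministic preorder node IDs (root = 0), which makes ancestral
reconstructions comparable across runs and lets the numerical code vectorise
over nodes.  Branch lengths are in millions of years.

Parsing is delegated to dendropy; validation and the round-trippable writer
are ours so error messages can name the offending token.
"""

from __future__ import annotations

import io
import warnings

import dendropy
import numpy as np

__all__ = ["Phylogeny", "parse_newick", "NewickParseError"]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be interpreted as a valid tree."""


def _strip_comments_and_quotes(text: str) -> str:
    """Remove [...] comments and '...' quoted spans for structural checks."""
    out = []
    depth = 0
    in_quote = False
    for ch in text:
        if in_quote:
            if ch == "'":
                in_quote = False
            continue
        if ch == "'":
            in_quote = True
            continue
        if ch == "[":
            depth += 1
            continue
        if ch == "]":
            depth = max(0, depth - 1)
            continue
        if depth == 0:
            out.append(ch)
    return "".join(out)


class Phylogeny:
    """A rooted tree with stable preorder integer node IDs.

    Parameters
    ----------
    parent
        ``parent[i]`` is the parent ID of node ``i``; the root has ``-1``.
    branch_length
        Length of the branch above each node in millions of years
        (``nan`` for the root).
    labels
        Per-node label; tips must carry unique non-empty labels, internal
        labels are optional (``None``).
    """

    def __init__(self, parent, branch_length, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if self.branch_length.size != n or len(self.labels) != n:
            raise ValueError("parent, branch_length and labels must have equal length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._validate()

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        n = self.n_nodes
        # acyclicity / connectivity: preorder walk must reach every node once
        seen = np.zeros(n, dtype=bool)
        stack = [self.root]
        while stack:
            v = stack.pop()
            if seen[v]:
                raise ValueError("cycle detected in parent mapping")
            seen[v] = True
            stack.extend(self.children[v])
        if not seen.all():
            raise ValueError("tree is not connected")
        bl = self.branch_length[np.arange(n) != self.root]
        if not np.all(np.isfinite(bl)):
            raise ValueError("non-root branch lengths must be finite")
        if np.any(bl < 0):
            raise ValueError("negative branch length")
        tips = [self.labels[i] for i in self.tip_ids]
        if any(t is None or t == "" for t in tips):
            raise ValueError("every tip must carry a non-empty label")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {', '.join(dup)}")

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def is_tip(self) -> np.ndarray:
        return np.array([len(c) == 0 for c in self.children])

    @property
    def tip_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    def preorder(self) -> np.ndarray:
        """Node IDs, parents before children (IDs are assigned in this order)."""
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return np.asarray(order)

    def postorder(self) -> np.ndarray:
        """Node IDs, children before parents."""
        return self.preorder()[::-1]

    def node_id(self, label: str) -> int:
        for i, lab in enumerate(self.labels):
            if lab == label:
                return i
        raise KeyError(f"no node labelled {label!r}")

    def depths(self) -> np.ndarray:
        """Distance from the root to each node (My)."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.branch_length[v]
        return d

    def mrca(self, labels) -> int:
        """Most recent common ancestor of a set of tip labels."""
        want = set(labels)
        below: list[set] = [set() for _ in range(self.n_nodes)]
        for v in self.postorder():
            if not self.children[v]:
                below[v] = {self.labels[v]}
            else:
                for c in self.children[v]:
                    below[v] |= below[c]
            if want <= below[v]:
                return int(v)
        raise KeyError(f"labels not all present in tree: {sorted(want)}")

    def tips_below(self, node: int) -> list[str]:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(self.labels[v])
            stack.extend(self.children[v])
        return out

    def shared_path_matrix(self, tip_order: list[str] | None = None) -> np.ndarray:
        """Brownian covariance structure: V[i, j] = root-to-MRCA(i, j) distance.

        ``tip_order`` fixes the row/column ordering (defaults to preorder
        tip labels).
        """
        if tip_order is None:
            tip_order = self.tip_labels
        idx = {lab: k for k, lab in enumerate(tip_order)}
        m = len(tip_order)
        depth = self.depths()
        V = np.zeros((m, m))
        below: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in self.postorder():
            if not self.children[v]:
                lab = self.labels[v]
                if lab in idx:
                    below[v] = [idx[lab]]
                    V[idx[lab], idx[lab]] = depth[v]
            else:
                kids = [below[c] for c in self.children[v]]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                V[i, j] = V[j, i] = depth[v]
                below[v] = [i for k in kids for i in k]
        return V

    # -- copies ------------------------------------------------------------

    def with_branch_lengths(self, new_lengths) -> "Phylogeny":
        """Copy of the tree with replaced branch lengths (root entry ignored)."""
        bl = np.asarray(new_lengths, dtype=float).copy()
        bl[self.root] = np.nan
        return Phylogeny(self.parent.copy(), bl, list(self.labels))

    # -- serialisation -----------------------------------------------------

    @staticmethod
    def _quote(label: str) -> str:
        if any(c in label for c in "()[]':;,= \t\n"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def to_newick(self, include_internal_labels: bool = True) -> str:
        def render(v: int) -> str:
            lab = self.labels[v]
            if self.children[v]:
                inner = ",".join(render(c) for c in self.children[v])
                s = f"({inner})"
                if include_internal_labels and lab:
                    s += self._quote(lab)
            else:
                s = self._quote(lab)
            if v != self.root:
                s += f":{np.format_float_positional(self.branch_length[v], trim='0')}"
            return s

        return render(self.root) + ";"

    def __repr__(self) -> str:
        return f"<Phylogeny: {self.n_tips} tips, {self.n_nodes} nodes>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick statement into a :class:`Phylogeny`.

    Branch lengths are optional and default to 1.0 (with a warning); square
    bracket comments are stripped; quoted labels are unescaped.  Node IDs are
    assigned in deterministic preorder.

    Raises
    ------
    NewickParseError
        On unbalanced parentheses, duplicate tip labels, negative branch
        lengths or other malformed input.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("newick statement must end with ';'")
    bare = _strip_comments_and_quotes(stripped)
    if bare.count("(") != bare.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {bare.count('(')} '(' vs {bare.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        msg = str(exc)
        if "Duplicate taxon labels" in msg:
            dup = msg.rsplit(":", 1)[-1].strip()
            raise NewickParseError(f"duplicate tip labels: {dup}") from exc
        raise NewickParseError(f"could not parse newick: {msg}") from exc

    # preorder numbering
    dnodes = list(dtree.preorder_node_iter())
    ids = {id(nd): k for k, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.full(n, np.nan)
    labels: list[str | None] = [None] * n
    defaulted = 0
    for nd in dnodes:
        k = ids[id(nd)]
        if nd.parent_node is not None:
            parent[k] = ids[id(nd.parent_node)]
            if nd.edge.length is None:
                blen[k] = 1.0
                defaulted += 1
            else:
                if nd.edge.length < 0:
                    raise NewickParseError(
                        f"negative branch length {nd.edge.length} above node "
                        f"{nd.taxon.label if nd.taxon else nd.label!r}"
                    )
                blen[k] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[k] = nd.taxon.label
        elif nd.label:
            labels[k] = nd.label
    if defaulted:
        warnings.warn(
            f"{defaulted} branch length(s) missing; defaulted to 1.0", stacklevel=2
        )
    try:
        return Phylogeny(parent, blen, labels)
    except ValueError as exc:
        raise NewickParseError(str(exc)) from exc
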