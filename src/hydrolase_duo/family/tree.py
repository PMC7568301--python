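"""Neighbor-joining phylogenetics with column-resampling bootstrap.

The canonical Saitou–Nei neighbor-joining algorithm is implemented
directly: it is exact on additive distance matrices (it reproduces the
generating tree's topology and path lengths), which is the main
correctness oracle.  Negative branch-length estimates are clamped to
zero with the deficit moved to the sister branch so the joined pair's
distance is preserved.

Distances between aligned sequences are 1 − fractional identity (same
pair-deletion convention as the identity profile).  Bootstrap support
of each internal edge is the fraction of column-resampled replicate
trees containing the same leaf bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import GAP, ReferencedMSA

__all__ = ["TreeNode", "nj_tree", "msa_distance_matrix", "bootstrap_support",
           "bipartitions"]


@dataclass
class TreeNode:
    """A node of an unrooted tree (the root is a trifurcation artifact)."""

    name: str = ""
    length: float = 0.0  # branch to parent
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.2f}"
        return f"({inner}){label}:{self.length:.6f}"


def _check_matrix(dist: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError(f"distance matrix must be square, got {dist.shape}")
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dist)):
        raise ValueError("distance matrix has non-finite entries")
    if np.max(np.abs(dist - dist.T)) > tol:
        raise ValueError("distance matrix is asymmetric beyond tolerance")
    if np.max(np.abs(np.diag(dist))) > tol:
        raise ValueError("distance matrix diagonal must be zero")
    return 0.5 * (dist + dist.T)


def _clamp(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def nj_tree(dist: np.ndarray, taxa: list[str]) -> TreeNode:
    """Canonical neighbor joining; returns an unrooted tree.

    Ties in the Q-criterion break toward the lexicographically first
    (i, j) index pair, so the result is deterministic and invariant
    (up to relabeling) under taxon permutation.
    """
    d = _check_matrix(dist)
    if len(taxa) != d.shape[0]:
        raise ValueError("taxa list must match the matrix dimension")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    active = list(range(len(taxa)))
    d = d.copy()

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        ai, aj = divmod(flat, n)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances to the new node
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (max(la, 0.0), max(lb, 0.0), max(lc, 0.0))):
        node.length = ln
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def msa_distance_matrix(rows: list[str]) -> np.ndarray:
    """Pairwise 1 − fractional-identity distances over aligned rows."""
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matches = denom = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP and b == GAP:
                    continue
                denom += 1
                if a == b:
                    matches += 1
            d[i, j] = d[j, i] = 1.0 - (matches / denom if denom else 0.0)
    return d


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Leaf bipartitions induced by internal edges, canonicalized.

    Each split is stored as the side not containing the alphabetically
    first taxon; trivial splits (single leaf / all-but-one) are
    excluded.
    """
    all_leaves = set(tree.leaves())
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name}
        below: set[str] = set()
        for c in node.children:
            below |= walk(c)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            out.add(frozenset(side))
        return below

    for c in tree.children:
        walk(c)
    return out


def _annotate_support(tree: TreeNode, supports: dict[frozenset[str], float]) -> None:
    all_leaves = set(tree.leaves())
    anchor = min(all_leaves)

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name}
        below: set[str] = set()
        for c in node.children:
            below |= walk(c)
        if 1 < len(below) < len(all_leaves) - 1:
            side = frozenset(below if anchor not in below else all_leaves - below)
            node.support = supports.get(side, 0.0)
        return below

    for c in tree.children:
        walk(c)


def bootstrap_support(msa: ReferencedMSA, n_boot: int = 100, seed: int = 0) -> TreeNode:
    """NJ tree of the alignment with column-resampling bootstrap supports.

    Distances are 1 − fractional identity.  Support of each internal
    edge is the fraction of replicate trees containing its bipartition.
    Deterministic given ``seed``.
    """
    if n_boot < 10:
        raise ValueError(f"need at least 10 bootstrap replicates, got {n_boot}")
    rows = list(msa.rows)
    n_cols = len(rows[0])
    if n_cols < 10:
        import warnings

        warnings.warn(
            f"alignment has only {n_cols} columns; bootstrap supports will be crude",
            stacklevel=2,
        )
    taxa = list(msa.ids)
    tree = nj_tree(msa_distance_matrix(rows), taxa)
    ref_splits = bipartitions(tree)
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(r[c] for c in cols) for r in rows]
        rep_tree = nj_tree(msa_distance_matrix(rep_rows), taxa)
        for s in bipartitions(rep_tree):
            if s in counts:
                counts[s] += 1
    supports = {s: c / n_boot for s, c in counts.items()}
    _annotate_support(tree, supports)
    return tree
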