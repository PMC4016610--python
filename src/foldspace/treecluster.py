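"""Neighbor-joining dendrograms and maximum-linkage tessellation.

The structure space is first linked into a dendrogram by canonical
Saitou-Nei neighbor joining (exhaustive Q-criterion search, as in ClearCut's
"strict" mode).  The space is then tessellated by descending the tree from
the root and emitting a subtree's leaves as one cluster as soon as ALL
pairwise ORIGINAL distances among them fall within a threshold
(maximum-linkage clustering); the tree topology restricts candidate
clusters so a single threshold can recover clusters of varying density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .annotate import Partition
from .scores import DistanceMatrix

__all__ = [
    "TreeNode",
    "Dendrogram",
    "neighbor_joining",
    "max_linkage_clusters",
    "tree_path_distances",
]


@dataclass
class TreeNode:
    """A dendrogram node; ``children`` pairs each child with its branch length."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out


@dataclass
class Dendrogram:
    """Rooted view of an NJ tree; the final join may leave a trifurcating root."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def iter_nodes(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(child for child, _ in reversed(node.children))


def neighbor_joining(dist: DistanceMatrix) -> Dendrogram:
    """Canonical Saitou-Nei NJ with deterministic tie-breaking.

    At each step the pair minimising Q_ij = (m-2) d_ij - r_i - r_j is joined
    (ties broken by the lexicographically smallest index pair), branch
    lengths follow the standard two-point formulas, and distances to the new
    node are d_uk = (d_ik + d_jk - d_ij)/2.  The final three-way join is kept
    as a trifurcating root; with two taxa the root splits the single edge.
    Negative branch lengths are kept as computed.
    """
    if not dist.complete:
        raise ValueError("neighbor joining needs a complete matrix; impute first")
    n = dist.n
    if n < 2:
        raise ValueError("need at least two entities")
    nodes: list[TreeNode] = [TreeNode(name=e) for e in dist.ids]
    d = dist.values.astype(float).copy()

    if n == 2:
        half = d[0, 1] / 2.0
        return Dendrogram(root=TreeNode(children=[(nodes[0], half), (nodes[1], half)]))

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(m)] = np.inf
        # flat argmin over the upper triangle is row-major, i.e. the
        # lexicographically smallest (i, j) among ties
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        new = TreeNode(children=[(nodes[active[i]], li), (nodes[active[j]], lj)])
        du = 0.5 * (sub[i, :] + sub[j, :] - dij)
        # grow the working matrix with the new node's row/column
        d = np.pad(d, ((0, 1), (0, 1)))
        k_new = d.shape[0] - 1
        for pos, k in enumerate(active):
            d[k_new, k] = d[k, k_new] = du[pos]
        nodes.append(new)
        ai, aj = active[i], active[j]
        active = [k for k in active if k not in (ai, aj)] + [k_new]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return Dendrogram(root=root)


def max_linkage_clusters(tree: Dendrogram, dist: DistanceMatrix, t: float) -> Partition:
    """Tessellate by the subtree maximum-linkage criterion.

    Descend from the root; whenever every pairwise original distance among a
    subtree's leaves is <= t, emit those leaves as one cluster and stop
    descending.  Leaves always qualify (singletons).  Labels are assigned in
    depth-first discovery order.
    """
    idx = {e: k for k, e in enumerate(dist.ids)}
    missing = [e for e in tree.leaf_names() if e not in idx]
    if missing:
        raise ValueError(f"leaves missing from distance matrix: {missing[:5]}")

    clusters: dict[str, set[str]] = {}

    def emit(members: list[str]) -> None:
        clusters[f"C{len(clusters)}"] = set(members)

    def visit(node: TreeNode) -> None:
        leaves = node.leaf_names()
        rows = np.array([idx[e] for e in leaves])
        if len(leaves) == 1 or dist.values[np.ix_(rows, rows)].max() <= t:
            emit(leaves)
            return
        for child, _ in node.children:
            visit(child)

    visit(tree.root)
    return Partition(clusters=clusters)


def tree_path_distances(tree: Dendrogram) -> DistanceMatrix:
    """Leaf-to-leaf sums of branch lengths (additivity oracle support)."""
    ids = tree.leaf_names()
    idx = {e: k for k, e in enumerate(ids)}
    n = len(ids)
    values = np.zeros((n, n))

    def visit(node: TreeNode) -> dict[int, float]:
        if node.is_leaf:
            return {idx[node.name]: 0.0}
        child_maps = []
        for child, length in node.children:
            sub = visit(child)
            child_maps.append({leaf: dist + length for leaf, dist in sub.items()})
        merged: dict[int, float] = {}
        for cm in child_maps:
            for other in child_maps:
                if other is cm:
                    continue
                for li, di in cm.items():
                    for lj, dj in other.items():
                        values[li, lj] = values[lj, li] = di + dj
            merged.update(cm)
        return merged

    visit(tree.root)
    return DistanceMatrix(ids=ids, values=values)
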