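"""Neighbor joining and maximum-linkage tessellation against independent oracles.

The oracles are built from scratch here: random additive trees are generated
by edge insertion, their leaf-to-leaf path distances feed NJ, and recovery is
checked by split-set equality (plus, for small trees, exhaustive enumeration
of all unrooted topologies with least-squares branch-length fitting to prove
the generator topology is the unique additive-consistent one).
"""

import itertools

import numpy as np
import pytest

from foldspace import (
    DistanceMatrix,
    max_linkage_clusters,
    neighbor_joining,
    tree_path_distances,
)
from foldspace.treecluster import Dendrogram, TreeNode
from conftest import dense_matrix


# ---------------------------------------------------------------- oracles


def random_edge_tree(n_leaves: int, rng) -> tuple[list[tuple[int, int]], dict, int]:
    """Random unrooted binary tree as an edge list with branch lengths."""
    edges = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]
    next_node = n_leaves + 1
    for leaf in range(3, n_leaves):
        k = int(rng.integers(len(edges)))
        u, v = edges.pop(k)
        w = next_node
        next_node += 1
        edges.extend([(u, w), (w, v), (leaf, w)])
    lengths = {e: float(rng.uniform(0.5, 2.0)) for e in edges}
    return edges, lengths, next_node


def edge_tree_distances(n_leaves, edges, lengths, n_nodes) -> np.ndarray:
    adj: dict[int, list[tuple[int, float]]] = {k: [] for k in range(n_nodes)}
    for (u, v), w in lengths.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    out = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            out[src, dst] = dist[dst]
    return out


def edge_tree_splits(n_leaves, edges) -> set[frozenset]:
    """Non-trivial splits (canonicalized to the side not containing leaf 0)."""
    splits = set()
    for cut in edges:
        adj: dict[int, list[int]] = {}
        for u, v in edges:
            if (u, v) == cut:
                continue
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        side = {cut[0]}
        stack = [cut[0]]
        while stack:
            u = stack.pop()
            for v in adj.get(u, []):
                if v not in side:
                    side.add(v)
                    stack.append(v)
        leaves = frozenset(l for l in range(n_leaves) if l in side)
        if 2 <= len(leaves) <= n_leaves - 2:
            if 0 in leaves:
                leaves = frozenset(range(n_leaves)) - leaves
            splits.add(leaves)
    return splits


def dendrogram_splits(tree: Dendrogram) -> set[frozenset]:
    names = tree.leaf_names()
    index = {e: int(e[1:]) for e in names}  # leaves are named L<i>
    n = len(names)
    splits = set()
    for node in tree.iter_nodes():
        leaves = frozenset(index[e] for e in node.leaf_names())
        if 2 <= len(leaves) <= n - 2:
            if 0 in leaves:
                leaves = frozenset(range(n)) - leaves
            splits.add(leaves)
    return splits


def enumerate_topologies(n_leaves: int):
    """All unrooted binary topologies by recursive edge insertion."""
    base = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]
    stack = [(base, 3, n_leaves + 1)]
    while stack:
        edges, leaf, next_node = stack.pop()
        if leaf == n_leaves:
            yield edges
            continue
        for k in range(len(edges)):
            u, v = edges[k]
            w = next_node
            new_edges = edges[:k] + edges[k + 1:] + [(u, w), (w, v), (leaf, w)]
            stack.append((new_edges, leaf + 1, next_node + 1))


def additive_on_topology(d: np.ndarray, n_leaves, edges, n_nodes) -> bool:
    """Least-squares branch lengths reproduce d exactly (residual ~ 0)."""
    pairs = list(itertools.combinations(range(n_leaves), 2))
    a = np.zeros((len(pairs), len(edges)))
    adj: dict[int, list[tuple[int, int]]] = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))

    def path_edges(src, dst):
        prev = {src: None}
        stack = [src]
        while stack:
            u = stack.pop()
            if u == dst:
                break
            for v, k in adj[u]:
                if v not in prev:
                    prev[v] = (u, k)
                    stack.append(v)
        out, node = [], dst
        while prev[node] is not None:
            node, k = prev[node]
            out.append(k)
        return out

    for row, (i, j) in enumerate(pairs):
        for k in path_edges(i, j):
            a[row, k] = 1.0
    b = np.array([d[i, j] for i, j in pairs])
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return bool(np.abs(a @ sol - b).max() < 1e-8)


def nj_from_matrix(d: np.ndarray) -> Dendrogram:
    return neighbor_joining(dense_matrix(d, ids=[f"L{i}" for i in range(d.shape[0])]))


# ------------------------------------------------------------------- tests


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(dense_matrix([[0, 4], [4, 0]], ids=["A", "B"]))
        pd = tree_path_distances(tree)
        assert pd.values[pd.ids.index("A"), pd.ids.index("B")] == pytest.approx(4.0)

    def test_four_taxon_worked_example(self):
        ids = list("ABCD")
        m = np.array([[0, 5, 9, 8], [5, 0, 10, 9], [9, 10, 0, 7], [8, 9, 7, 0]], float)
        tree = neighbor_joining(dense_matrix(m, ids=ids))
        # split AB | CD with leaf branches A:2, B:3, C:4, D:3 and internal edge 3
        internal = [n for n in tree.iter_nodes() if not n.is_leaf and n is not tree.root]
        assert len(internal) == 1
        assert sorted(internal[0].leaf_names()) == ["A", "B"]
        lengths = {}
        for node in tree.iter_nodes():
            for child, length in node.children:
                if child.is_leaf:
                    lengths[child.name] = length
                else:
                    lengths["internal"] = length
        assert lengths == {"A": 2, "B": 3, "C": 4, "D": 3, "internal": 3}
        pd = tree_path_distances(tree)
        order = [pd.ids.index(e) for e in ids]
        assert np.abs(pd.values[np.ix_(order, order)] - m).max() < 1e-9

    def test_equal_distances_deterministic(self):
        m = np.ones((5, 5)) - np.eye(5)
        t1 = neighbor_joining(dense_matrix(m))
        t2 = neighbor_joining(dense_matrix(m))
        assert dendrogram_splits(t1) == dendrogram_splits(t2)

    def test_additive_recovery_random_trees(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            edges, lengths, n_nodes = random_edge_tree(n, rng)
            d = edge_tree_distances(n, edges, lengths, n_nodes)
            tree = nj_from_matrix(d)
            assert dendrogram_splits(tree) == edge_tree_splits(n, edges)
            pd = tree_path_distances(tree)
            order = [pd.ids.index(f"L{i}") for i in range(n)]
            assert np.abs(pd.values[np.ix_(order, order)] - d).max() < 1e-9

    def test_unique_additive_topology_by_enumeration(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 7))
            edges, lengths, n_nodes = random_edge_tree(n, rng)
            d = edge_tree_distances(n, edges, lengths, n_nodes)
            consistent = [
                edge_tree_splits(n, topo)
                for topo in enumerate_topologies(n)
                if additive_on_topology(d, n, topo, 2 * n - 2)
            ]
            unique = {frozenset(s) for s in consistent}
            assert unique == {frozenset(edge_tree_splits(n, edges))}
            assert dendrogram_splits(nj_from_matrix(d)) == edge_tree_splits(n, edges)

    def test_incomplete_matrix_rejected(self):
        observed = np.ones((3, 3), dtype=bool)
        observed[0, 1] = observed[1, 0] = False
        dist = DistanceMatrix(ids=list("abc"), values=np.ones((3, 3)) - np.eye(3), observed=observed)
        with pytest.raises(ValueError, match="complete"):
            neighbor_joining(dist)


class TestMaxLinkage:
    def worked(self):
        ids = list("ABCD")
        m = np.array([[0, 5, 9, 8], [5, 0, 10, 9], [9, 10, 0, 7], [8, 9, 7, 0]], float)
        dist = dense_matrix(m, ids=ids)
        return neighbor_joining(dist), dist

    def test_threshold_above_max_is_one_cluster(self):
        tree, dist = self.worked()
        part = max_linkage_clusters(tree, dist, 10)
        assert len(part) == 1

    def test_threshold_below_min_is_singletons(self):
        tree, dist = self.worked()
        part = max_linkage_clusters(tree, dist, 4.9)
        assert len(part) == 4

    def test_worked_threshold_five(self):
        tree, dist = self.worked()
        part = max_linkage_clusters(tree, dist, 5)
        groups = {frozenset(m) for m in part.clusters.values()}
        assert groups == {frozenset({"A", "B"}), frozenset({"C"}), frozenset({"D"})}

    @staticmethod
    def brute_force_partition(tree: Dendrogram, dist: DistanceMatrix, t: float):
        """Node emitted iff it qualifies and no proper ancestor qualifies."""
        idx = {e: k for k, e in enumerate(dist.ids)}

        def qualifies(node: TreeNode) -> bool:
            leaves = node.leaf_names()
            if len(leaves) == 1:
                return True
            rows = np.array([idx[e] for e in leaves])
            return bool(dist.values[np.ix_(rows, rows)].max() <= t)

        out = []

        def walk(node, ancestor_qualified):
            q = qualifies(node)
            if q and not ancestor_qualified:
                out.append(frozenset(node.leaf_names()))
            for child, _ in node.children:
                walk(child, ancestor_qualified or q)

        walk(tree.root, False)
        return set(out)

    def test_matches_brute_force_on_random_trees(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            edges, lengths, n_nodes = random_edge_tree(n, rng)
            d = edge_tree_distances(n, edges, lengths, n_nodes)
            d += rng.normal(0, 0.05, d.shape)
            d = np.abs(0.5 * (d + d.T))
            np.fill_diagonal(d, 0)
            dist = dense_matrix(d, ids=[f"L{i}" for i in range(n)])
            tree = neighbor_joining(dist)
            t = float(rng.uniform(0, d.max() * 1.1))
            got = {frozenset(m) for m in max_linkage_clusters(tree, dist, t).clusters.values()}
            assert got == self.brute_force_partition(tree, dist, t)

    def test_partitions_nested_in_threshold(self, rng):
        n = 12
        edges, lengths, n_nodes = random_edge_tree(n, rng)
        d = edge_tree_distances(n, edges, lengths, n_nodes)
        dist = dense_matrix(d, ids=[f"L{i}" for i in range(n)])
        tree = neighbor_joining(dist)
        prev = None
        for t in np.linspace(0, d.max(), 12):
            part = max_linkage_clusters(tree, dist, t)
            groups = [frozenset(m) for m in part.clusters.values()]
            assert set().union(*groups) == set(dist.ids)
            if prev is not None:
                # every earlier cluster is contained in some current cluster
                for g in prev:
                    assert any(g <= h for h in groups)
            prev = groups

    def test_missing_leaf_rejected(self):
        tree, dist = self.worked()
        small = dense_matrix(dist.values[:3, :3], ids=list("ABC"))
        with pytest.raises(ValueError, match="missing"):
            max_linkage_clusters(tree, small, 5)


class TestPathDistances:
    def test_star_tree(self):
        leaves = [TreeNode(name=n) for n in "abc"]
        tree = Dendrogram(root=TreeNode(children=[(l, 1.0) for l in leaves]))
        pd = tree_path_distances(tree)
        off = pd.values[~np.eye(3, dtype=bool)]
        assert np.all(off == 2.0)
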