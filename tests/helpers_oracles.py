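"""Independent brute-force oracles used to validate the main implementations.

Each oracle recomputes a quantity by exhaustive enumeration or dense linear
algebra, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_nw(a: str, b: str, score, open_cost: float, extend_cost: float) -> float:
    """Maximum global alignment score by exhaustive recursion over alignments.

    Explores every sequence of substitution / gap-in-a / gap-in-b columns;
    a gap run of length L costs open_cost + L * extend_cost (tracked through
    the ``last`` operation).  Exponential: only for short sequences.
    """

    def best(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b (consume a)
            cost = extend_cost if last == "D" else open_cost + extend_cost
            options.append(-cost + best(i + 1, j, "D"))
        if j < len(b):  # gap in a (consume b)
            cost = extend_cost if last == "I" else open_cost + extend_cost
            options.append(-cost + best(i, j + 1, "I"))
        return max(options)

    return best(0, 0, "M")


def brute_force_mst_weight(labels: list[str], values: np.ndarray) -> float:
    """Minimum spanning tree weight by enumerating all edge subsets of size N-1."""
    n = len(labels)
    all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok and len({find(i) for i in range(n)}) == 1:
            w = sum(values[u, v] for u, v in subset)
            best = min(best, w)
    return float(best)


def splits_by_edge_removal(d) -> frozenset[frozenset[str]]:
    """Non-trivial splits of the unrooted tree, by removing each edge.

    Builds the undirected adjacency of the tree (suppressing the degree-2
    root), removes every edge in turn, and records the leaf set of one
    component.  Canonical side: the one without the smallest leaf.
    """
    # collect nodes and undirected edges
    nodes: list = []
    edges: list[tuple[int, int]] = []
    index: dict[int, int] = {}

    def reg(n) -> int:
        if id(n) not in index:
            index[id(n)] = len(nodes)
            nodes.append(n)
        return index[id(n)]

    def walk(n) -> None:
        ni = reg(n)
        for c in n.children:
            ci = reg(c)
            edges.append((ni, ci))
            walk(c)

    walk(d.root)
    root_i = index[id(d.root)]
    # suppress a degree-2 root: join its two neighbours
    adj_count: dict[int, int] = {}
    for u, v in edges:
        adj_count[u] = adj_count.get(u, 0) + 1
        adj_count[v] = adj_count.get(v, 0) + 1
    if adj_count.get(root_i, 0) == 2:
        nbrs = [v for u, v in edges if u == root_i] + [u for u, v in edges if v == root_i]
        edges = [(u, v) for u, v in edges if root_i not in (u, v)]
        edges.append((nbrs[0], nbrs[1]))

    leaves = {i: nodes[i].label for i in range(len(nodes)) if not nodes[i].children}
    universe = frozenset(leaves.values())
    anchor = min(universe)
    splits: set[frozenset[str]] = set()
    for k in range(len(edges)):
        remaining = edges[:k] + edges[k + 1:]
        adj: dict[int, list[int]] = {}
        for u, v in remaining:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        start = edges[k][0]
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj.get(x, []):
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(leaves[i] for i in seen if i in leaves)
        if anchor in side:
            side = universe - side
        if 2 <= len(side) <= len(universe) - 2:
            splits.add(side)
    return frozenset(splits)


def pagerank_dense(nodes: list[str], edges, damping: float) -> dict[str, float]:
    """PageRank by direct linear solve of (I - d*M) r = (1-d)/n * 1.

    M is the column-stochastic transition matrix of the bidirected graph with
    dangling columns replaced by uniform 1/n.
    """
    idx = {x: k for k, x in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in edges:
        A[idx[u], idx[v]] = 1.0
        A[idx[v], idx[u]] = 1.0
    out_deg = A.sum(axis=1)
    M = np.zeros((n, n))
    for j in range(n):
        if out_deg[j] == 0:
            M[:, j] = 1.0 / n
        else:
            M[:, j] = A[j] / out_deg[j]
    r = np.linalg.solve(np.eye(n) - damping * M, np.full(n, (1.0 - damping) / n))
    return {x: float(r[idx[x]]) for x in nodes}


def random_tree(labels, rng):
    """Random dendrogram via a uniform random distance matrix (test utility)."""
    from metadendro.dendro import build_dendrogram, random_distance_matrix

    return build_dendrogram(random_distance_matrix(list(labels), rng))
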