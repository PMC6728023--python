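"""Distance matrices and their conversion to dendrograms.

A distance matrix over N organisms is viewed as a complete weighted graph;
Kruskal's algorithm extracts the minimum spanning tree, and processing the
accepted edges in order performs single-linkage agglomeration: each accepted
edge merges the two clusters containing its endpoints at a height equal to
the edge weight.  This is the canonical bijection between an MST and a
single-linkage dendrogram (the Gower-Ross property), and it makes "branch
lengths proportional to distances" well defined.  Because the distance units
of the different construction methods are arbitrary, dendrograms are rescaled
so that the largest merge height is exactly 1 before any comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "DendroNode",
    "Dendrogram",
    "kruskal_mst",
    "mst_to_dendrogram",
    "rescale",
    "random_distance_matrix",
    "build_dendrogram",
]

#: symmetry tolerance for validating distance matrices
SYMMETRY_TOL = 1e-9


class MatrixValidationError(ValueError):
    """Raised when a distance matrix violates its invariants."""


@dataclass
class DistanceMatrix:
    """Labeled symmetric non-negative matrix with zero diagonal.

    Parameters
    ----------
    labels
        Ordered organism identifiers, one per row/column.
    values
        Square array of pairwise distances.  Must be symmetric within
        ``SYMMETRY_TOL``, finite, non-negative, with zero diagonal.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise MatrixValidationError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise MatrixValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise MatrixValidationError("non-finite entries in distance matrix")
        if np.any(self.values < 0):
            raise MatrixValidationError("negative entries in distance matrix")
        if np.any(np.abs(np.diag(self.values)) > 0):
            raise MatrixValidationError("non-zero diagonal in distance matrix")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise MatrixValidationError(
                f"matrix asymmetric beyond tolerance ({asym:.3g} > {SYMMETRY_TOL})"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


@dataclass
class DendroNode:
    """Node of a dendrogram: a labeled leaf (height 0) or an internal merge."""

    height: float = 0.0
    label: str | None = None
    children: list["DendroNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["DendroNode"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


@dataclass
class Dendrogram:
    """Rooted binary merge tree with internal-node heights.

    Leaves sit at height 0; each internal node records the distance at which
    its two child clusters were joined.  Heights are non-decreasing from the
    leaves to the root.  The branch length of a child edge is the difference
    of the two node heights.
    """

    root: DendroNode

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())

    @property
    def max_height(self) -> float:
        return self.root.height

    def nodes(self) -> Iterator[DendroNode]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in dendrogram")
        for node in self.nodes():
            for c in node.children:
                if c.height > node.height + 1e-12:
                    raise ValueError("dendrogram heights decrease toward the root")


def kruskal_mst(D: DistanceMatrix) -> list[tuple[str, str, float]]:
    """Minimum spanning tree of the complete graph defined by ``D``.

    Edges are considered in ascending order of (weight, lexicographic label
    pair), a deterministic tie-break, and accepted when they join two distinct
    components (union-find).  Returns the N-1 accepted edges in acceptance
    order, each as ``(label_u, label_v, weight)`` with ``label_u < label_v``.
    """
    D.validate()
    n = D.n
    if n < 2:
        raise MatrixValidationError("need at least 2 labels for a spanning tree")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            u, v = sorted((D.labels[i], D.labels[j]))
            edges.append((float(D.values[i, j]), u, v))
    edges.sort()

    parent = {lab: lab for lab in D.labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    accepted: list[tuple[str, str, float]] = []
    for w, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            accepted.append((u, v, w))
            if len(accepted) == n - 1:
                break
    return accepted


def mst_to_dendrogram(edges: Sequence[tuple[str, str, float]]) -> Dendrogram:
    """Single-linkage agglomeration over a Kruskal-ordered edge list.

    Each edge, in order, merges the two current clusters containing its
    endpoints into a new internal node whose height is the edge weight.
    Because Kruskal accepts edges in ascending weight order the resulting
    heights are monotone, so the output is a valid dendrogram.
    """
    if not edges:
        raise ValueError("empty edge list")
    cluster: dict[str, DendroNode] = {}
    members: dict[int, list[str]] = {}
    for u, v, w in edges:
        for lab in (u, v):
            if lab not in cluster:
                cluster[lab] = DendroNode(height=0.0, label=lab)
    node_of: dict[str, DendroNode] = dict(cluster)

    # union-find over labels, each root mapping to its current cluster node
    parent = {lab: lab for lab in cluster}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    top: dict[str, DendroNode] = dict(node_of)
    last = None
    for u, v, w in edges:
        ru, rv = find(u), find(v)
        if ru == rv:
            raise ValueError(f"edge ({u},{v}) does not merge two clusters: not a spanning tree")
        merged = DendroNode(height=float(w), children=[top[ru], top[rv]])
        parent[ru] = rv
        top[rv] = merged
        last = merged
    roots = {find(lab) for lab in parent}
    if len(roots) != 1:
        raise ValueError("edge list does not span all labels")
    d = Dendrogram(root=last)
    d.validate()
    return d


def rescale(d: Dendrogram) -> Dendrogram:
    """Divide all heights by the maximum height so the deepest merge is 1.

    The distance units of every construction method are arbitrary; only
    relative distances carry meaning, so dendrograms are normalized before
    comparison.  Topology is unchanged.
    """
    h = d.max_height
    if h <= 0:
        raise ValueError(
            "degenerate dendrogram: maximum merge height is 0 "
            "(all organisms identical under this distance); cannot rescale"
        )

    def copy(node: DendroNode) -> DendroNode:
        return DendroNode(
            height=node.height / h,
            label=node.label,
            children=[copy(c) for c in node.children],
        )

    return Dendrogram(root=copy(d.root))


def random_distance_matrix(labels: Sequence[str], rng: np.random.Generator) -> DistanceMatrix:
    """Symmetric matrix with i.i.d. uniform(0,1) off-diagonal entries.

    This is the null model behind random dendrograms: organisms linked with
    no information at all.
    """
    n = len(labels)
    vals = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals[iu] = rng.uniform(0.0, 1.0, size=len(iu[0]))
    vals = vals + vals.T
    return DistanceMatrix(labels=list(labels), values=vals)


def build_dendrogram(D: DistanceMatrix) -> Dendrogram:
    """Distance matrix -> Kruskal MST -> single-linkage merges -> rescaled tree."""
    return rescale(mst_to_dendrogram(kruskal_mst(D)))
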