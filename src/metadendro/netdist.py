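"""Metabolic-network comparison distances.

A metabolic network is an undirected simple graph whose nodes are metabolites
and whose edges are substrate-product links.  For a set of organisms the
networks are merged into a single union graph; PageRank on that union assigns
each metabolite an importance, and each union edge the mean importance of its
endpoints.  Comparing a pair of organisms then partitions their combined edge
set into edges private to i (A), private to j (B) and shared (C), whose
weight sums alpha, beta, gamma feed the network distances:

    DS1   = |n_i - n_j|            (node-count difference)
    DS2   = |e_i - e_j|            (edge-count difference)
    DNET1 = n_common / gamma
    DNET2 = alpha + beta
    DNET3 = (alpha + beta) / gamma
    DNET4 = node-based analogue of DNET3 (zeta), with node weight
            degree / (2 * union edge count)

The union graph (hence all weights) is recomputed per organism set: the
importance of a metabolite is relative to the metabolisms under comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dendro import DistanceMatrix

__all__ = [
    "MetabolicNetwork",
    "UnionGraph",
    "PairComparison",
    "NETWORK_METHODS",
    "union_graph",
    "pagerank",
    "pair_sets",
    "alpha_beta_gamma",
    "network_distance",
    "network_distance_matrix",
]

log = logging.getLogger(__name__)

NETWORK_METHODS = ("DS1", "DS2", "DNET1", "DNET2", "DNET3", "DNET4")

Edge = tuple[str, str]


def _edge(u: str, v: str) -> Edge:
    """Canonical (sorted) representation of an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class MetabolicNetwork:
    """Undirected simple graph of metabolites for one organism."""

    organism_id: str
    nodes: set[str] = field(default_factory=set)
    edges: set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = {_edge(u, v) for u, v in self.edges}
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r} in network {self.organism_id}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(
                    f"edge ({u},{v}) has endpoint outside node set of {self.organism_id}"
                )
        if not self.nodes:
            raise ValueError(f"network {self.organism_id} has no nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class UnionGraph:
    """Union of a set of organisms' networks, with PageRank-derived weights."""

    nodes: list[str]
    edges: set[Edge]
    node_rank: dict[str, float]
    edge_weight: dict[Edge, float]

    @property
    def total_degree(self) -> int:
        return 2 * len(self.edges)


@dataclass
class PairComparison:
    """Edge-set partition for one organism pair plus its weight sums."""

    A: set[Edge]
    B: set[Edge]
    C: set[Edge]
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    n_common_nodes: int = 0


def pagerank(
    nodes: Sequence[str],
    edges: Iterable[Edge],
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """PageRank on an undirected graph by power iteration.

    Each undirected edge is treated as a pair of directed arcs; teleportation
    is uniform with damping factor ``damping``.  Nodes without edges are
    dangling: their outgoing mass is spread uniformly, so the ranks always sum
    to 1 and isolated nodes end up with teleport-level mass.  Iteration stops
    when the L1 change drops below ``tol``.
    """
    idx = {lab: k for k, lab in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        raise ValueError("pagerank of empty node set")
    deg = np.zeros(n)
    pairs = []
    for u, v in edges:
        pairs.append((idx[u], idx[v]))
        deg[idx[u]] += 1
        deg[idx[v]] += 1
    r = np.full(n, 1.0 / n)
    dangling = deg == 0
    safe_deg = np.where(dangling, 1.0, deg)
    src = np.array([p[0] for p in pairs], dtype=int)
    dst = np.array([p[1] for p in pairs], dtype=int)
    for _ in range(max_iter):
        out = r / safe_deg
        new = np.zeros(n)
        if len(pairs):
            np.add.at(new, dst, out[src])
            np.add.at(new, src, out[dst])
        dangling_mass = r[dangling].sum()
        new = damping * (new + dangling_mass / n) + (1.0 - damping) / n
        if np.abs(new - r).sum() < tol:
            r = new
            break
        r = new
    else:
        log.warning("pagerank did not converge in %d iterations", max_iter)
    return {lab: float(r[idx[lab]]) for lab in nodes}


def union_graph(
    nets: Sequence[MetabolicNetwork],
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> UnionGraph:
    """Merge the networks of a set of organisms and weight the union's edges.

    The weight of a union edge is the mean of the PageRank of its two
    endpoints, so that links between important (highly connected, within the
    set's joint metabolism) metabolites count more.
    """
    if not nets:
        raise ValueError("union of zero networks")
    nodes: set[str] = set()
    edges: set[Edge] = set()
    for net in nets:
        nodes |= net.nodes
        edges |= net.edges
    ordered = sorted(nodes)
    rank = pagerank(ordered, sorted(edges), damping=damping, tol=tol, max_iter=max_iter)
    weight = {e: (rank[e[0]] + rank[e[1]]) / 2.0 for e in edges}
    return UnionGraph(nodes=ordered, edges=edges, node_rank=rank, edge_weight=weight)


def pair_sets(net_i: MetabolicNetwork, net_j: MetabolicNetwork) -> PairComparison:
    """Partition the two organisms' combined edges into private/shared sets."""
    A = net_i.edges - net_j.edges
    B = net_j.edges - net_i.edges
    C = net_i.edges & net_j.edges
    return PairComparison(A=A, B=B, C=C, n_common_nodes=len(net_i.nodes & net_j.nodes))


def alpha_beta_gamma(pc: PairComparison, ug: UnionGraph) -> tuple[float, float, float]:
    """Sum the union-graph edge weights over the A, B and C edge sets."""
    w = ug.edge_weight
    alpha = sum(w[e] for e in pc.A)
    beta = sum(w[e] for e in pc.B)
    gamma = sum(w[e] for e in pc.C)
    pc.alpha, pc.beta, pc.gamma = alpha, beta, gamma
    return alpha, beta, gamma


def _node_weight(node: str, ug: UnionGraph) -> float:
    # degree in the union graph normalized by total degree; weights sum to 1
    deg = sum(1 for e in ug.edges if node in e)
    return deg / ug.total_degree if ug.total_degree else 0.0


def network_distance(
    net_i: MetabolicNetwork,
    net_j: MetabolicNetwork,
    ug: UnionGraph | None,
    method: str,
) -> float:
    """Distance between two organisms' networks under one of the six methods.

    A zero denominator (no shared edges for DNET1/DNET3, or no shared nodes
    for DNET4) yields ``inf``; the matrix-level builder replaces such
    sentinels with twice the largest finite entry.
    """
    if method == "DS1":
        return float(abs(net_i.n_nodes - net_j.n_nodes))
    if method == "DS2":
        return float(abs(net_i.n_edges - net_j.n_edges))
    if method not in NETWORK_METHODS:
        raise ValueError(f"unknown network distance method {method!r}")
    if ug is None:
        raise ValueError(f"method {method} requires the union graph")
    pc = pair_sets(net_i, net_j)
    if method == "DNET4":
        only_i = net_i.nodes - net_j.nodes
        only_j = net_j.nodes - net_i.nodes
        both = net_i.nodes & net_j.nodes
        a = sum(_node_weight(x, ug) for x in only_i)
        b = sum(_node_weight(x, ug) for x in only_j)
        g = sum(_node_weight(x, ug) for x in both)
        return (a + b) / g if g > 0 else float("inf")
    alpha, beta, gamma = alpha_beta_gamma(pc, ug)
    if method == "DNET1":
        return pc.n_common_nodes / gamma if gamma > 0 else float("inf")
    if method == "DNET2":
        return alpha + beta
    # DNET3
    return (alpha + beta) / gamma if gamma > 0 else float("inf")


def network_distance_matrix(
    nets: Sequence[MetabolicNetwork],
    method: str,
    damping: float = 0.85,
    tol: float = 1e-10,
) -> DistanceMatrix:
    """Symmetric distance matrix over a set of organisms' networks.

    Infinite entries (pairs with empty shared sets under the ratio methods)
    are replaced by twice the largest finite off-diagonal entry, preserving
    the ordering Kruskal relies on while keeping the matrix numeric.
    """
    if len(nets) < 3:
        raise ValueError("need at least 3 networks for a distance matrix")
    labels = [net.organism_id for net in nets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate organism ids among networks")
    ug = None
    if method not in ("DS1", "DS2"):
        ug = union_graph(nets, damping=damping, tol=tol)
    n = len(nets)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = network_distance(nets[i], nets[j], ug, method)
            vals[i, j] = vals[j, i] = d
    if np.isinf(vals).any():
        off = vals[np.triu_indices(n, k=1)]
        finite_off = off[np.isfinite(off)]
        if finite_off.size == 0:
            raise ValueError(
                f"all pairwise {method} distances are infinite: no pair shares edges/nodes"
            )
        sentinel = 2.0 * float(finite_off.max())
        n_inf = int(np.isinf(vals).sum() // 2)
        log.warning(
            "%s: %d pair(s) with empty shared set; using sentinel distance %.6g",
            method,
            n_inf,
            sentinel,
        )
        vals[np.isinf(vals)] = sentinel
    return DistanceMatrix(labels=labels, values=vals)
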