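"""Synthetic organism evolution: known tree, sequences and metabolic networks.

The generator emulates the statistical structure of a prokaryote dataset
(one universal 16S-like marker per organism, several shared enzyme families
tagged with EC-style identifiers, and a metabolite network) so that every
stage of the pipeline — alignment distances, network distances, dendrogram
construction and ensemble comparison — can run with no external data, and so
that reconstruction quality can be measured against the generating tree.

Model summary
-------------
* Tree: Yule pure-birth process run until ``n_organisms`` tips, branch
  lengths in units of expected divergence time (ultrametric by default; an
  optional relaxed clock multiplies each branch by a lognormal rate).
* Sequences: per-site substitution events arrive as Poisson(rate * t); an
  event redraws the site uniformly over the full alphabet, so sequence
  identity decays from 1 to the alphabet background (1/4 or 1/20).  No
  indels: lengths are preserved.
* Networks: each edge of the parent network survives a branch of length t
  with probability exp(-loss_rate * t); Poisson(gain_rate * t) new edges are
  gained, occasionally introducing a fresh metabolite.  Nodes are never
  deleted, mirroring the ubiquity of core metabolites across species.
* Enzyme families: family 1 is present in every organism (guaranteeing a
  non-empty common-EC set); other families are present per organism with
  ``family_presence_prob``, and with ``multi_copy_prob`` an organism carries
  a diverged second copy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    Alphabet,
    Dataset,
    EnsembleSpec,
    RIBO_MARKER,
    SequenceRecord,
    write_ensemble_file,
    write_fasta,
    write_network_tsv,
)
from .netdist import MetabolicNetwork, _edge

__all__ = [
    "TreeConfig",
    "NetworkConfig",
    "SequenceConfig",
    "SynthConfig",
    "TreeNode",
    "TrueTree",
    "simulate_tree",
    "simulate_ancestor_network",
    "evolve_network",
    "evolve_sequence",
    "generate_dataset",
    "SynthBundle",
]

SIM_NUC = "ACGT"
SIM_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class TreeConfig:
    birth_rate: float = 1.0
    ultrametric: bool = True
    #: lognormal sigma of per-branch rate multipliers when ultrametric=False
    clock_sigma: float = 0.3


@dataclass
class NetworkConfig:
    ancestor_nodes: int = 60
    ancestor_edges: int = 90
    edge_loss_rate: float = 0.2
    edge_gain_rate: float = 18.0
    new_metabolite_prob: float = 0.2


@dataclass
class SequenceConfig:
    ribo_length: int = 500
    ribo_subst_rate: float = 0.05
    n_enzyme_families: int = 8
    enzyme_length: int = 200
    enzyme_subst_rate: float = 0.05
    family_presence_prob: float = 0.9
    multi_copy_prob: float = 0.1
    #: extra divergence time applied to a duplicated enzyme copy
    duplicate_divergence: float = 0.2


@dataclass
class SynthConfig:
    n_organisms: int = 12
    seed: int = 0
    tree: TreeConfig = field(default_factory=TreeConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    sequences: SequenceConfig = field(default_factory=SequenceConfig)

    def __post_init__(self) -> None:
        if self.n_organisms < 2:
            raise ValueError("need at least 2 organisms")
        net = self.network
        if net.ancestor_edges < net.ancestor_nodes - 1:
            raise ValueError("ancestor_edges must be >= ancestor_nodes - 1 (connectivity)")
        if not (0 < self.sequences.family_presence_prob <= 1):
            raise ValueError("family_presence_prob must be in (0, 1]")
        for rate in (
            net.edge_loss_rate,
            net.edge_gain_rate,
            self.sequences.ribo_subst_rate,
            self.sequences.enzyme_subst_rate,
            self.tree.birth_rate,
        ):
            if rate < 0:
                raise ValueError("rates must be non-negative")


@dataclass
class TreeNode:
    """Node of the generating tree; ``branch_length`` is the edge above it."""

    branch_length: float = 0.0
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class TrueTree:
    """Rooted binary generating tree with branch lengths."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        out: list[str] = []

        def visit(n: TreeNode) -> None:
            if n.is_leaf:
                out.append(n.label)
            for c in n.children:
                visit(c)

        visit(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    @property
    def depth(self) -> float:
        def d(n: TreeNode) -> float:
            if n.is_leaf:
                return n.branch_length
            return n.branch_length + max(d(c) for c in n.children)

        return d(self.root)

    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.label}:{n.branch_length:.10g}"
            inner = ",".join(fmt(c) for c in n.children)
            return f"({inner}):{n.branch_length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def organism_codes(n: int) -> list[str]:
    """Three-letter organism codes: aaa, aab, aac, ..."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    gen = ("".join(t) for t in itertools.product(letters, repeat=3))
    return list(itertools.islice(gen, n))


def simulate_tree(cfg: SynthConfig, rng: np.random.Generator) -> TrueTree:
    """Yule pure-birth tree with ``n_organisms`` tips.

    Starting from the root split (two lineages at time 0), while k lineages
    are alive the next speciation arrives after Exp(k * birth_rate) time on a
    uniformly chosen lineage; after the n-th lineage appears one further
    exponential wait sets the present, so the expected depth is
    sum_{k=2..n} 1 / (k * birth_rate).
    """
    lam = cfg.tree.birth_rate
    n = cfg.n_organisms
    root = TreeNode()
    c1, c2 = TreeNode(), TreeNode()
    root.children = [c1, c2]
    birth = {id(c1): 0.0, id(c2): 0.0}
    active = [c1, c2]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * lam))
        v = active.pop(rng.integers(k))
        v.branch_length = t - birth[id(v)]
        a, b = TreeNode(), TreeNode()
        v.children = [a, b]
        birth[id(a)] = birth[id(b)] = t
        active.extend([a, b])
    t_end = t + rng.exponential(1.0 / (n * lam))
    for leaf, code in zip(active, organism_codes(n)):
        leaf.branch_length = t_end - birth[id(leaf)]
        leaf.label = code
    # leaves were extended in creation order; relabel in traversal order so
    # codes read left-to-right in the newick
    tree = TrueTree(root=root)
    for leaf_node, code in zip(_leaves(root), organism_codes(n)):
        leaf_node.label = code
    if not cfg.tree.ultrametric:
        def relax(node: TreeNode) -> None:
            node.branch_length *= float(rng.lognormal(0.0, cfg.tree.clock_sigma))
            for c in node.children:
                relax(c)

        for c in root.children:
            relax(c)
    return tree


def _leaves(node: TreeNode) -> list[TreeNode]:
    if node.is_leaf:
        return [node]
    out: list[TreeNode] = []
    for c in node.children:
        out.extend(_leaves(c))
    return out


def simulate_ancestor_network(cfg: SynthConfig, rng: np.random.Generator) -> MetabolicNetwork:
    """Connected ancestor network: preferential attachment, then extra edges.

    Growth by degree-proportional attachment yields the right-skewed degree
    distribution typical of metabolic networks; random extra edges then top
    the graph up to ``ancestor_edges``.
    """
    ncfg = cfg.network
    n = ncfg.ancestor_nodes
    nodes = [f"m{i:04d}" for i in range(1, n + 1)]
    edges: set[tuple[str, str]] = {_edge(nodes[0], nodes[1])}
    degree = {nodes[0]: 1, nodes[1]: 1, **{x: 0 for x in nodes[2:]}}
    for i in range(2, n):
        present = nodes[:i]
        weights = np.array([degree[x] for x in present], dtype=float)
        target = present[rng.choice(i, p=weights / weights.sum())]
        edges.add(_edge(nodes[i], target))
        degree[nodes[i]] += 1
        degree[target] += 1
    while len(edges) < ncfg.ancestor_edges:
        u, v = rng.choice(n, size=2, replace=False)
        e = _edge(nodes[u], nodes[v])
        if e not in edges:
            edges.add(e)
    return MetabolicNetwork(organism_id="ancestor", nodes=set(nodes), edges=edges)


def evolve_network(
    parent: MetabolicNetwork,
    t: float,
    cfg: SynthConfig,
    rng: np.random.Generator,
    fresh_ids: "itertools.count | None" = None,
    organism_id: str | None = None,
) -> MetabolicNetwork:
    """Edge gain/loss along a branch of length ``t``.

    Each parent edge survives with probability exp(-loss_rate * t); the
    number of gained edges is Poisson(gain_rate * t).  A gained edge connects
    two existing metabolites (redrawn if already present) or, with
    ``new_metabolite_prob``, attaches a fresh metabolite to an existing one.
    Nodes are never removed, so isolated metabolites persist.
    """
    ncfg = cfg.network
    ordered = sorted(parent.edges)
    keep_p = math.exp(-ncfg.edge_loss_rate * t)
    mask = rng.random(len(ordered)) < keep_p
    edges = {e for e, k in zip(ordered, mask) if k}
    nodes = set(parent.nodes)
    n_gain = rng.poisson(ncfg.edge_gain_rate * t)
    node_list = sorted(nodes)
    for _ in range(n_gain):
        if fresh_ids is not None and rng.random() < ncfg.new_metabolite_prob:
            new = f"m{next(fresh_ids):04d}"
            anchor = node_list[rng.integers(len(node_list))]
            nodes.add(new)
            node_list.append(new)
            edges.add(_edge(new, anchor))
            continue
        # connect two existing metabolites; redraw on duplicates
        for _attempt in range(20):
            u, v = rng.choice(len(node_list), size=2, replace=False)
            e = _edge(node_list[u], node_list[v])
            if e not in edges:
                edges.add(e)
                break
    return MetabolicNetwork(
        organism_id=organism_id or parent.organism_id, nodes=nodes, edges=edges
    )


def evolve_sequence(
    parent: SequenceRecord,
    t: float,
    rate: float,
    rng: np.random.Generator,
) -> SequenceRecord:
    """Per-site substitution along a branch of length ``t``.

    A site experiences at least one Poisson(rate * t) event with probability
    1 - exp(-rate * t); an event redraws the site uniformly over the full
    alphabet (the multiple-hit limit therefore converges to the alphabet
    background identity, 1/4 for nucleotides and 1/20 for amino acids).
    Lengths are preserved: the generator introduces no indels.
    """
    alphabet = SIM_NUC if parent.alphabet is Alphabet.NUCLEOTIDE else SIM_AA
    p_event = 1.0 - math.exp(-rate * t)
    chars = np.frombuffer(parent.residues.encode(), dtype="S1").copy()
    hit = rng.random(len(chars)) < p_event
    n_hit = int(hit.sum())
    if n_hit:
        draws = rng.integers(len(alphabet), size=n_hit)
        repl = np.frombuffer(alphabet.encode(), dtype="S1")[draws]
        chars[hit] = repl
    return SequenceRecord(
        organism_id=parent.organism_id,
        marker_id=parent.marker_id,
        copy_index=parent.copy_index,
        alphabet=parent.alphabet,
        residues=chars.tobytes().decode(),
    )


def _random_sequence(length: int, alphabet: str, rng: np.random.Generator) -> str:
    idx = rng.integers(len(alphabet), size=length)
    return "".join(alphabet[i] for i in idx)


@dataclass
class SynthBundle:
    """Everything one synthetic study needs: data, truth and set definition."""

    dataset: Dataset
    tree: TrueTree
    ensemble: EnsembleSpec
    organisms: list[str]
    config: SynthConfig


def generate_dataset(cfg: SynthConfig, out_dir: str | Path | None = None) -> SynthBundle:
    """Simulate a tree and evolve sequences and networks down it.

    The root organism carries one RIBO sequence, ``n_enzyme_families`` enzyme
    sequences (families ``EC:1.1.1.k``) and the ancestor network; every branch
    evolves all of them.  At the tips, enzyme families other than family 1
    are retained with ``family_presence_prob`` and duplicated (as a diverged
    second copy) with ``multi_copy_prob``.  Deterministic under ``cfg.seed``;
    if ``out_dir`` is given the standard on-disk layout is written.
    """
    rng = np.random.default_rng(cfg.seed)
    scfg = cfg.sequences
    tree = simulate_tree(cfg, rng)
    ancestor_net = simulate_ancestor_network(cfg, rng)
    fresh_ids = itertools.count(cfg.network.ancestor_nodes + 1)

    families = [f"EC:1.1.1.{k}" for k in range(1, scfg.n_enzyme_families + 1)]
    root_ribo = SequenceRecord(
        organism_id="root",
        marker_id=RIBO_MARKER,
        residues=_random_sequence(scfg.ribo_length, SIM_NUC, rng),
        alphabet=Alphabet.NUCLEOTIDE,
    )
    root_fams = {
        fam: SequenceRecord(
            organism_id="root",
            marker_id=fam,
            residues=_random_sequence(scfg.enzyme_length, SIM_AA, rng),
            alphabet=Alphabet.AMINO_ACID,
        )
        for fam in families
    }

    dataset = Dataset()

    def descend(
        node: TreeNode,
        ribo: SequenceRecord,
        fams: dict[str, SequenceRecord],
        net: MetabolicNetwork,
    ) -> None:
        if node.is_leaf:
            org = node.label
            dataset.add_record(
                SequenceRecord(
                    organism_id=org,
                    marker_id=RIBO_MARKER,
                    residues=ribo.residues,
                    alphabet=Alphabet.NUCLEOTIDE,
                )
            )
            for k, fam in enumerate(families, start=1):
                if k > 1 and rng.random() >= scfg.family_presence_prob:
                    continue
                tip = SequenceRecord(
                    organism_id=org,
                    marker_id=fam,
                    residues=fams[fam].residues,
                    alphabet=Alphabet.AMINO_ACID,
                )
                dataset.add_record(tip)
                if rng.random() < scfg.multi_copy_prob:
                    dup = evolve_sequence(
                        tip, scfg.duplicate_divergence, scfg.enzyme_subst_rate, rng
                    )
                    dataset.add_record(
                        SequenceRecord(
                            organism_id=org,
                            marker_id=fam,
                            copy_index=2,
                            residues=dup.residues,
                            alphabet=Alphabet.AMINO_ACID,
                        )
                    )
            dataset.add_network(
                MetabolicNetwork(organism_id=org, nodes=set(net.nodes), edges=set(net.edges))
            )
            return
        for child in node.children:
            t = child.branch_length
            c_ribo = evolve_sequence(ribo, t, scfg.ribo_subst_rate, rng)
            c_fams = {
                fam: evolve_sequence(fams[fam], t, scfg.enzyme_subst_rate, rng)
                for fam in families
            }
            c_net = evolve_network(net, t, cfg, rng, fresh_ids=fresh_ids)
            descend(child, c_ribo, c_fams, c_net)

    descend(tree.root, root_ribo, root_fams, ancestor_net)

    organisms = sorted(tree.leaf_labels())
    ensemble = EnsembleSpec(sets=[organisms])
    bundle = SynthBundle(
        dataset=dataset, tree=tree, ensemble=ensemble, organisms=organisms, config=cfg
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_records = [
            rec
            for key in sorted(dataset.sequences)
            for rec in dataset.get_seqs(*key)
        ]
        write_fasta(all_records, out / "sequences.fasta")
        netdir = out / "networks"
        netdir.mkdir(exist_ok=True)
        for org in organisms:
            write_network_tsv(dataset.networks[org], netdir / f"{org}.tsv")
        write_ensemble_file(ensemble, out / "ensemble.txt")
        (out / "truth.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
    return bundle
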