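import numpy as np
import pytest

from metadendro.io_formats import Alphabet, SequenceRecord
from metadendro.netdist import MetabolicNetwork
from metadendro.seqdist import common_markers, distance_matrix_gene
from metadendro.synth import (
    NetworkConfig,
    SequenceConfig,
    SynthConfig,
    evolve_network,
    evolve_sequence,
    generate_dataset,
    simulate_ancestor_network,
    simulate_tree,
)


class TestSimulateTree:
    def test_two_organisms_give_a_cherry(self):
        t = simulate_tree(SynthConfig(n_organisms=2), np.random.default_rng(0))
        assert t.n_leaves == 2
        assert len(t.root.children) == 2
        assert all(c.is_leaf for c in t.root.children)

    def test_deterministic_under_seed(self):
        a = simulate_tree(SynthConfig(n_organisms=9), np.random.default_rng(7))
        b = simulate_tree(SynthConfig(n_organisms=9), np.random.default_rng(7))
        assert a.to_newick() == b.to_newick()

    def test_ultrametric_tips_align(self):
        t = simulate_tree(SynthConfig(n_organisms=10), np.random.default_rng(3))

        def depths(node, acc):
            acc = acc + node.branch_length
            if node.is_leaf:
                yield acc
            for c in node.children:
                yield from depths(c, acc)

        tip_depths = list(depths(t.root, 0.0))
        assert np.allclose(tip_depths, tip_depths[0])

    def test_mean_depth_matches_yule_expectation(self):
        # pure-birth depth expectation: sum_{k=2..n} 1/(k*lambda)
        rng = np.random.default_rng(42)
        n, lam, reps = 8, 1.0, 500
        cfg = SynthConfig(n_organisms=n)
        depths = np.array([simulate_tree(cfg, rng).depth for _ in range(reps)])
        expected = sum(1.0 / (k * lam) for k in range(2, n + 1))
        se = depths.std(ddof=1) / np.sqrt(reps)
        assert abs(depths.mean() - expected) < 3 * se


class TestAncestorNetwork:
    def test_tree_case_is_connected_and_acyclic(self):
        cfg = SynthConfig(network=NetworkConfig(ancestor_nodes=20, ancestor_edges=19))
        net = simulate_ancestor_network(cfg, np.random.default_rng(0))
        assert net.n_edges == net.n_nodes - 1
        # connectivity: union-find over edges reaches all nodes
        parent = {x: x for x in net.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in net.edges:
            parent[find(u)] = find(v)
        assert len({find(x) for x in net.nodes}) == 1

    def test_degree_distribution_right_skewed(self):
        maxes, medians = [], []
        for seed in range(50):
            cfg = SynthConfig(network=NetworkConfig(ancestor_nodes=40, ancestor_edges=60))
            net = simulate_ancestor_network(cfg, np.random.default_rng(seed))
            deg = {x: 0 for x in net.nodes}
            for u, v in net.edges:
                deg[u] += 1
                deg[v] += 1
            vals = sorted(deg.values())
            maxes.append(vals[-1])
            medians.append(np.median(vals))
        assert np.mean(maxes) > np.mean(medians)

    def test_exact_edge_count(self):
        cfg = SynthConfig(network=NetworkConfig(ancestor_nodes=30, ancestor_edges=45))
        net = simulate_ancestor_network(cfg, np.random.default_rng(5))
        assert net.n_nodes == 30 and net.n_edges == 45


class TestEvolveNetwork:
    def base_net(self):
        nodes = {f"m{i}" for i in range(10)}
        edges = {(f"m{i}", f"m{i+1}") for i in range(9)}
        return MetabolicNetwork(organism_id="p", nodes=nodes, edges=edges)

    def test_zero_branch_is_identity(self):
        cfg = SynthConfig()
        child = evolve_network(self.base_net(), 0.0, cfg, np.random.default_rng(0))
        assert child.edges == self.base_net().edges
        assert child.nodes == self.base_net().nodes

    def test_zero_rates_identity_for_any_branch(self):
        cfg = SynthConfig(network=NetworkConfig(edge_loss_rate=0.0, edge_gain_rate=0.0))
        child = evolve_network(self.base_net(), 5.0, cfg, np.random.default_rng(0))
        assert child.edges == self.base_net().edges

    def test_survival_fraction_matches_exponential_decay(self):
        loss, t, reps = 0.3, 1.2, 200
        cfg = SynthConfig(network=NetworkConfig(edge_loss_rate=loss, edge_gain_rate=0.0))
        parent = self.base_net()
        rng = np.random.default_rng(8)
        fracs = np.array(
            [len(evolve_network(parent, t, cfg, rng).edges) / parent.n_edges for _ in range(reps)]
        )
        expected = np.exp(-loss * t)
        se = fracs.std(ddof=1) / np.sqrt(reps)
        assert abs(fracs.mean() - expected) < 3 * se

    def test_nodes_never_deleted(self):
        cfg = SynthConfig(network=NetworkConfig(edge_loss_rate=2.0, edge_gain_rate=0.0))
        child = evolve_network(self.base_net(), 3.0, cfg, np.random.default_rng(1))
        assert child.nodes == self.base_net().nodes


class TestEvolveSequence:
    def rec(self, seq, alph=Alphabet.NUCLEOTIDE):
        return SequenceRecord("x", "RIBO" if alph is Alphabet.NUCLEOTIDE else "EC:1.1.1.1", seq, 1, alph)

    def test_zero_branch_identity(self):
        parent = self.rec("ACGT" * 25)
        child = evolve_sequence(parent, 0.0, 0.1, np.random.default_rng(0))
        assert child.residues == parent.residues

    def test_length_preserved(self):
        parent = self.rec("ACGT" * 25)
        child = evolve_sequence(parent, 2.0, 0.5, np.random.default_rng(0))
        assert len(child.residues) == len(parent.residues)

    @pytest.mark.parametrize(
        "alph,background",
        [(Alphabet.NUCLEOTIDE, 1 / 4), (Alphabet.AMINO_ACID, 1 / 20)],
    )
    def test_saturation_identity_approaches_alphabet_background(self, alph, background):
        seq = ("ACGT" * 50) if alph is Alphabet.NUCLEOTIDE else ("ACDEFGHIKLMNPQRSTVWY" * 10)
        parent = self.rec(seq, alph)
        rng = np.random.default_rng(10)
        idents = []
        for _ in range(100):
            child = evolve_sequence(parent, 100.0, 1.0, rng)
            idents.append(np.mean([a == b for a, b in zip(parent.residues, child.residues)]))
        idents = np.array(idents)
        se = idents.std(ddof=1) / np.sqrt(len(idents))
        assert abs(idents.mean() - background) < 3 * se

    def test_small_divergence_first_order_expansion(self):
        L, rate, t, reps = 400, 0.02, 0.5, 200
        parent = self.rec("ACGT" * (L // 4))
        rng = np.random.default_rng(11)
        diffs = np.array(
            [
                sum(a != b for a, b in zip(parent.residues, evolve_sequence(parent, t, rate, rng).residues))
                for _ in range(reps)
            ]
        )
        expected = L * (1 - np.exp(-rate * t)) * (1 - 1 / 4)
        se = diffs.std(ddof=1) / np.sqrt(reps)
        assert abs(diffs.mean() - expected) < 3 * se


class TestGenerateDataset:
    def test_family_one_common_to_all(self, small_bundle):
        common = common_markers(small_bundle.organisms, small_bundle.dataset)
        assert "EC:1.1.1.1" in common

    def test_every_organism_has_ribo_and_network(self, small_bundle):
        for org in small_bundle.organisms:
            assert small_bundle.dataset.get_seqs(org, "RIBO")
            assert org in small_bundle.dataset.networks

    def test_deterministic_bundles_and_files(self, tmp_path):
        cfg = SynthConfig(n_organisms=5, seed=21)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        generate_dataset(cfg, out_dir=d1)
        generate_dataset(cfg, out_dir=d2)
        for rel in ["sequences.fasta", "ensemble.txt", "truth.nwk"]:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
        for f in sorted((d1 / "networks").glob("*.tsv")):
            assert f.read_bytes() == (d2 / "networks" / f.name).read_bytes()

    def test_zero_rates_make_all_organisms_identical(self):
        cfg = SynthConfig(
            n_organisms=4,
            seed=2,
            sequences=SequenceConfig(
                ribo_subst_rate=0.0, enzyme_subst_rate=0.0, multi_copy_prob=0.0,
                family_presence_prob=1.0,
            ),
            network=NetworkConfig(edge_loss_rate=0.0, edge_gain_rate=0.0),
        )
        b = generate_dataset(cfg)
        D = distance_matrix_gene(b.organisms, b.dataset, "DRIBO")
        assert np.array_equal(D.values, np.zeros((4, 4)))

    def test_roundtrip_through_disk_layout(self, tmp_path):
        from metadendro.io_formats import Dataset

        cfg = SynthConfig(n_organisms=5, seed=31)
        bundle = generate_dataset(cfg, out_dir=tmp_path)
        ds = Dataset.from_dir(tmp_path)
        assert ds.organisms() == bundle.organisms
        for org in bundle.organisms:
            assert ds.networks[org].edges == bundle.dataset.networks[org].edges
            assert (
                ds.get_seqs(org, "RIBO")[0].residues
                == bundle.dataset.get_seqs(org, "RIBO")[0].residues
            )
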