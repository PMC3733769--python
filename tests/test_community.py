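import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcnet.community import (
    AnnealConfig,
    Partition,
    anneal,
    brute_force_min,
    frequency_solutions,
    module_reproducibility,
    null_model,
    rb_energy,
)
from mcnet.errors import StructureError
from mcnet.rv import CorrelationNetwork
from tests.conftest import make_random_network

CFG = AnnealConfig(trials=20, master_seed=42)


class TestNullModel:
    def test_unweighted_graph_edge_density(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)]:
            w[a, b] = w[b, a] = 1.0
        net = CorrelationNetwork(tuple("ABCDEF"), w)
        assert null_model(net).p == pytest.approx(6 / 15)

    def test_uniform_complete_graph(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        net = CorrelationNetwork(tuple("ABCD"), w)
        assert null_model(net).p == pytest.approx(0.5)

    def test_empty_network(self):
        net = CorrelationNetwork(("A", "B", "C"), np.zeros((3, 3)))
        assert null_model(net).p == 0.0

    def test_single_node_rejected(self):
        net = CorrelationNetwork(("A",), np.zeros((1, 1)))
        with pytest.raises(StructureError):
            null_model(net)


class TestRbEnergy:
    def test_all_singletons_energy_zero(self, rng):
        net = make_random_network(7, rng)
        null = null_model(net)
        part = Partition.from_labels(list(range(7)), net.labels)
        assert rb_energy(part, net, null) == 0.0

    def test_all_in_one_energy_zero_by_weight_conservation(self, rng):
        # the null preserves total weight, so sum(W_ij - p) over all pairs is 0
        for _ in range(20):
            k = int(rng.integers(3, 12))
            net = make_random_network(k, rng, density=float(rng.uniform(0.2, 1.0)))
            null = null_model(net)
            part = Partition.from_labels([0] * k, net.labels)
            assert rb_energy(part, net, null) == pytest.approx(0.0, abs=1e-12)

    def test_two_clique_value_and_minimality(self, two_clique_network):
        net = two_clique_network
        null = null_model(net)
        planted = Partition.from_labels([0, 0, 0, 1, 1, 1], net.labels)
        # 6 within-pairs x (1 - 0.4)
        assert rb_energy(planted, net, null) == pytest.approx(-3.6, abs=1e-12)
        parts, e_min = brute_force_min(net, null)
        assert e_min == pytest.approx(-3.6, abs=1e-12)
        assert planted in parts

    def test_missing_node_is_coverage_error(self, rng):
        net = make_random_network(4, rng)
        part = Partition.from_labels([0, 0, 1], net.labels[:3])
        with pytest.raises(StructureError):
            rb_energy(part, net, null_model(net))


class TestBruteForce:
    def test_enumerates_all_partitions_of_six_nodes(self, two_clique_network):
        from mcnet.community import _partitions_rgs

        assert sum(1 for _ in _partitions_rgs(6)) == 203  # Bell(6)

    def test_empty_network_all_partitions_tie(self):
        net = CorrelationNetwork(("A", "B", "C"), np.zeros((3, 3)))
        parts, e = brute_force_min(net, null_model(net))
        assert e == 0.0
        assert len(parts) == 5  # Bell(3)

    def test_single_node_single_partition(self):
        net = CorrelationNetwork(("A",), np.zeros((1, 1)))
        parts, e = brute_force_min(net, NullOrZero())
        assert len(parts) == 1 and e == 0.0

    def test_too_many_nodes_rejected(self, rng):
        net = make_random_network(13, rng)
        with pytest.raises(StructureError):
            brute_force_min(net, null_model(net))


class NullOrZero:
    p = 0.0


class TestAnneal:
    def test_deterministic_given_seed(self, two_clique_network):
        null = null_model(two_clique_network)
        a = anneal(two_clique_network, null, CFG, 7)
        b = anneal(two_clique_network, null, CFG, 7)
        assert a.partition == b.partition
        assert a.energy == b.energy

    def test_finds_two_clique_optimum(self, two_clique_network):
        null = null_model(two_clique_network)
        planted = Partition.from_labels([0, 0, 0, 1, 1, 1], two_clique_network.labels)
        hits = sum(
            anneal(two_clique_network, null, CFG, seed).partition == planted
            for seed in range(40)
        )
        assert hits >= 39

    def test_final_energy_not_above_initial(self, rng):
        for trial in range(10):
            net = make_random_network(8, rng)
            null = null_model(net)
            res = anneal(net, null, CFG, trial)
            assert res.energy <= res.initial_energy + 1e-12
            assert res.energy == pytest.approx(
                rb_energy(res.partition, net, null), abs=1e-9
            )

    def test_uniform_network_flagged_degenerate(self):
        w = np.full((5, 5), 0.3)
        np.fill_diagonal(w, 0.0)
        net = CorrelationNetwork(tuple("ABCDE"), w)
        res = anneal(net, null_model(net), CFG, 3)
        assert res.degenerate
        assert res.energy == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_small_networks(self, rng):
        # min over repeated trials equals the exhaustive minimum
        for trial in range(5):
            net = make_random_network(int(rng.integers(5, 10)), rng)
            null = null_model(net)
            _, e_min = brute_force_min(net, null)
            cfg = AnnealConfig(trials=30, master_seed=100 + trial)
            table = frequency_solutions(net, null, cfg)
            best = min(e.mean_energy for e in table.entries)
            assert best == pytest.approx(e_min, abs=1e-9)


class TestCanonicalization:
    @given(
        spins=st.lists(st.integers(0, 4), min_size=5, max_size=5),
        perm_seed=st.integers(0, 1000),
    )
    def test_invariant_to_index_relabeling(self, spins, perm_seed):
        labels = ("A", "B", "C", "D", "E")
        rng = np.random.default_rng(perm_seed)
        relabel = {s: int(v) for s, v in zip(set(spins), rng.permutation(100))}
        p1 = Partition.from_labels(spins, labels)
        p2 = Partition.from_labels([relabel[s] for s in spins], labels)
        assert p1 == p2

    def test_canonical_ordering_by_node_position(self):
        p = Partition.from_labels([2, 0, 2, 1], ("W", "X", "Y", "Z"))
        assert p.modules == (("W", "Y"), ("X",), ("Z",))

    def test_recanonicalizing_is_idempotent(self):
        p = Partition.from_labels([1, 0, 1, 0], ("A", "B", "C", "D"))
        again = Partition.from_assignment(p.assignment(), p.node_order)
        assert p == again

    def test_partial_cover_rejected(self):
        with pytest.raises(StructureError):
            Partition((("A",),), ("A", "B"))


class TestFrequencySolutions:
    def test_single_trial_single_entry(self, two_clique_network):
        cfg = AnnealConfig(trials=1, master_seed=5)
        table = frequency_solutions(
            two_clique_network, null_model(two_clique_network), cfg
        )
        assert len(table.entries) == 1
        assert table.entries[0].frequency == 1.0

    def test_counts_sum_to_trials(self, rng):
        net = make_random_network(7, rng, density=0.4)
        cfg = AnnealConfig(trials=37, master_seed=11)
        table = frequency_solutions(net, null_model(net), cfg)
        assert sum(e.count for e in table.entries) == 37
        assert sum(e.frequency for e in table.entries) == pytest.approx(1.0, abs=1e-12)

    def test_unambiguous_bipartition_dominates(self, two_clique_network):
        cfg = AnnealConfig(trials=100, master_seed=9)
        table = frequency_solutions(
            two_clique_network, null_model(two_clique_network), cfg
        )
        planted = Partition.from_labels([0, 0, 0, 1, 1, 1], two_clique_network.labels)
        assert table.top.partition == planted
        assert table.top.frequency >= 0.99

    def test_reproducible_given_master_seed(self, rng):
        net = make_random_network(6, rng)
        null = null_model(net)
        t1 = frequency_solutions(net, null, AnnealConfig(trials=15, master_seed=3))
        t2 = frequency_solutions(net, null, AnnealConfig(trials=15, master_seed=3))
        assert t1 == t2


class TestModuleReproducibility:
    def test_always_present_module_scores_one(self, two_clique_network):
        cfg = AnnealConfig(trials=50, master_seed=13)
        table = frequency_solutions(
            two_clique_network, null_model(two_clique_network), cfg
        )
        assert module_reproducibility(table, {"A", "B", "C"}) >= 0.99

    def test_never_occurring_module_scores_zero(self, two_clique_network):
        cfg = AnnealConfig(trials=20, master_seed=13)
        table = frequency_solutions(
            two_clique_network, null_model(two_clique_network), cfg
        )
        assert module_reproducibility(table, {"A", "D"}) == 0.0

    def test_unknown_label_rejected(self, two_clique_network):
        cfg = AnnealConfig(trials=5, master_seed=1)
        table = frequency_solutions(
            two_clique_network, null_model(two_clique_network), cfg
        )
        with pytest.raises(StructureError):
            module_reproducibility(table, {"A", "ZZZ"})


class TestIgraphCrossCheck:
    def test_agrees_with_independent_spinglass_implementation(self):
        # two 4-cliques joined by one weak edge: clear-cut structure on which
        # ER-null and configuration-null spin glasses agree
        igraph = pytest.importorskip("igraph")
        k = 8
        w = np.zeros((k, k))
        for grp in (range(4), range(4, 8)):
            for a in grp:
                for b in grp:
                    if a < b:
                        w[a, b] = w[b, a] = 1.0
        w[0, 4] = w[4, 0] = 0.2
        net = CorrelationNetwork(tuple(f"N{i}" for i in range(k)), w)
        table = frequency_solutions(
            net, null_model(net), AnnealConfig(trials=30, master_seed=21)
        )
        g = igraph.Graph.Weighted_Adjacency(w.tolist(), mode="undirected")
        ig = g.community_spinglass(weights="weight", spins=k, gamma=1.0)
        ours = table.top.partition
        theirs = Partition.from_labels(ig.membership, net.labels)
        assert ours == theirs
        assert ours.modules == (tuple(f"N{i}" for i in range(4)),
                                tuple(f"N{i}" for i in range(4, 8)))
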