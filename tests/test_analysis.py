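"""Connectivity indices, clustering, cores, epitopes and growth."""

import itertools
import math
import random

import pytest

from oglyco.analysis import (
    EPITOPE_CATALOG,
    avg_clustering,
    classify_core,
    clustering,
    core_counts,
    degree_stats,
    detect_epitopes,
    epitope_combinations,
    epitope_distribution,
    growth_series,
    indices,
)
from oglyco.simulator import Reaction, ReactionNetwork


def _net(edges, nodes=None):
    """Build a ReactionNetwork from bare (substrate, product) pairs."""
    nodes = list(nodes or [])
    net = ReactionNetwork(start=nodes[0] if nodes else "T")
    for a, b in edges:
        for x in (a, b):
            if x not in nodes:
                nodes.append(x)
    for i, n in enumerate(nodes):
        net.nodes[n] = i
        net.first_seen[n] = 0
    net.edges = [Reaction(a, 1, b, 1) for a, b in edges]
    return net


class TestIndices:
    def test_two_node_path(self):
        ix = indices(_net([("T", "VT")]))
        assert ix.beta == 0.5
        assert math.isnan(ix.alpha)  # undefined below three nodes
        assert ix.gamma == 1.0

    def test_tree_has_zero_alpha(self):
        ix = indices(_net([("a", "b"), ("a", "c"), ("b", "d")]))
        assert ix.alpha == 0.0

    def test_triangle(self):
        ix = indices(_net([("a", "b"), ("b", "c"), ("a", "c")]))
        assert ix.gamma == 1.0
        assert ix.beta == 1.0

    def test_parallel_enzyme_edges_count_once(self):
        net = _net([("a", "b")])
        net.edges.append(Reaction("a", 2, "b", 1))
        assert indices(net).beta == 0.5


class TestClustering:
    def test_single_link_between_two_neighbours(self):
        net = _net([("a", "b"), ("a", "c"), ("b", "c")])
        assert clustering(net, "a") == 0.5

    def test_degree_one_node_is_zero(self):
        net = _net([("a", "b")])
        assert clustering(net, "a") == 0.0

    def test_brute_force_equality_on_random_dags(self):
        """Mean clustering equals an O(v^3) neighbour-pair enumeration."""
        rng = random.Random(17)
        for _ in range(40):
            v = rng.randint(2, 8)
            labels = [f"n{i}" for i in range(v)]
            edges = [(labels[i], labels[j])
                     for i in range(v) for j in range(i + 1, v)
                     if rng.random() < 0.45]
            if not edges:
                continue
            net = _net(edges, nodes=labels)
            eset = set(edges)
            total = 0.0
            for n in labels:
                neigh = {b for a, b in eset if a == n} | \
                        {a for a, b in eset if b == n}
                k = len(neigh)
                if k < 2:
                    continue
                e_i = sum((a in neigh and b in neigh) for a, b in eset)
                total += e_i / (k * (k - 1))
            assert avg_clustering(net) == pytest.approx(total / v)
            for n in labels:
                neigh = {b for a, b in eset if a == n} | \
                        {a for a, b in eset if b == n}
                k = len(neigh)
                expected = 0.0 if k < 2 else sum(
                    (a in neigh and b in neigh) for a, b in eset) / (k * (k - 1))
                assert clustering(net, n) == pytest.approx(expected)

    def test_exhaustive_small_dags(self):
        """Indices agree with direct formula evaluation on every DAG
        over four ordered nodes."""
        labels = ["a", "b", "c", "d"]
        pairs = [(x, y) for i, x in enumerate(labels)
                 for y in labels[i + 1:]]
        for mask in range(1, 2 ** len(pairs)):
            edges = [p for i, p in enumerate(pairs) if mask >> i & 1]
            net = _net(edges, nodes=labels)
            v, e = 4, len(edges)
            ix = indices(net)
            assert ix.beta == pytest.approx(e / v)
            assert ix.gamma == pytest.approx(2 * e / (v * (v - 1)))
            assert ix.alpha == pytest.approx(
                (e - v + 1) / (v * (v - 1) / 2 - (v - 1)))


class TestDegrees:
    def test_path(self):
        stats = degree_stats(_net([("T", "VT")]))
        assert stats["mean_total"] == 1.0
        assert stats["mean_in"] == stats["mean_out"] == 0.5

    def test_histogram_sums_to_node_count(self, small_network):
        stats = degree_stats(small_network)
        assert sum(stats["total"].values()) == small_network.node_count

    def test_in_out_means_are_half_the_total(self, small_network):
        stats = degree_stats(small_network)
        assert stats["mean_in"] == pytest.approx(stats["mean_total"] / 2)
        assert stats["mean_out"] == pytest.approx(stats["mean_total"] / 2)


class TestCores:
    @pytest.mark.parametrize("ident, core", [
        ("[Y6][L3]VT", "core2"),
        ("[S6]VT", "unclassified"),
        ("[S6][S3L3]VT", "core1"),
        ("[Y3]VT", "core3"),
        ("[Y6][Y3]VT", "core4"),
        ("[S6][L4Y3]VT", "core3"),
        ("VT", "unclassified"),
        ("T", "unclassified"),
    ])
    def test_examples(self, ident, core):
        assert classify_core(ident) == core

    def test_unclassified_structures_are_tn_and_sialyl_tn(
            self, full_8930_network):
        unclassified = [g for g in full_8930_network.glycans()
                        if classify_core(g) == "unclassified"]
        assert set(unclassified) == {"[S6]VT", "VT"}


class TestEpitopes:
    def test_sialyl_lewis_x(self):
        assert detect_epitopes("[S3L4[f3]Y6][L3]VT") == {"sialyl-Lewis X"}

    def test_tn_carries_nothing(self):
        assert detect_epitopes("VT") == set()

    def test_lewis_b_does_not_fire_lewis_a(self):
        assert detect_epitopes("[[f2]L3[f4]Y3]VT") == {"Lewis B"}

    def test_distribution_rows_are_percentages(self, small_network):
        dist = epitope_distribution(small_network)
        assert set(dist) == set(EPITOPE_CATALOG) | {"other"}
        assert all(0.0 <= v <= 100.0 for v in dist.values())

    def test_combination_count(self):
        net = _net([("T", "VT")])
        assert epitope_combinations(net) == 0
        net2 = _net([("[L3[f4]Y3]VT", "[[f2]L3[f4]Y3]VT")])
        assert epitope_combinations(net2) == 2  # {Lewis A}, {Lewis B}


class TestGrowth:
    def test_totals_are_cumulative(self, small_network):
        gs = growth_series(small_network)
        assert gs.totals == tuple(itertools.accumulate(gs.new_structures))
        assert all(b >= a for a, b in zip(gs.totals, gs.totals[1:]))

    def test_closed_network_ends_with_zero(self):
        from oglyco.simulator import SimulationConfig, simulate

        net = simulate(SimulationConfig(max_iterations=10,
                                        enabled_enzymes=frozenset({2, 6, 14})))
        assert net.closed_at is not None
        gs = growth_series(net)
        assert gs.new_structures[-1] == 0 or net.closed_at - 1 == len(gs.new_structures)

    def test_growth_factor_on_geometric_series(self):
        net = ReactionNetwork(start="T")
        serial = 0
        for it in range(1, 6):
            for j in range(2 ** it):
                name = f"g{it}_{j}"
                net.nodes[name] = serial = serial + 1
                net.first_seen[name] = it
        net.nodes["T"] = 0
        net.first_seen["T"] = 0
        assert growth_series(net).growth_factor == pytest.approx(2.0)


class TestTables:
    def test_core_and_growth_tables(self, small_network):
        from oglyco.analysis import core_table, degree_table, growth_table

        cores = core_table(small_network)
        assert cores["count"].sum() == small_network.glycan_count
        degrees = degree_table(small_network)
        assert degrees["total"].sum() == small_network.node_count
        growth = growth_table(small_network)
        assert growth["total"].iloc[-1] == small_network.node_count - 1
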