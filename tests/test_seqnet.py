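import math

import numpy as np
import pytest

from songnet import seqnet
from songnet.song_data import recording_from_sequences

from .conftest import random_recording
from .oracles import bfs_all_pairs_mean_path, transitivity_undirected


def _edges(net):
    g = net.digraph()
    return set(g.edges)


class TestBuildNetwork:
    def test_transition_counts(self, two_song_recording):
        net = seqnet.build_network(two_song_recording)
        lab = {l: i for i, l in enumerate(net.node_labels)}
        assert net.n_nodes == 4
        assert net.weight_matrix[lab["A"], lab["B"]] == 2
        assert net.weight_matrix[lab["B"], lab["C"]] == 1
        assert net.weight_matrix[lab["B"], lab["D"]] == 1
        assert net.weight_matrix.sum() == 4  # sum of (len-1)
        assert len(_edges(net)) == 3

    def test_no_cross_song_adjacency(self):
        net = seqnet.build_network(recording_from_sequences([["A", "B"], ["C", "D"]]))
        assert _edges(net) == {("A", "B"), ("C", "D")}

    def test_self_loop_flag(self):
        rec = recording_from_sequences([["A", "A", "B"]])
        excl = seqnet.build_network(rec, include_self_loops=False)
        incl = seqnet.build_network(rec, include_self_loops=True)
        # the repetition count is always retained in the weight matrix
        for net in (excl, incl):
            i = net.node_labels.index("A")
            assert net.weight_matrix[i, i] == 1
        assert _edges(excl) == {("A", "B")}
        assert _edges(incl) == {("A", "A"), ("A", "B")}

    def test_asymmetry(self):
        net = seqnet.build_network(recording_from_sequences([["A", "B", "A"]]))
        lab = {l: i for i, l in enumerate(net.node_labels)}
        assert net.weight_matrix[lab["A"], lab["B"]] == 1
        assert net.weight_matrix[lab["B"], lab["A"]] == 1
        net2 = seqnet.build_network(recording_from_sequences([["A", "B"]]))
        lab2 = {l: i for i, l in enumerate(net2.node_labels)}
        assert net2.weight_matrix[lab2["B"], lab2["A"]] == 0

    def test_concatenation_adds_weight_matrices(self):
        rng = np.random.default_rng(11)
        r1 = random_recording(rng)
        r2 = random_recording(rng)
        combined = recording_from_sequences(
            r1.type_sequences() + r2.type_sequences()
        )
        net = seqnet.build_network(combined)
        n1 = seqnet.build_network(r1)
        n2 = seqnet.build_network(r2)
        for part in (n1, n2):
            for i, a in enumerate(part.node_labels):
                for j, b in enumerate(part.node_labels):
                    ia, ib = net.node_labels.index(a), net.node_labels.index(b)
                    other = 0
                    o = n2 if part is n1 else n1
                    if a in o.node_labels and b in o.node_labels:
                        other = o.weight_matrix[o.node_labels.index(a),
                                                o.node_labels.index(b)]
                    assert net.weight_matrix[ia, ib] == part.weight_matrix[i, j] + other


class TestMetrics:
    def test_average_degree_examples(self, two_song_recording):
        net = seqnet.build_network(two_song_recording)
        assert seqnet.average_degree(net) == pytest.approx(1.5)
        single = seqnet.build_network(recording_from_sequences([["A"]]))
        assert seqnet.average_degree(single) == 0.0
        tri = seqnet.build_network(
            recording_from_sequences([["A", "B", "A", "C", "A"], ["B", "C", "B"],
                                      ["C", "A"], ["C", "B"]])
        )
        assert seqnet.average_degree(tri) == pytest.approx(4.0)  # 2*6/3

    def test_shortest_path_examples(self, two_song_recording):
        net = seqnet.build_network(two_song_recording)
        assert seqnet.average_shortest_path(net) == pytest.approx(1.4)  # 7/5
        cyc = seqnet.build_network(recording_from_sequences([["A", "B", "A"]]))
        assert seqnet.average_shortest_path(cyc) == pytest.approx(1.0)
        lone = seqnet.build_network(recording_from_sequences([["A"], ["B"]]))
        assert math.isnan(seqnet.average_shortest_path(lone))

    def test_clustering_examples(self):
        chain = seqnet.build_network(recording_from_sequences([["A", "B", "C", "D"]]))
        assert seqnet.clustering_coefficient(chain) == 0.0
        tri = seqnet.build_network(recording_from_sequences([["A", "B", "C", "A"]]))
        assert seqnet.clustering_coefficient(tri) == pytest.approx(1.0)

    def test_small_worldness_complete_graph_closed_form(self):
        rec = recording_from_sequences(
            [["A", "B", "C", "D", "A", "C", "B", "D", "A"],
             ["D", "C", "A", "B", "D", "B", "A", "D", "C", "B"]]
        )
        net = seqnet.build_network(rec)
        # C=1, L=1, k=3, n=4: S = (1/0.75)/(1/(ln4/ln3))
        expected = (1 / 0.75) / (1 / (math.log(4) / math.log(3)))
        assert seqnet.small_worldness(net) == pytest.approx(expected, rel=1e-9)

    def test_small_worldness_zero_clustering_and_undefined(self):
        path3 = seqnet.build_network(recording_from_sequences([["A", "B", "C"]]))
        assert seqnet.small_worldness(path3) == 0.0  # mean degree 4/3, no triangle
        sparse = seqnet.build_network(recording_from_sequences([["A", "B"]]))
        assert math.isnan(seqnet.small_worldness(sparse))  # mean degree 1

    def test_montecarlo_er_agrees_with_analytic_on_er_like_net(self):
        rng = np.random.default_rng(21)
        # an unstructured random recording is close to an ER graph
        rec = random_recording(rng, n_songs=40, max_types=50, max_len=25)
        net = seqnet.build_network(rec)
        s_a = seqnet.small_worldness(net, mode="analytic-er")
        s_mc = seqnet.small_worldness(net, mode="montecarlo-er", n_random=200,
                                      rng=np.random.default_rng(7))
        assert s_mc == pytest.approx(s_a, rel=0.15)

    def test_compute_metrics_bundles(self, two_song_recording):
        m = seqnet.compute_metrics(two_song_recording)
        assert (m.repertoire_size, m.n_syllables) == (4, 6)
        assert m.average_degree == pytest.approx(1.5)
        assert m.average_shortest_path == pytest.approx(1.4)
        assert m.clustering_coefficient == 0.0
        assert m.small_worldness == 0.0

    def test_one_token_recording_degenerate(self):
        m = seqnet.compute_metrics(recording_from_sequences([["A"]]))
        assert m.repertoire_size == 1 and m.n_syllables == 1
        assert m.average_degree == 0.0
        assert math.isnan(m.average_shortest_path)


class TestOracleAgreement:
    """Path and clustering match exhaustive brute-force implementations."""

    def test_random_graphs_small(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            rec = random_recording(rng)
            net = seqnet.build_network(rec)
            edges = set(net.digraph().edges)
            oracle_path = bfs_all_pairs_mean_path(net.node_labels, edges)
            got = seqnet.average_shortest_path(net)
            if oracle_path is None:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(oracle_path)
            assert seqnet.clustering_coefficient(net) == pytest.approx(
                transitivity_undirected(net.node_labels, edges)
            )

    def test_exhaustive_tiny_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            rec = random_recording(rng, max_types=6, max_len=8)
            net = seqnet.build_network(rec)
            edges = set(net.digraph().edges)
            oracle = bfs_all_pairs_mean_path(net.node_labels, edges)
            got = seqnet.average_shortest_path(net)
            assert (oracle is None and math.isnan(got)) or got == pytest.approx(oracle)
            assert seqnet.clustering_coefficient(net) == pytest.approx(
                transitivity_undirected(net.node_labels, edges)
            )


def test_relabeling_invariance():
    rng = np.random.default_rng(3)
    rec = random_recording(rng, n_songs=6)
    mapping = {t: f"z{k}" for k, t in enumerate(rec.syllable_types)}
    relabelled = recording_from_sequences(
        [[mapping[t] for t in s] for s in rec.type_sequences()]
    )
    m1 = seqnet.compute_metrics(rec)
    m2 = seqnet.compute_metrics(relabelled)
    for attr in ("repertoire_size", "n_syllables", "average_degree",
                 "average_shortest_path", "clustering_coefficient",
                 "small_worldness"):
        a, b = getattr(m1, attr), getattr(m2, attr)
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


class TestDescriptiveStats:
    def test_enumerated_example(self, two_song_recording):
        net = seqnet.build_network(two_song_recording)
        d = seqnet.descriptive_stats(net)
        assert d.pct_nodes_degree_lt3 == pytest.approx(75.0)
        assert d.pct_edges_bidirectional == 0.0
        assert d.pct_edges_weight_gt1 == pytest.approx(100 / 3)

    def test_two_cycle_fully_bidirectional(self):
        net = seqnet.build_network(recording_from_sequences([["A", "B", "A"]]))
        assert seqnet.descriptive_stats(net).pct_edges_bidirectional == 100.0

    def test_all_weight_one(self):
        net = seqnet.build_network(recording_from_sequences([["A", "B", "C"]]))
        assert seqnet.descriptive_stats(net).pct_edges_weight_gt1 == 0.0

    def test_no_edges_undefined(self):
        net = seqnet.build_network(recording_from_sequences([["A"], ["B"]]))
        d = seqnet.descriptive_stats(net)
        assert math.isnan(d.pct_edges_bidirectional)
        assert math.isnan(d.pct_edges_weight_gt1)


def test_exports_round_trip(tmp_path, two_song_recording):
    net = seqnet.build_network(two_song_recording)
    seqnet.write_graphml(net, tmp_path / "net.graphml")
    seqnet.write_edgelist(net, tmp_path / "net.csv")
    import networkx as nx
    import pandas as pd

    g = nx.read_graphml(tmp_path / "net.graphml")
    assert set(g.edges) == set(net.digraph().edges)
    el = pd.read_csv(tmp_path / "net.csv")
    assert el["weight"].sum() == net.weight_matrix.sum()
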