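"""Directed syllable-adjacency networks and their summary variables.

A syllable network has one node per syllable type.  The weight matrix counts
how often type A is immediately followed by type B *within a song*; counts
are summed over all songs of the recording, and order matters (the matrix is
asymmetric).  Metrics are computed on the derived unweighted directed graph:

- average degree: mean total (in+out) degree, ``2E/n``;
- average shortest path: mean directed distance over reachable ordered pairs;
- clustering coefficient: global transitivity of the undirected projection;
- small-worldness: Humphries & Gurney's ``S = (C/C_rand) / (L/L_rand)`` on the
  undirected projection, against an Erdos-Renyi baseline of the same size.

Self-loop transitions (immediate repetition of a type) are always counted in
the weight matrix but excluded from the unweighted graph by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .song_data import Recording

__all__ = [
    "SyllableNetwork",
    "NetworkMetrics",
    "DescriptiveStats",
    "build_network",
    "average_degree",
    "average_shortest_path",
    "clustering_coefficient",
    "small_worldness",
    "compute_metrics",
    "descriptive_stats",
    "metrics_table",
    "write_graphml",
    "write_edgelist",
]


@dataclass(frozen=True)
class SyllableNetwork:
    """Transition-count matrix plus the derived directed unweighted graph."""

    node_labels: tuple[str, ...]
    weight_matrix: np.ndarray  # square, non-negative int; row=predecessor
    include_self_loops: bool = False

    def __post_init__(self):
        n = len(self.node_labels)
        if self.weight_matrix.shape != (n, n):
            raise ValueError("weight matrix shape does not match node labels")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def digraph(self) -> nx.DiGraph:
        """Unweighted directed graph: edge where transition count > 0."""
        g = nx.DiGraph()
        g.add_nodes_from(self.node_labels)
        rows, cols = np.nonzero(self.weight_matrix)
        for i, j in zip(rows, cols):
            if i == j and not self.include_self_loops:
                continue
            g.add_edge(self.node_labels[i], self.node_labels[j])
        return g

    def undirected(self) -> nx.Graph:
        """Undirected projection (A-B present if A->B or B->A), no self-loops."""
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        rows, cols = np.nonzero(self.weight_matrix)
        for i, j in zip(rows, cols):
            if i != j:
                g.add_edge(self.node_labels[i], self.node_labels[j])
        return g


def build_network(recording: Recording, include_self_loops: bool = False) -> SyllableNetwork:
    """Count first-order transitions within songs, summed over songs.

    No adjacency is counted across song boundaries; a single-token song
    contributes no transitions.  The total weight equals
    ``sum(len(song) - 1)`` over songs.
    """
    labels = tuple(recording.syllable_types)
    index = {lab: i for i, lab in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for song in recording.type_sequences():
        for a, b in zip(song[:-1], song[1:]):
            w[index[a], index[b]] += 1
    return SyllableNetwork(labels, w, include_self_loops)


def _n_edges(net: SyllableNetwork) -> int:
    off = np.count_nonzero(net.weight_matrix) - np.count_nonzero(
        np.diag(net.weight_matrix)
    )
    if net.include_self_loops:
        return off + int(np.count_nonzero(np.diag(net.weight_matrix)))
    return off


def average_degree(net: SyllableNetwork) -> float:
    """Mean total degree of the unweighted directed graph, ``2E/n``."""
    if net.n_nodes == 0:
        raise ValueError("network has no nodes")
    return 2.0 * _n_edges(net) / net.n_nodes


def _mean_reachable_path(g) -> float:
    """Mean shortest-path length over reachable ordered pairs u != v.

    NaN when no pair is reachable.  Averaging over reachable pairs only keeps
    the variable finite on disconnected networks (isolated chains are common
    in real song networks).
    """
    total = 0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    return total / count if count else float("nan")


def average_shortest_path(net: SyllableNetwork) -> float:
    """Mean directed distance over all reachable ordered type pairs."""
    return _mean_reachable_path(net.digraph())


def clustering_coefficient(net: SyllableNetwork) -> float:
    """Global transitivity of the undirected projection.

    3 x triangles / connected triples; 0 when no connected triple exists.
    """
    return nx.transitivity(net.undirected())


def small_worldness(
    net: SyllableNetwork,
    mode: str = "analytic-er",
    n_random: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Small-world coefficient ``S = (C/C_rand) / (L/L_rand)``.

    Computed on the undirected projection.  ``mode="analytic-er"`` uses the
    Erdos-Renyi expectations ``C_rand = k/n`` and ``L_rand = ln(n)/ln(k)``
    (k = mean degree); ``mode="montecarlo-er"`` replaces them by averages over
    ``n_random`` G(n, m) graphs with the same node and edge counts.

    Returns NaN (undefined) when the mean degree is <= 1 or the network has no
    defined path length; returns 0 when the clustering coefficient is 0.
    """
    g = net.undirected()
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n < 2:
        return float("nan")
    kbar = 2.0 * m / n
    if kbar <= 1.0:
        return float("nan")
    c = nx.transitivity(g)
    if c == 0.0:
        return 0.0
    ell = _mean_reachable_path(g)
    if not math.isfinite(ell):
        return float("nan")

    if mode == "analytic-er":
        c_rand = kbar / n
        l_rand = math.log(n) / math.log(kbar)
    elif mode == "montecarlo-er":
        rng = np.random.default_rng() if rng is None else rng
        cs, ls = [], []
        for _ in range(n_random):
            gr = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
            cs.append(nx.transitivity(gr))
            lr = _mean_reachable_path(gr)
            if math.isfinite(lr):
                ls.append(lr)
        c_rand = float(np.mean(cs))
        l_rand = float(np.mean(ls)) if ls else float("nan")
    else:
        raise ValueError(f"unknown small-worldness mode: {mode!r}")

    if not (c_rand > 0) or not math.isfinite(l_rand) or l_rand <= 0:
        return float("nan")
    return (c / c_rand) / (ell / l_rand)


@dataclass(frozen=True)
class NetworkMetrics:
    """The two classical and four network variables for one recording."""

    recording_id: str
    repertoire_size: int
    n_syllables: int
    average_degree: float
    average_shortest_path: float
    clustering_coefficient: float
    small_worldness: float


def compute_metrics(
    recording: Recording,
    include_self_loops: bool = False,
    sw_mode: str = "analytic-er",
    sw_n_random: int = 200,
    rng: np.random.Generator | None = None,
) -> NetworkMetrics:
    """Bundle all six sequence-organisation variables for one recording."""
    net = build_network(recording, include_self_loops=include_self_loops)
    return NetworkMetrics(
        recording_id=recording.recording_id,
        repertoire_size=net.n_nodes,
        n_syllables=recording.n_tokens,
        average_degree=average_degree(net),
        average_shortest_path=average_shortest_path(net),
        clustering_coefficient=clustering_coefficient(net),
        small_worldness=small_worldness(net, mode=sw_mode, n_random=sw_n_random, rng=rng),
    )


@dataclass(frozen=True)
class DescriptiveStats:
    """Percent summaries of one network's local structure."""

    recording_id: str
    pct_nodes_degree_lt3: float
    pct_edges_bidirectional: float
    pct_edges_weight_gt1: float


def descriptive_stats(net: SyllableNetwork, recording_id: str = "") -> DescriptiveStats:
    """Degree-, direction- and weight-based percentages for one network.

    - % of nodes with total degree < 3 (one or two connections);
    - % of connected unordered pairs linked in both directions;
    - % of directed edges whose transition count exceeds 1.
    """
    g = net.digraph()
    n = net.n_nodes
    degs = [g.in_degree(v) + g.out_degree(v) for v in g.nodes]
    pct_lt3 = 100.0 * sum(1 for d in degs if d < 3) / n if n else float("nan")

    w = net.weight_matrix
    fwd = w > 0
    np.fill_diagonal(fwd, False)
    pairs = fwd | fwd.T
    n_pairs = int(np.triu(pairs).sum())
    n_bidir = int(np.triu(fwd & fwd.T).sum())
    n_edges = _n_edges(net)
    if n_edges == 0:
        return DescriptiveStats(recording_id, pct_lt3, float("nan"), float("nan"))
    pct_bidir = 100.0 * n_bidir / n_pairs if n_pairs else float("nan")

    mask = w.copy()
    if not net.include_self_loops:
        np.fill_diagonal(mask, 0)
    n_gt1 = int(np.count_nonzero(mask > 1))
    pct_gt1 = 100.0 * n_gt1 / n_edges
    return DescriptiveStats(recording_id, pct_lt3, pct_bidir, pct_gt1)


def metrics_table(
    recordings: Iterable[Recording], include_self_loops: bool = False,
    sw_mode: str = "analytic-er", rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Metrics for a corpus, one row per recording, keyed by recording_id."""
    rows = []
    for rec in recordings:
        m = compute_metrics(rec, include_self_loops, sw_mode, rng=rng)
        rows.append(vars(m))
    df = pd.DataFrame(rows)
    if df.empty:
        warnings.warn("metrics_table: no recordings supplied")
    return df


def write_graphml(net: SyllableNetwork, path) -> None:
    g = net.digraph()
    for i, a in enumerate(net.node_labels):
        for j, b in enumerate(net.node_labels):
            if g.has_edge(a, b):
                g[a][b]["weight"] = int(net.weight_matrix[i, j])
    nx.write_graphml(g, path)


def write_edgelist(net: SyllableNetwork, path) -> None:
    """CSV edge list (source,target,weight) of the weight matrix."""
    rows, cols = np.nonzero(net.weight_matrix)
    df = pd.DataFrame(
        {
            "source": [net.node_labels[i] for i in rows],
            "target": [net.node_labels[j] for j in cols],
            "weight": net.weight_matrix[rows, cols],
        }
    )
    df.to_csv(path, index=False)
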