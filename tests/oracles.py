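"""Independent brute-force oracles used to validate the network metrics.

These deliberately avoid networkx and the package's own code paths: paths by
explicit breadth-first search over an adjacency dict, transitivity by direct
triangle/triple enumeration, motifs by exhaustive substring collection.
"""

from collections import deque
from itertools import combinations


def bfs_all_pairs_mean_path(nodes, edges):
    """Mean shortest directed path over reachable ordered pairs, else None."""
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
    total, count = 0, 0
    for src in nodes:
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for v, d in dist.items():
            if d > 0:
                total, count = total + d, count + 1
    return total / count if count else None


def transitivity_undirected(nodes, edges):
    """Closed connected triples / connected triples by explicit enumeration.

    Each triangle is seen once per centre node, i.e. three times, which is
    exactly the "3 x triangles" numerator of global transitivity.
    """
    und = {u: set() for u in nodes}
    for u, v in edges:
        if u != v:
            und[u].add(v)
            und[v].add(u)
    closed = 0
    triples = 0
    for centre in nodes:
        nbrs = sorted(und[centre])
        for a, b in combinations(nbrs, 2):
            triples += 1
            if b in und[a]:
                closed += 1
    return closed / triples if triples else 0.0


def brute_force_motifs(sequences, length):
    """Distinct length-L substrings occurring in >= 2 distinct songs."""
    per_song = []
    for seq in sequences:
        seq = tuple(seq)
        per_song.append({seq[i : i + length] for i in range(len(seq) - length + 1)})
    motifs = set()
    for i, si in enumerate(per_song):
        for j in range(i + 1, len(per_song)):
            motifs |= si & per_song[j]
    return motifs
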