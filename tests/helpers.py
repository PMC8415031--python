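"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, all-pairs BFS, dense
eigendecomposition, exact rational arithmetic) and shares no code with
the implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def set_partitions(items):
    """Yield every partition of ``items`` as a list of lists."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1 :]
        yield [[first]] + partial


def modularity_of_blocks(g: nx.Graph, blocks) -> float:
    """Q of a partition given as a list of node lists (aggregated form)."""
    m = g.number_of_edges()
    deg = dict(g.degree())
    q = 0.0
    for block in blocks:
        block = set(block)
        internal = sum(1 for u, v in g.edges() if u in block and v in block)
        d = sum(deg[n] for n in block)
        q += internal / m - (d / (2 * m)) ** 2
    return q


def brute_force_max_modularity(g: nx.Graph) -> float:
    """Maximum Q over every partition of the node set (graphs <= ~9 nodes)."""
    return max(modularity_of_blocks(g, blocks) for blocks in set_partitions(g.nodes))


def pair_counting_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index by explicit pair counting."""
    labels_a, labels_b = list(labels_a), list(labels_b)
    assert len(labels_a) == len(labels_b)
    n = len(labels_a)
    both = same_a = same_b = 0
    for i, j in itertools.combinations(range(n), 2):
        a = labels_a[i] == labels_a[j]
        b = labels_b[i] == labels_b[j]
        same_a += a
        same_b += b
        both += a and b
    total = comb(n, 2)
    expected = same_a * same_b / total
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


def bfs_distances(g: nx.Graph, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in g[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def closeness_by_bfs(g: nx.Graph) -> dict:
    """cc_i = (r_i - 1) / sum of BFS distances over the reachable set."""
    out = {}
    for node in g:
        dist = bfs_distances(g, node)
        total = sum(dist.values())
        out[node] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def eigenvector_by_dense_eig(g: nx.Graph) -> dict:
    """Dominant adjacency eigenvector via numpy.linalg.eigh, L2-normalized, >= 0."""
    nodes = sorted(g, key=str)
    a = nx.to_numpy_array(g, nodelist=nodes)
    vals, vecs = np.linalg.eigh(a)
    vec = vecs[:, np.argmax(vals)]
    if vec.sum() < 0:
        vec = -vec
    vec = np.abs(vec)  # Perron vector of the dominant component is non-negative
    vec /= np.linalg.norm(vec)
    return dict(zip(nodes, vec))


def exact_hypergeom_tail(n_universe: int, k_set: int, n_module: int, overlap: int) -> Fraction:
    """P(X >= overlap) for X ~ Hypergeometric(N, K, n), exact rational."""
    denom = comb(n_universe, n_module)
    num = sum(
        comb(k_set, x) * comb(n_universe - k_set, n_module - x)
        for x in range(overlap, min(k_set, n_module) + 1)
    )
    return Fraction(num, denom)


def bh_stepup_by_hand(pvals) -> list[float]:
    """BH adjusted q-values by the textbook step-up recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out
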