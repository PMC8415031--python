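"""Module detection by Louvain modularity optimization and qs-test significance.

Modularity of a partition of an undirected simple graph is

    Q = (1 / 2m) * sum_ij [ A_ij - d_i d_j / 2m ] * delta(c_i, c_j)

which aggregates per community c to  sum_c [ m_c / m - (D_c / 2m)^2 ],
with m_c the internal edge count and D_c the summed degree of c.  Both
forms are implemented and must agree to machine precision.

The Louvain optimizer follows the classic two-phase scheme: repeated
seed-shuffled sweeps of single-node moves taking the best strictly
positive modularity gain (ties broken toward the smallest community
label), then aggregation of communities into super-nodes, iterated until
no sweep improves Q.  It is deterministic given its seed.

Module significance uses the qs-test: the observed module quality q_M is
compared against the (q, s) pool of modules detected in degree-preserving
randomizations of the graph, conditioning on comparable size s (summed
member degree) via a +/-10% window that doubles until at least 50 null
draws are available.  The add-one empirical p-value is compared to a
Sidak-corrected level across the detected modules.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Partition",
    "ModuleStats",
    "modularity",
    "modularity_pairwise",
    "module_quality",
    "module_size",
    "louvain",
    "rewire_degree_preserving",
    "qs_test",
]


@dataclass
class Partition:
    """Node-to-community assignment with its modularity Q.

    Community labels are contiguous integers 0..C-1, ordered by each
    community's smallest member (string order of node names).
    """

    assignment: dict[Hashable, int]
    q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


@dataclass
class ModuleStats:
    """qs-test result for one detected module."""

    label: int
    n_nodes: int
    quality: float  # q_M: the module's additive modularity term
    size: int  # s_M: summed member degree
    p_value: float
    significant: bool
    n_null: int  # null draws inside the final size window
    window_empty: bool = False


def _check_cover(g: nx.Graph, assignment: dict) -> None:
    nodes = set(g.nodes)
    assigned = set(assignment)
    if nodes - assigned:
        raise ValueError(f"nodes missing from assignment: {sorted(map(str, nodes - assigned))[:5]}")


def modularity(g: nx.Graph, assignment: dict) -> float:
    """Q in the per-community aggregated form sum_c [m_c/m - (D_c/2m)^2]."""
    _check_cover(g, assignment)
    m = g.number_of_edges()
    if m < 1:
        raise ValueError("modularity requires at least one edge")
    m_c: dict[int, int] = {}
    d_c: dict[int, int] = {}
    for node, deg in g.degree():
        c = assignment[node]
        d_c[c] = d_c.get(c, 0) + deg
    for u, v in g.edges():
        if assignment[u] == assignment[v]:
            c = assignment[u]
            m_c[c] = m_c.get(c, 0) + 1
    two_m = 2.0 * m
    return sum(m_c.get(c, 0) / m - (d_c[c] / two_m) ** 2 for c in d_c)


def modularity_pairwise(g: nx.Graph, assignment: dict) -> float:
    """Q by the literal double sum over ordered node pairs (reference form)."""
    _check_cover(g, assignment)
    m = g.number_of_edges()
    if m < 1:
        raise ValueError("modularity requires at least one edge")
    nodes = list(g.nodes)
    deg = dict(g.degree())
    two_m = 2.0 * m
    total = 0.0
    for i in nodes:
        for j in nodes:
            if assignment[i] != assignment[j]:
                continue
            a_ij = 1.0 if g.has_edge(i, j) and i != j else 0.0
            total += a_ij - deg[i] * deg[j] / two_m
    return total / two_m


def module_quality(g: nx.Graph, member_nodes: Iterable[Hashable]) -> float:
    """q_M = m_M/m - (D_M/2m)^2: one module's additive term of aggregated Q."""
    members = set(member_nodes)
    if not members:
        raise ValueError("module must be nonempty")
    if members - set(g.nodes):
        raise ValueError("module contains nodes outside the graph")
    m = g.number_of_edges()
    if m < 1:
        raise ValueError("module quality requires a graph with edges")
    internal = sum(1 for u, v in g.edges(members) if u in members and v in members)
    d_m = sum(d for _, d in g.degree(members))
    return internal / m - (d_m / (2.0 * m)) ** 2


def module_size(g: nx.Graph, member_nodes: Iterable[Hashable]) -> int:
    """s_M: sum of the (whole-graph) degrees of the module's members."""
    return int(sum(d for _, d in g.degree(set(member_nodes))))


# ---------------------------------------------------------------------------
# Louvain


def _one_level(
    adj: list[dict[int, float]],
    loops: list[float],
    m2: float,
    rng: random.Random,
    resolution: float = 1.0,
) -> tuple[list[int], bool]:
    """One local-move phase; returns (community labels, improved?).

    Moves are accepted only on a strictly positive gain over staying put;
    gain ties between candidate communities break toward the smallest label.
    """
    n = len(adj)
    k = [sum(adj[i].values()) + 2.0 * loops[i] for i in range(n)]
    comm = list(range(n))
    sigma = k[:]  # summed degree per community
    improved = False
    order = list(range(n))
    moved = True
    eps = 1e-12
    while moved:
        moved = False
        rng.shuffle(order)
        for u in order:
            cu = comm[u]
            w_to: dict[int, float] = {}
            for v, w in adj[u].items():
                cv = comm[v]
                w_to[cv] = w_to.get(cv, 0.0) + w
            sigma[cu] -= k[u]
            stay_gain = w_to.get(cu, 0.0) - resolution * k[u] * sigma[cu] / m2
            best_c, best_gain = cu, stay_gain
            for c in sorted(w_to):
                if c == cu:
                    continue
                gain = w_to[c] - resolution * k[u] * sigma[c] / m2
                if gain > best_gain + eps or (
                    abs(gain - best_gain) <= eps and best_c != cu and c < best_c
                ):
                    best_c, best_gain = c, gain
            sigma[best_c] += k[u]
            if best_c != cu:
                comm[u] = best_c
                moved = True
                improved = True
    return comm, improved


def _aggregate(
    adj: list[dict[int, float]],
    loops: list[float],
    comm: Sequence[int],
) -> tuple[list[dict[int, float]], list[float], dict[int, int]]:
    labels = sorted(set(comm))
    relabel = {c: i for i, c in enumerate(labels)}
    n2 = len(labels)
    new_adj: list[dict[int, float]] = [dict() for _ in range(n2)]
    new_loops = [0.0] * n2
    for u in range(len(adj)):
        cu = relabel[comm[u]]
        new_loops[cu] += loops[u]
        for v, w in adj[u].items():
            if v < u:
                continue  # each undirected edge once
            cv = relabel[comm[v]]
            if cu == cv:
                new_loops[cu] += w
            else:
                new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
                new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
    return new_adj, new_loops, relabel


def louvain(g: nx.Graph, seed: int = 0, resolution: float = 1.0) -> Partition:
    """Two-phase Louvain optimization of modularity, deterministic given seed.

    ``resolution`` rescales the null term of the gain; the canonical
    quality function corresponds to resolution 1, which is what the final
    reported Q always uses.
    """
    nodes = sorted(g.nodes, key=str)
    if g.number_of_edges() == 0:
        warnings.warn("graph has no edges: every node is its own community, Q = 0", stacklevel=2)
        return Partition({n: i for i, n in enumerate(nodes)}, 0.0)
    index = {n: i for i, n in enumerate(nodes)}
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    # index-sorted edge list makes the walk independent of insertion order
    for i, j in sorted((min(index[u], index[v]), max(index[u], index[v])) for u, v in g.edges()):
        if i == j:
            continue
        adj[i][j] = adj[i].get(j, 0.0) + 1.0
        adj[j][i] = adj[j].get(i, 0.0) + 1.0
    loops = [0.0] * len(nodes)
    m2 = 2.0 * g.number_of_edges()
    rng = random.Random(int(seed))

    membership = list(range(len(nodes)))  # original index -> current super-node
    while True:
        comm, improved = _one_level(adj, loops, m2, rng, float(resolution))
        if not improved:
            break
        adj, loops, relabel = _aggregate(adj, loops, comm)
        membership = [relabel[comm[s]] for s in membership]

    # contiguous labels ordered by smallest member (in string node order)
    first_seen: dict[int, int] = {}
    for i, _ in enumerate(nodes):
        c = membership[i]
        if c not in first_seen:
            first_seen[c] = len(first_seen)
    assignment = {nodes[i]: first_seen[membership[i]] for i in range(len(nodes))}
    return Partition(assignment, modularity(g, assignment))


# ---------------------------------------------------------------------------
# Null model and qs-test


def rewire_degree_preserving(g: nx.Graph, n_swaps: int | None = None, seed: int = 0) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``n_swaps`` swaps (default 10 * m) rejecting self-loops and
    multi-edges; the degree sequence is preserved exactly.  If the graph
    admits no legal swap it is returned unchanged with a warning.
    """
    h = g.copy()
    m = h.number_of_edges()
    if m < 2 or h.number_of_nodes() < 4:
        warnings.warn("graph too small to rewire; returned unchanged", stacklevel=2)
        return h
    if n_swaps is None:
        n_swaps = 10 * m
    try:
        nx.double_edge_swap(h, nswap=n_swaps, max_tries=max(100, 20 * n_swaps), seed=int(seed))
    except nx.NetworkXError as err:
        warnings.warn(f"rewiring stopped early: {err}", stacklevel=2)
    return h


def qs_test(
    g: nx.Graph,
    partition: Partition,
    n_rand: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    size_window: float = 0.10,
    min_null: int = 50,
) -> list[ModuleStats]:
    """qs-test: empirical significance of each detected module.

    For each of ``n_rand`` degree-preserving randomizations, Louvain is
    re-run and every detected module contributes a (quality, size) draw
    to the null pool.  An observed module with quality q_M and size s_M
    gets  p = (1 + #{null: s in window, q >= q_M}) / (1 + #{null in
    window}),  where the size window starts at +/-``size_window``
    (relative) and doubles until it holds at least ``min_null`` draws or
    spans the whole pool.  Significance compares p to the Sidak level
    1 - (1 - alpha)^(1/C) for C observed modules.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    comms = partition.communities()
    if not comms:
        return []
    rng = random.Random(int(seed))
    null_q: list[float] = []
    null_s: list[int] = []
    for _ in range(int(n_rand)):
        s_rewire = rng.randrange(2**31)
        s_louvain = rng.randrange(2**31)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = rewire_degree_preserving(g, seed=s_rewire)
        p_null = louvain(h, seed=s_louvain)
        for members in p_null.communities():
            null_q.append(module_quality(h, members))
            null_s.append(module_size(h, members))
    nq = np.asarray(null_q)
    ns = np.asarray(null_s, dtype=float)
    s_min, s_max = (float(ns.min()), float(ns.max())) if len(ns) else (0.0, 0.0)

    c_obs = len(comms)
    alpha_prime = 1.0 - (1.0 - alpha) ** (1.0 / c_obs)
    # The window must hold enough null draws for the add-one estimator to
    # resolve the working level: with n draws the smallest attainable p is
    # 1/(1+n), so n must reach 1/alpha_prime for the test to have any power.
    min_null = max(int(min_null), math.ceil(1.0 / alpha_prime))
    stats: list[ModuleStats] = []
    for label, members in enumerate(comms):
        q_m = module_quality(g, members)
        s_m = module_size(g, members)
        window = float(size_window)
        in_window = np.zeros(0, dtype=bool)
        while True:
            lo, hi = s_m * (1.0 - window), s_m * (1.0 + window)
            in_window = (ns >= lo) & (ns <= hi) if len(ns) else np.zeros(0, dtype=bool)
            if int(in_window.sum()) >= min_null or (lo <= s_min and hi >= s_max):
                break
            window *= 2.0
        n_in = int(in_window.sum())
        if n_in == 0:
            stats.append(
                ModuleStats(label, len(members), q_m, s_m, 1.0, False, 0, window_empty=True)
            )
            continue
        n_ge = int((nq[in_window] >= q_m).sum())
        p = (1.0 + n_ge) / (1.0 + n_in)
        stats.append(ModuleStats(label, len(members), q_m, s_m, p, p < alpha_prime, n_in))
    return stats
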