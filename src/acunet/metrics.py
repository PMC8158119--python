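"""Centrality and community structure, implemented from first principles.

Degree/strength, Brandes betweenness, Newman modularity with a resolution
parameter, two-phase Louvain partitioning, and an exhaustive modularity
oracle for small graphs.  All procedures are deterministic by default: the
Louvain sweep follows a fixed node order unless a seeded-random policy is
requested.
"""

from __future__ import annotations

import heapq
import itertools
import random
from collections import deque
from dataclasses import dataclass

import pandas as pd

from .errors import RefusalError, ValidationError
from .network import WeightedGraph

ORDER_POLICIES = ("node-order", "lexicographic", "seeded-random")


@dataclass
class CommunityPartition:
    """Node -> community assignment with its modularity score.

    Community ids are contiguous from 0, numbered by each community's
    first node in graph node order.
    """

    assignment: dict[str, int]
    Q: float
    gamma: float = 1.0

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return [out[c] for c in sorted(out)]


# -- degree and strength --------------------------------------------------

def degree_centrality(g: WeightedGraph) -> pd.DataFrame:
    """Unweighted degree k_i and strength s_i (sum of incident weights)."""
    return pd.DataFrame(
        {"degree": [g.degree(u) for u in g.nodes],
         "strength": [g.strength(u) for u in g.nodes]},
        index=pd.Index(g.nodes, name="node"),
    )


# -- betweenness (Brandes) ------------------------------------------------

def betweenness_centrality(g: WeightedGraph, use_weights: bool = False) -> pd.DataFrame:
    """Betweenness b_v = sum over pairs s<t of sigma_st(v) / sigma_st.

    Unweighted mode counts BFS hops; weighted mode runs Dijkstra on the
    dissimilarity d = 1 - p (every edge must then have p < 1).  The
    normalized column divides the raw pair count by (n-1)(n-2)/2, the
    number of pairs that could route through a given vertex.
    """
    if use_weights:
        for u, v, w in g.edges():
            if 1.0 - w <= 0:
                raise ValidationError(
                    f"edge ({u}, {v}) has non-positive dissimilarity 1 - {w}"
                )
    b = dict.fromkeys(g.nodes, 0.0)
    for s in g.nodes:
        sigma = dict.fromkeys(g.nodes, 0.0)
        sigma[s] = 1.0
        dist: dict[str, float] = {}
        preds: dict[str, list[str]] = {u: [] for u in g.nodes}
        stack: list[str] = []
        if not use_weights:
            dist[s] = 0
            queue = deque([s])
            while queue:
                v = queue.popleft()
                stack.append(v)
                for w_node in g.neighbors(v):
                    if w_node not in dist:
                        dist[w_node] = dist[v] + 1
                        queue.append(w_node)
                    if dist[w_node] == dist[v] + 1:
                        sigma[w_node] += sigma[v]
                        preds[w_node].append(v)
        else:
            seen = {s: 0.0}
            heap = [(0.0, g.rank[s], s)]
            while heap:
                d, _, v = heapq.heappop(heap)
                if v in dist:
                    continue
                dist[v] = d
                stack.append(v)
                for w_node, p in g.neighbors(v).items():
                    nd = d + (1.0 - p)
                    if w_node not in dist and (w_node not in seen or nd < seen[w_node] - 1e-15):
                        seen[w_node] = nd
                        sigma[w_node] = sigma[v]
                        preds[w_node] = [v]
                        heapq.heappush(heap, (nd, g.rank[w_node], w_node))
                    elif w_node not in dist and abs(nd - seen[w_node]) <= 1e-15:
                        sigma[w_node] += sigma[v]
                        preds[w_node].append(v)
        delta = dict.fromkeys(g.nodes, 0.0)
        while stack:
            w_node = stack.pop()
            for v in preds[w_node]:
                delta[v] += sigma[v] / sigma[w_node] * (1.0 + delta[w_node])
            if w_node != s:
                b[w_node] += delta[w_node]
    n = g.n_nodes
    raw = pd.Series(b).loc[g.nodes] / 2.0  # each unordered pair counted twice
    denom = (n - 1) * (n - 2) / 2.0
    norm = raw / denom if denom > 0 else raw * 0.0
    return pd.DataFrame({"betweenness_raw": raw, "betweenness_norm": norm},
                        index=pd.Index(g.nodes, name="node"))


def centrality_table(g: WeightedGraph, use_weights_betweenness: bool = False) -> pd.DataFrame:
    """Combined degree/strength/betweenness table, one row per node."""
    return degree_centrality(g).join(
        betweenness_centrality(g, use_weights=use_weights_betweenness))


# -- modularity -----------------------------------------------------------

def _edge_stats(g: WeightedGraph, use_weights: bool):
    if use_weights:
        m = g.total_weight()
        strength = {u: g.strength(u) for u in g.nodes}
        wfun = g.weight
    else:
        m = float(g.n_edges)
        strength = {u: float(g.degree(u)) for u in g.nodes}
        wfun = lambda u, v: 1.0
    return m, strength, wfun


def modularity(g: WeightedGraph, partition: dict[str, int], gamma: float = 1.0,
               use_weights: bool = True) -> float:
    """Newman modularity Q of a partition, with resolution gamma.

    Q = (1/2m) * sum_ij [A_ij - gamma * k_i k_j / 2m] delta(c_i, c_j),
    using strengths for k and total edge weight for m when ``use_weights``.
    """
    missing = set(g.nodes) - set(partition)
    if missing:
        raise ValidationError(f"partition does not cover nodes: {sorted(missing)}")
    m, strength, wfun = _edge_stats(g, use_weights)
    if m == 0:
        raise ValidationError("modularity undefined on an edgeless graph")
    w_in: dict[int, float] = {}
    s_tot: dict[int, float] = {}
    for u in g.nodes:
        s_tot[partition[u]] = s_tot.get(partition[u], 0.0) + strength[u]
    for u, v, _ in g.edges():
        if partition[u] == partition[v]:
            w_in[partition[u]] = w_in.get(partition[u], 0.0) + wfun(u, v)
    return sum(w_in.get(c, 0.0) / m - gamma * (s_tot[c] / (2.0 * m)) ** 2
               for c in s_tot)


def _relabel(g: WeightedGraph, assignment: dict[str, int]) -> dict[str, int]:
    """Contiguous community ids, numbered by first member in node order."""
    mapping: dict[int, int] = {}
    for u in g.nodes:
        c = assignment[u]
        if c not in mapping:
            mapping[c] = len(mapping)
    return {u: mapping[assignment[u]] for u in g.nodes}


# -- Louvain --------------------------------------------------------------

def _louvain_once(g: WeightedGraph, gamma: float, use_weights: bool,
                  order_policy: str, rng: random.Random | None) -> dict[str, int]:
    m, strength0, wfun = _edge_stats(g, use_weights)
    # working copy on integer ids; aggregated rounds reuse the same routine
    nodes = list(range(g.n_nodes))
    if order_policy == "lexicographic":
        base_order = sorted(range(g.n_nodes), key=lambda i: g.nodes[i])
    else:
        base_order = nodes[:]
    adj = [dict() for _ in nodes]
    for u, v, w in g.edges():
        iu, iv = g.rank[u], g.rank[v]
        val = w if use_weights else 1.0
        adj[iu][iv] = adj[iu].get(iv, 0.0) + val
        adj[iv][iu] = adj[iv].get(iu, 0.0) + val
    self_w = [0.0] * len(nodes)
    strength = [strength0[g.nodes[i]] for i in nodes]
    membership = list(range(g.n_nodes))  # original node -> current community
    current = nodes[:]                   # current-level node ids
    order = base_order[:]
    two_m = 2.0 * m

    while True:
        if rng is not None:
            rng.shuffle(order)
        comm = {i: i for i in current}
        s_tot = {i: strength[i] + self_w[i] * 0 for i in current}
        # community totals: sum of strengths (incl. self-loop weight already in strength)
        improved_level = False
        moved = True
        while moved:
            moved = False
            for i in order:
                ci = comm[i]
                k_i = strength[i]
                # links from i to neighbouring communities
                links: dict[int, float] = {}
                for j, w in adj[i].items():
                    links[comm[j]] = links.get(comm[j], 0.0) + w
                s_tot[ci] -= k_i
                best_c, best_gain = ci, links.get(ci, 0.0) - gamma * k_i * s_tot[ci] / two_m
                for c, k_in in sorted(links.items()):
                    if c == ci:
                        continue
                    gain = k_in - gamma * k_i * s_tot[c] / two_m
                    if gain > best_gain + 1e-12:
                        best_c, best_gain = c, gain
                s_tot[best_c] = s_tot.get(best_c, 0.0) + k_i
                if best_c != ci:
                    comm[i] = best_c
                    moved = True
                    improved_level = True
        if not improved_level:
            break
        # aggregation: communities become nodes, ordered by first member
        new_ids: dict[int, int] = {}
        for i in current:
            c = comm[i]
            if c not in new_ids:
                new_ids[c] = len(new_ids)
        membership = [new_ids[comm[membership[k]]] for k in range(g.n_nodes)]
        n_new = len(new_ids)
        new_adj = [dict() for _ in range(n_new)]
        new_self = [0.0] * n_new
        new_strength = [0.0] * n_new
        for i in current:
            ci = new_ids[comm[i]]
            new_self[ci] += self_w[i]
            new_strength[ci] += strength[i]
            for j, w in adj[i].items():
                cj = new_ids[comm[j]]
                if ci == cj:
                    new_self[ci] += w / 2.0
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
        current = list(range(n_new))
        adj, self_w, strength = new_adj, new_self, new_strength
        order = current[:]
    return {g.nodes[k]: membership[k] for k in range(g.n_nodes)}


def louvain_partition(g: WeightedGraph, gamma: float = 1.0,
                      use_weights: bool = True,
                      order_policy: str = "node-order",
                      seed: int | None = None,
                      restarts: int = 1) -> CommunityPartition:
    """Two-phase Louvain modularity maximization.

    ``order_policy`` fixes the local-moving sweep order: ``node-order``
    (graph node list; default, fully deterministic), ``lexicographic``
    (sorted labels), or ``seeded-random`` (shuffled per pass from ``seed``,
    with ``restarts`` independent runs keeping the best-Q partition, first
    found on ties).
    """
    if order_policy not in ORDER_POLICIES:
        raise ValidationError(f"unknown order policy {order_policy!r}; expected {ORDER_POLICIES}")
    if g.n_edges == 0:
        raise ValidationError("Louvain requires a graph with at least one edge")
    runs = restarts if order_policy == "seeded-random" else 1
    best: CommunityPartition | None = None
    for r in range(runs):
        rng = random.Random((seed or 0) + r) if order_policy == "seeded-random" else None
        assignment = _louvain_once(g, gamma, use_weights, order_policy, rng)
        assignment = _relabel(g, assignment)
        q = modularity(g, assignment, gamma=gamma, use_weights=use_weights)
        if best is None or q > best.Q + 1e-12:
            best = CommunityPartition(assignment, q, gamma)
    return best


# -- exhaustive oracle ----------------------------------------------------

def _set_partitions(items: list[str]):
    """All set partitions (Bell-number enumeration) of ``items``."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def brute_force_modularity_max(g: WeightedGraph, gamma: float = 1.0,
                               use_weights: bool = True) -> CommunityPartition:
    """Test oracle: exhaustive maximum-modularity partition for <= 10 nodes.

    The search is restricted to partitions whose communities are connected
    in ``g`` (an optimal modularity partition always has connected
    communities when all weights are positive).
    """
    if g.n_nodes > 10:
        raise RefusalError(f"exhaustive modularity search limited to 10 nodes, got {g.n_nodes}")
    if g.n_edges == 0:
        raise ValidationError("modularity undefined on an edgeless graph")

    def connected(block: list[str]) -> bool:
        block_set = set(block)
        seen = {block[0]}
        stack = [block[0]]
        while stack:
            u = stack.pop()
            for v in g.neighbors(u):
                if v in block_set and v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == len(block)

    best_q, best_assign = None, None
    for part in _set_partitions(list(g.nodes)):
        if not all(connected(b) for b in part):
            continue
        assignment = {u: ci for ci, block in enumerate(part) for u in block}
        q = modularity(g, assignment, gamma=gamma, use_weights=use_weights)
        if best_q is None or q > best_q + 1e-12:
            best_q, best_assign = q, assignment
    best_assign = _relabel(g, best_assign)
    return CommunityPartition(best_assign, best_q, gamma)
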