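"""Shared fixtures and brute-force helpers for the test suite."""

from __future__ import annotations

import itertools
import string

import numpy as np
import pytest

from acunet import WeightedGraph, builtin_table2, run_network_pipeline


@pytest.fixture(scope="session")
def table2():
    return builtin_table2()


@pytest.fixture(scope="session")
def network_report():
    """Default-configuration network pipeline on the packaged corpus."""
    return run_network_pipeline()


def random_graph(rng: np.random.Generator, n_nodes: int,
                 edge_prob: float = 0.5, connected: bool = True) -> WeightedGraph:
    """Random weighted graph on sorted single-letter nodes.

    Weights are drawn from a coarse grid so ties occur regularly, which
    exercises the deterministic tie-breaking rules.
    """
    nodes = list(string.ascii_uppercase[:n_nodes])
    g = WeightedGraph(nodes)
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < edge_prob:
            g.add_edge(u, v, float(rng.choice([0.1, 0.2, 0.3, 0.5, 0.7, 0.9])))
    if connected:
        comps = g.connected_components()
        for comp in comps[1:]:
            g.add_edge(comps[0][0], comp[0], float(rng.choice([0.1, 0.5, 0.9])))
    return g


def betweenness_by_enumeration(g: WeightedGraph, use_weights: bool = False):
    """Independent betweenness oracle: enumerate every simple path between
    every node pair, keep the shortest, and count pass-throughs."""
    def all_simple_paths(s, t):
        paths = []
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nbr in g.neighbors(node):
                if nbr not in path:
                    stack.append((nbr, path + [nbr]))
        return paths

    def length(path):
        if use_weights:
            return sum(1.0 - g.weight(a, b) for a, b in zip(path, path[1:]))
        return len(path) - 1

    raw = dict.fromkeys(g.nodes, 0.0)
    for s, t in itertools.combinations(g.nodes, 2):
        paths = all_simple_paths(s, t)
        if not paths:
            continue
        best = min(length(p) for p in paths)
        shortest = [p for p in paths if length(p) <= best + 1e-12]
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            raw[v] += through / len(shortest)
    return raw
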