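"""Shared fixtures and the independent brute-force path/chi oracle."""

from __future__ import annotations

import itertools
import math
import random

import networkx as nx
import pytest

from chelstab import chi_table, load_experimental_table
from chelstab.chi import graph_deltas


@pytest.fixture(scope="session")
def records():
    return load_experimental_table()


@pytest.fixture(scope="session")
def chi():
    """Connectivity indices for the full metal x ligand x species grid."""
    return chi_table()


def brute_force_paths(g: nx.Graph, n: int) -> set[tuple]:
    """Oracle: test every (n+1)-tuple of distinct vertices for path-ness.

    Independent of the package's DFS enumeration; O(V^(n+1)) but fine
    for the small graphs used in tests.
    """
    paths = set()
    for tup in itertools.permutations(g.nodes(), n + 1):
        if all(g.has_edge(a, b) for a, b in zip(tup, tup[1:])):
            rev = tuple(reversed(tup))
            paths.add(min(tup, rev, key=lambda p: tuple(map(str, p))))
    return paths


def brute_force_chi(g: nx.Graph, n: int, decimals=3) -> float:
    """Oracle chi: sum reciprocal-sqrt delta products over oracle paths."""
    deltas = graph_deltas(g, decimals)
    total = 0.0
    for path in brute_force_paths(g, n):
        prod = 1.0
        for node in path:
            prod *= deltas[node]
        total += 1.0 / math.sqrt(prod)
    return total


def random_molecular_graph(rng: random.Random, max_nodes: int = 10) -> nx.Graph:
    """Random connected graph with chemically plausible vertex weights."""
    n = rng.randint(2, max_nodes)
    while True:
        g = nx.gnp_random_graph(n, rng.uniform(0.25, 0.7), seed=rng.randint(0, 2**31 - 1))
        if nx.is_connected(g):
            break
    elements = [("C", 6, 4), ("N", 7, 5), ("O", 8, 6), ("Ni", 28, 10), ("Mn", 25, 7)]
    for node in g.nodes():
        element, Z, Zv = rng.choice(elements)
        max_h = max(0, Zv - g.degree(node) - 1) if Z > 8 else max(0, min(Zv - 1, 3))
        g.nodes[node].update(
            element=element, Z=Z, Zv=Zv, nH=rng.randint(0, max_h) if Z <= 8 else 0
        )
    return g
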