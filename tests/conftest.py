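import networkx as nx
import numpy as np
import pytest

import songnet as sn


@pytest.fixture
def tiny_corpus():
    """Hand-checkable corpus: two bouts, repeats, a reversible transition."""
    return sn.corpus_from_bouts([["1", "2", "3", "1"], ["2", "4", "4", "2"]])


@pytest.fixture
def walk_corpus():
    """Mid-sized synthetic corpus from a planted small-world digraph."""
    graph = sn.planted_graph(
        sn.PlantedGraphSpec(n=40, k=4, beta=0.1, directed=True, seed=7)
    )
    return sn.random_walk_song(
        sn.WalkSpec(graph=graph, length=1500, n_bouts=5, restart=0.05, seed=8)
    )


def random_connected_graph(rng: np.random.Generator, max_n: int = 12) -> nx.Graph:
    """Small random connected graph for oracle-equivalence batteries."""
    n = int(rng.integers(3, max_n + 1))
    while True:
        p = float(rng.uniform(0.2, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return g


def brute_force_L(g: nx.Graph | nx.DiGraph) -> float:
    """Mean shortest-path length over reachable ordered pairs, by plain BFS."""
    lengths = []
    for src in g.nodes():
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                succ = g.successors(u) if g.is_directed() else g.neighbors(u)
                for v in succ:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        lengths.extend(d for node, d in dist.items() if node != src)
    return sum(lengths) / len(lengths)


def brute_force_C(g: nx.Graph) -> float:
    """Average clustering by direct neighbour-pair counting."""
    total = 0.0
    for node in g.nodes():
        nbrs = list(g.neighbors(node))
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if g.has_edge(nbrs[i], nbrs[j])
        )
        total += links / (k * (k - 1) / 2)
    return total / g.number_of_nodes()
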