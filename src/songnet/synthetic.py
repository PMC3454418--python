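"""Synthetic song corpora with known ground truth.

Real corpora of this kind (a single bird, ~50-200 phrase types, a few
thousand phrase tokens) are rarely public, so the test surface is built on
*planted* transition graphs and random walks over them:

* ``planted_graph`` builds a Watts-Strogatz-style ring lattice with
  probabilistic rewiring. At beta = 0 the pure lattice has high clustering
  and long paths; small beta yields small-world structure (the regime the
  pipeline must detect); beta = 1 approaches an Erdos-Renyi random graph.
  The directed variant gives each lattice edge both directions before
  rewiring arcs independently.
* ``random_walk_song`` emits a phrase-label corpus by a uniform random walk
  on a planted digraph with a teleport (restart) probability. A teleport
  models the end of one bout and the start of the next, so it breaks the
  bout rather than recording a spurious transition; sufficiently long walks
  on strongly connected graphs therefore reconstruct the planted arc set
  exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .construction import SongDigraph, SongNetwork
from .corpus import Bout, SongCorpus
from .nulls import _rng

__all__ = [
    "PlantedGraphSpec",
    "WalkSpec",
    "GenerationError",
    "planted_graph",
    "random_walk_song",
]


class GenerationError(RuntimeError):
    """A walk could not proceed (dead-end node with no teleport)."""


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Ring-lattice-plus-rewiring graph parameters.

    n nodes on a ring, each joined to its k nearest neighbours (k even),
    then each edge rewired with probability beta.
    """

    n: int
    k: int
    beta: float
    directed: bool = False
    seed: int | None = None


@dataclass(frozen=True)
class WalkSpec:
    """Random-walk song parameters over a planted digraph.

    restart is the per-step probability of teleporting to a uniform node,
    which starts a new bout; n_bouts additionally splits the token stream
    into that many contiguous chunks (scheduled recording breaks), so the
    emitted corpus has at least n_bouts bouts.
    """

    graph: SongDigraph
    length: int
    n_bouts: int = 1
    restart: float = 0.0
    seed: int | None = None
    start: str | None = None


def _validate(spec: PlantedGraphSpec) -> None:
    if spec.k >= spec.n:
        raise ValueError(f"need k < n, got k={spec.k}, n={spec.n}")
    if spec.k < 2 or spec.k % 2:
        raise ValueError(f"k must be even and >= 2, got {spec.k}")
    if not 0 <= spec.beta <= 1:
        raise ValueError(f"beta must be in [0, 1], got {spec.beta}")


def planted_graph(spec: PlantedGraphSpec) -> SongNetwork | SongDigraph:
    """Watts-Strogatz-style planted graph; nodes are labelled "0".."n-1"."""
    _validate(spec)
    rng = _rng(spec.seed)
    if not spec.directed:
        g = nx.watts_strogatz_graph(
            spec.n, spec.k, spec.beta, seed=int(rng.integers(2**31))
        )
        g = nx.relabel_nodes(g, {i: str(i) for i in g.nodes()})
        return SongNetwork(g)

    # directed: both arc directions on every lattice edge, then independent
    # arc rewiring (keep the source, draw a fresh non-duplicate target)
    lattice = nx.watts_strogatz_graph(spec.n, spec.k, 0)
    g = nx.DiGraph()
    g.add_nodes_from(str(i) for i in range(spec.n))
    arcs = [(u, v) for u, v in lattice.edges()] + [
        (v, u) for u, v in lattice.edges()
    ]
    arc_set = {(str(u), str(v)) for u, v in arcs}
    for u, v in arcs:
        su, sv = str(u), str(v)
        if spec.beta > 0 and rng.random() < spec.beta:
            candidates = [
                str(w)
                for w in range(spec.n)
                if str(w) != su and (su, str(w)) not in arc_set
            ]
            if candidates:
                new = candidates[rng.integers(len(candidates))]
                arc_set.discard((su, sv))
                arc_set.add((su, new))
    g.add_edges_from(arc_set)
    return SongDigraph(g)


def random_walk_song(spec: WalkSpec) -> SongCorpus:
    """Generate a corpus by a teleporting random walk on a planted digraph.

    Each step moves to a uniformly chosen out-neighbour; with probability
    ``restart`` (or always, at a dead end) the walk teleports to a uniform
    node and a new bout begins. A dead end with ``restart = 0`` raises
    :class:`GenerationError` naming the node.
    """
    if spec.length < 1:
        raise ValueError("walk length must be >= 1")
    if not 0 <= spec.restart < 1:
        raise ValueError("restart must be in [0, 1)")
    if spec.n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    g = spec.graph.graph
    nodes = sorted(g.nodes())
    if not nodes:
        raise ValueError("planted graph has no nodes")
    rng = _rng(spec.seed)
    succ = {u: sorted(g.successors(u)) for u in nodes}

    current = spec.start if spec.start is not None else nodes[rng.integers(len(nodes))]
    if current not in g:
        raise ValueError(f"start node {current!r} not in graph")
    tokens = [current]
    breaks: set[int] = set()  # index i means a bout boundary BEFORE token i
    while len(tokens) < spec.length:
        teleport = spec.restart > 0 and rng.random() < spec.restart
        if not teleport and not succ[current]:
            if spec.restart == 0:
                raise GenerationError(
                    f"dead-end node {current!r} reached with restart=0"
                )
            teleport = True
        if teleport:
            breaks.add(len(tokens))
            current = nodes[rng.integers(len(nodes))]
        else:
            out = succ[current]
            current = out[rng.integers(len(out))]
        tokens.append(current)

    # scheduled contiguous splits into n_bouts chunks, merged with teleports
    chunk = max(1, spec.length // spec.n_bouts)
    breaks.update(range(chunk, spec.length, chunk))
    cuts = sorted(b for b in breaks if 0 < b < spec.length)
    bouts, prev = [], 0
    for c in cuts + [spec.length]:
        bouts.append(Bout(tuple(tokens[prev:c]), bout_id=f"walk{len(bouts)}"))
        prev = c
    return SongCorpus(bouts=tuple(bouts), source_id="synthetic-walk")
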