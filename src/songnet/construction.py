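"""Build song networks from corpora.

A corpus of bouts is turned into a *song directed network* (SDN) whose
nodes are phrase types and whose arcs are the observed ordered transitions
between successive phrases, and into its direction-forgetting projection,
the *song undirected network* (SUN). Immediate repetitions of the same
phrase (self-transitions) are collapsed before pairing, so ``a a b``
contributes the single transition ``a -> b`` and the networks never contain
self-loops. Transitions are counted within each bout independently; no pair
spans a bout boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .corpus import Bout, SongCorpus

__all__ = [
    "SongDigraph",
    "SongNetwork",
    "collapse_repeats",
    "extract_transitions",
    "build_sdn",
    "build_sun",
    "build_networks",
]


@dataclass(frozen=True)
class SongDigraph:
    """Directed phrase-transition network (SDN).

    Wraps a :class:`networkx.DiGraph` whose arcs carry a ``count``
    attribute: the number of times the ordered transition was observed.
    """

    graph: nx.DiGraph

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    @property
    def arcs(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    @property
    def arc_counts(self) -> dict[tuple[str, str], int]:
        return {
            (u, v): d.get("count", 1) for u, v, d in self.graph.edges(data=True)
        }

    @property
    def mean_total_degree(self) -> float:
        """Average of in+out degree over nodes: 2 * arcs / n."""
        if self.n == 0:
            raise ValueError("mean degree undefined for an empty network")
        return 2.0 * self.n_arcs / self.n

    def in_degree(self, node) -> int:
        return self.graph.in_degree(node)

    def out_degree(self, node) -> int:
        return self.graph.out_degree(node)


@dataclass(frozen=True)
class SongNetwork:
    """Undirected phrase-transition network (SUN)."""

    graph: nx.Graph

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges()}

    @property
    def degree(self) -> dict:
        return dict(self.graph.degree())

    @property
    def mean_degree(self) -> float:
        if self.n == 0:
            raise ValueError("mean degree undefined for an empty network")
        return 2.0 * self.n_edges / self.n


def collapse_repeats(bout: Bout) -> Bout:
    """Collapse runs of immediately repeated phrases to a single token.

    ``[a, a, b, b, b, c]`` becomes ``[a, b, c]``; the operation is
    idempotent and preserves the order of run-first occurrences.
    """
    out: list[str] = []
    for p in bout.phrases:
        if not out or out[-1] != p:
            out.append(p)
    return Bout(tuple(out), bout_id=bout.bout_id)


def extract_transitions(corpus: SongCorpus) -> dict[tuple[str, str], int]:
    """Count ordered adjacent-phrase transitions, per bout, repeats collapsed.

    Returns a map ``(source, target) -> count`` with no self-pairs and no
    pairs spanning bout boundaries.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for bout in corpus.bouts:
        phrases = collapse_repeats(bout).phrases
        for a, b in zip(phrases, phrases[1:]):
            counts[(a, b)] += 1
    return dict(counts)


def build_sdn(corpus: SongCorpus) -> SongDigraph:
    """Construct the song directed network from a corpus.

    Every phrase appearing in any bout becomes a node (phrases that only
    occur in single-phrase bouts are isolated nodes); arcs carry observed
    transition counts.
    """
    g = nx.DiGraph()
    g.add_nodes_from(sorted(corpus.repertoire))
    for (u, v), c in extract_transitions(corpus).items():
        g.add_edge(u, v, count=c)
    return SongDigraph(g)


def build_sun(sdn: SongDigraph) -> SongNetwork:
    """Direction-forgetting projection of an SDN.

    Reversible transitions (u->v and v->u) collapse to the single
    undirected edge u--v; node sets are identical.
    """
    g = nx.Graph()
    g.add_nodes_from(sdn.graph.nodes())
    g.add_edges_from(sdn.graph.edges())
    return SongNetwork(g)


def build_networks(corpus: SongCorpus) -> tuple[SongDigraph, SongNetwork]:
    """Convenience: build both the SDN and its undirected projection."""
    sdn = build_sdn(corpus)
    return sdn, build_sun(sdn)
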