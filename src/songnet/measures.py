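"""Global network measures for song networks.

* ``average_path_length`` — mean shortest-path hop count over all ordered
  node pairs (u, v), u != v, for which v is reachable from u; unreachable
  pairs are excluded from the average, which keeps L finite on directed
  networks that are not strongly connected.
* ``clustering_coefficient`` — mean over nodes of C_i = E_i / (k_i(k_i-1)/2),
  where E_i counts edges among the k_i neighbours of i; C_i := 0 when
  k_i < 2 and such nodes are included in the average.
* ``degree_distribution`` / ``average_degree`` — P(k) and <k>; for a
  digraph the default degree is the total (in+out) degree.
* ``small_worldness`` — S = (C/C_rand) / (L/L_rand); S > 1 indicates
  small-world structure relative to matched random networks.
* ``z_score`` — (observed - ensemble mean) / ensemble SD.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .construction import SongDigraph, SongNetwork
from .corpus import _as_nx

__all__ = [
    "UndefinedMeasureError",
    "MeasureSet",
    "average_path_length",
    "local_clustering",
    "clustering_coefficient",
    "degree_histogram",
    "degree_distribution",
    "average_degree",
    "small_worldness",
    "z_score",
    "compute_measures",
]


class UndefinedMeasureError(ValueError):
    """A measure is undefined for this network (e.g. L on an edgeless graph)."""


def average_path_length(net) -> float:
    """Mean shortest-path length over reachable ordered node pairs.

    Reachability is undirected for a SUN and follows arc direction for an
    SDN. Raises :class:`UndefinedMeasureError` on networks with fewer than
    2 nodes or no edges.
    """
    g = _as_nx(net)
    n = g.number_of_nodes()
    if n < 2 or g.number_of_edges() == 0:
        raise UndefinedMeasureError(
            "average path length requires >=2 nodes and >=1 edge"
        )
    adj = nx.to_scipy_sparse_array(g, format="csr", weight=None)
    dist = shortest_path(adj, method="D", directed=g.is_directed(),
                         unweighted=True)
    mask = np.isfinite(dist)
    np.fill_diagonal(mask, False)
    if not mask.any():
        raise UndefinedMeasureError("no reachable ordered pairs")
    return float(dist[mask].mean())


def local_clustering(net, node) -> float:
    """C_i: fraction of the node's neighbour pairs that are connected.

    Defined as 0 for nodes of degree < 2.
    """
    g = _as_nx(net)
    if g.is_directed():
        raise TypeError("local clustering is defined for undirected networks")
    return float(nx.clustering(g, node))


def clustering_coefficient(net) -> float:
    """C: average of C_i over all nodes (degree-deficient nodes count as 0)."""
    g = _as_nx(net)
    if g.is_directed():
        raise TypeError("clustering coefficient is defined for undirected networks")
    if g.number_of_nodes() == 0:
        raise UndefinedMeasureError("clustering undefined for an empty network")
    return float(nx.average_clustering(g, count_zeros=True))


def _degrees(g: nx.Graph | nx.DiGraph, kind: str) -> list[int]:
    if not g.is_directed():
        return [d for _, d in g.degree()]
    if kind == "total":
        return [d for _, d in g.degree()]
    if kind == "in":
        return [d for _, d in g.in_degree()]
    if kind == "out":
        return [d for _, d in g.out_degree()]
    raise ValueError(f"unknown degree kind: {kind!r}")


def degree_histogram(net, kind: str = "total") -> dict[int, int]:
    """Map degree k -> number of nodes with that degree.

    For digraphs *kind* selects ``"total"`` (in+out, the default), ``"in"``
    or ``"out"`` degree.
    """
    g = _as_nx(net)
    return dict(sorted(Counter(_degrees(g, kind)).items()))


def degree_distribution(net, kind: str = "total") -> dict[int, float]:
    """P(k): probability that a node has degree k; sums to 1."""
    g = _as_nx(net)
    n = g.number_of_nodes()
    if n == 0:
        raise UndefinedMeasureError("degree distribution undefined for 0 nodes")
    return {k: c / n for k, c in degree_histogram(net, kind).items()}


def average_degree(net, kind: str = "total") -> float:
    """<k> = sum_k k * P(k); equals 2E/n (undirected) or 2A/n (total degree)."""
    g = _as_nx(net)
    if g.number_of_nodes() == 0:
        raise UndefinedMeasureError("average degree undefined for 0 nodes")
    degs = _degrees(g, kind)
    return float(np.mean(degs))


def small_worldness(C: float, L: float, C_rand: float, L_rand: float) -> float:
    """S = (C/C_rand) / (L/L_rand); the network is small-world when S > 1."""
    for name, v in (("C", C), ("L", L), ("C_rand", C_rand), ("L_rand", L_rand)):
        if not (v > 0):
            raise ValueError(f"small-world-ness requires {name} > 0, got {v}")
    return (C / C_rand) / (L / L_rand)


def z_score(observed: float, ensemble_mean: float, ensemble_sd: float) -> float:
    """Z = (observed - ensemble mean) / ensemble SD; requires SD > 0."""
    if not (ensemble_sd > 0):
        raise ValueError(f"z-score requires ensemble SD > 0, got {ensemble_sd}")
    return (observed - ensemble_mean) / ensemble_sd


@dataclass(frozen=True)
class MeasureSet:
    """Bundle of global measures for one undirected network."""

    n: int
    L: float | None
    C: float
    mean_degree: float
    degree_histogram: dict[int, int] = field(default_factory=dict)
    degree_probability: dict[int, float] = field(default_factory=dict)

    @property
    def m(self) -> int:
        """Alias of n: the number of phrases the C average runs over."""
        return self.n


def compute_measures(net: SongNetwork) -> MeasureSet:
    """All global measures for a SUN; L is None when undefined (edgeless)."""
    try:
        L = average_path_length(net)
    except UndefinedMeasureError:
        L = None
    return MeasureSet(
        n=net.n,
        L=L,
        C=clustering_coefficient(net),
        mean_degree=average_degree(net),
        degree_histogram=degree_histogram(net),
        degree_probability=degree_distribution(net),
    )
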