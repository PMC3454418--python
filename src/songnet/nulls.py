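"""Null models: matched random networks, shuffled corpora, ensembles.

Random undirected networks (RUNs) and random directed networks (RDNs) are
Erdos-Renyi-style graphs matched to an observed network's node count and
average degree. Each unordered pair (RUN) or ordered pair (RDN) receives an
edge independently with probability p = target / #pairs, and a draw is
retained only if its edge count equals the target exactly; otherwise it is
rejected and redrawn. Matching "exactly the same <k>" is implemented as an
exact edge/arc-count match, which is equivalent at fixed n and avoids float
comparison.

The rejection loop is realised in two equivalent stages: the total edge
count of an independent-pair draw is Binomial(#pairs, p), so the sampler
first redraws that binomial count until it hits the target, then places the
target number of edges uniformly at random among the pairs — exactly the
conditional law of the independent-pair draw given its count.

Shuffle nulls randomise a corpus by repeated position switches of randomly
selected token pairs, preserving the phrase frequency distribution while
destroying transition context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .construction import SongDigraph, SongNetwork, build_sdn
from .corpus import Bout, SongCorpus
from .measures import (
    UndefinedMeasureError,
    average_degree,
    average_path_length,
    clustering_coefficient,
    z_score,
)
from .motifs import MOTIF_CLASSES, motif_profile

__all__ = [
    "NullConfig",
    "EnsembleSummary",
    "NullConvergenceError",
    "generate_run",
    "generate_rdn",
    "ensemble_summary",
    "shuffle_corpus",
    "occurrence_vs_degree",
]

DEFAULT_MAX_REJECTS = 10**6


class NullConvergenceError(RuntimeError):
    """The exact-count rejection loop exceeded its attempt cap."""


@dataclass(frozen=True)
class NullConfig:
    """Parameters of a matched random-network ensemble."""

    n: int
    target_edges: int | None = None
    target_arcs: int | None = None
    reps: int = 1000
    seed: int | None = None
    max_rejects: int = DEFAULT_MAX_REJECTS


@dataclass(frozen=True)
class EnsembleSummary:
    """Null-ensemble mean, SD and Z-score for one scalar measure."""

    measure: str
    mean: float
    sd: float
    reps: int
    observed: float | None = None
    z: float | None = None


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _exact_count(
    rng: np.random.Generator, n_pairs: int, target: int, max_rejects: int
) -> None:
    """Redraw Binomial(n_pairs, p) until it equals target (rejection loop)."""
    p = target / n_pairs
    for _ in range(max_rejects):
        if rng.binomial(n_pairs, p) == target:
            return
    raise NullConvergenceError(
        f"exact-count rejection did not converge within {max_rejects} attempts "
        f"(n_pairs={n_pairs}, target={target})"
    )


def generate_run(
    n: int,
    target_edges: int,
    seed=None,
    max_rejects: int = DEFAULT_MAX_REJECTS,
) -> SongNetwork:
    """One random undirected network with exactly *target_edges* edges.

    Nodes are labelled 0..n-1; no self-loops.
    """
    n_pairs = n * (n - 1) // 2
    if not 0 < target_edges <= n_pairs:
        raise ValueError(
            f"target_edges={target_edges} out of range (0, {n_pairs}] for n={n}"
        )
    rng = _rng(seed)
    _exact_count(rng, n_pairs, target_edges, max_rejects)
    rows, cols = np.triu_indices(n, k=1)
    idx = rng.choice(n_pairs, size=target_edges, replace=False)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(rows[idx].tolist(), cols[idx].tolist()))
    return SongNetwork(g)


def generate_rdn(
    n: int,
    target_arcs: int,
    seed=None,
    max_rejects: int = DEFAULT_MAX_REJECTS,
) -> SongDigraph:
    """One random directed network with exactly *target_arcs* arcs.

    Every ordered pair (u, v), u != v, is a candidate arc; mean total
    degree of the result is 2 * target_arcs / n.
    """
    n_pairs = n * (n - 1)
    if not 0 < target_arcs <= n_pairs:
        raise ValueError(
            f"target_arcs={target_arcs} out of range (0, {n_pairs}] for n={n}"
        )
    rng = _rng(seed)
    _exact_count(rng, n_pairs, target_arcs, max_rejects)
    # ordered pair index -> (u, v): enumerate all pairs u != v
    idx = rng.choice(n_pairs, size=target_arcs, replace=False)
    u = idx // (n - 1)
    r = idx % (n - 1)
    v = np.where(r >= u, r + 1, r)  # skip the diagonal
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(u.tolist(), v.tolist()))
    return SongDigraph(g)


def _measure_value(name: str, net, profile_cache: dict) -> float:
    if name == "L":
        try:
            return average_path_length(net)
        except UndefinedMeasureError:
            return math.nan
    if name == "C":
        return clustering_coefficient(net)
    if name in ("mean_degree", "mean_total_degree"):
        return average_degree(net)
    if name.startswith("motif_count:") or name.startswith("motif_prop:"):
        kind, cls = name.split(":", 1)
        if cls not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class: {cls!r}")
        if "profile" not in profile_cache:
            profile_cache["profile"] = motif_profile(net)
        prof = profile_cache["profile"]
        return prof.count(cls) if kind == "motif_count" else prof.proportions[cls]
    raise ValueError(f"unknown measure name: {name!r}")


def ensemble_summary(
    config: NullConfig,
    kind: str,
    measures: list[str],
    observed: dict[str, float] | None = None,
) -> list[EnsembleSummary]:
    """Generate a RUN or RDN ensemble and summarise the requested measures.

    Parameters
    ----------
    config
        Ensemble parameters; ``target_edges`` is required for ``kind="run"``,
        ``target_arcs`` for ``kind="rdn"``.
    kind
        ``"run"`` or ``"rdn"``.
    measures
        Names among ``"L"``, ``"C"`` (undirected only), ``"mean_degree"``,
        ``"motif_count:<class>"``, ``"motif_prop:<class>"`` (directed only).
    observed
        Optional map measure name -> observed value; Z-scores are filled in
        where given. An SD of exactly 0 yields ``z=None``.

    Deterministic for a fixed ``config.seed``.
    """
    if config.reps < 2:
        raise ValueError("ensemble requires reps >= 2")
    if kind == "run":
        if config.target_edges is None:
            raise ValueError("target_edges required for a RUN ensemble")
        make = lambda rng: generate_run(  # noqa: E731
            config.n, config.target_edges, rng, config.max_rejects
        )
    elif kind == "rdn":
        if config.target_arcs is None:
            raise ValueError("target_arcs required for an RDN ensemble")
        make = lambda rng: generate_rdn(  # noqa: E731
            config.n, config.target_arcs, rng, config.max_rejects
        )
    else:
        raise ValueError(f"kind must be 'run' or 'rdn', got {kind!r}")

    rng = _rng(config.seed)
    values = {m: np.empty(config.reps) for m in measures}
    for i in range(config.reps):
        net = make(rng)
        cache: dict = {}
        for m in measures:
            values[m][i] = _measure_value(m, net, cache)

    out: list[EnsembleSummary] = []
    for m in measures:
        v = values[m]
        mean, sd = float(np.nanmean(v)), float(np.nanstd(v, ddof=1))
        obs = None if observed is None else observed.get(m)
        z = None
        if obs is not None and sd > 0:
            z = z_score(obs, mean, sd)
        out.append(
            EnsembleSummary(
                measure=m, mean=mean, sd=sd, reps=config.reps, observed=obs, z=z
            )
        )
    return out


def shuffle_corpus(
    corpus: SongCorpus, n_swaps: int = 1000, seed=None
) -> SongCorpus:
    """Randomise transition context by repeated token-position switches.

    Performs exactly *n_swaps* swaps of two uniformly chosen global token
    positions (with replacement across iterations; a position may be swapped
    with itself). Bout lengths and the per-label token counts are preserved
    exactly; only the contexts change.
    """
    tokens = list(corpus.tokens())
    total = len(tokens)
    if total < 2:
        raise ValueError("shuffling requires a corpus with >=2 tokens")
    rng = _rng(seed)
    pairs = rng.integers(0, total, size=(n_swaps, 2))
    for i, j in pairs:
        tokens[i], tokens[j] = tokens[j], tokens[i]
    return _rebuild_with_tokens(corpus, tokens, suffix="shuffled")


def _rebuild_with_tokens(
    corpus: SongCorpus, tokens: list[str], suffix: str
) -> SongCorpus:
    """Reassemble a corpus from a flat token list, keeping bout lengths."""
    bouts = []
    pos = 0
    for b in corpus.bouts:
        bouts.append(Bout(tuple(tokens[pos : pos + len(b)]), bout_id=b.bout_id))
        pos += len(b)
    label = f"{corpus.source_id}[{suffix}]" if corpus.source_id else suffix
    return SongCorpus(bouts=tuple(bouts), source_id=label)


def occurrence_vs_degree(corpus: SongCorpus) -> pd.DataFrame:
    """Occurrence frequency vs degree frequency per phrase.

    Occurrence frequency is each phrase's raw token count (repeats not
    collapsed) divided by the total token count; degree frequency is its
    total degree in the SDN divided by the summed total degree. Popular
    phrases with stereotyped transitions sit below the random expectation
    on this plot. Both columns sum to 1.
    """
    sdn = build_sdn(corpus)
    if sdn.n_arcs == 0:
        raise UndefinedMeasureError(
            "occurrence-vs-degree undefined for an edgeless SDN"
        )
    counts = corpus.token_counts()
    total_tokens = corpus.n_tokens
    degrees = dict(sdn.graph.degree())  # in+out for a DiGraph
    total_degree = sum(degrees.values())
    rows = [
        {
            "phrase": p,
            "occurrence_frequency": counts[p] / total_tokens,
            "degree_frequency": degrees.get(p, 0) / total_degree,
        }
        for p in sorted(counts)
    ]
    return pd.DataFrame(rows)
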