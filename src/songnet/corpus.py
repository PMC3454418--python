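"""Symbolic song corpora: parsing, validation, and network export.

A corpus is an ordered collection of *bouts* — continuous singing sequences
recorded as separate units — each an ordered list of phrase labels. Phrase
labels are opaque tokens (catalog IDs, letters, anything); no numeric
interpretation is ever applied. Transitions are later counted only within
bouts, never across them.

Two input dialects are supported:

* ``bout-lines`` — one bout per line, whitespace-separated labels. Blank
  lines and ``#`` comment lines are skipped. This is the canonical fixture
  format.
* ``csv`` — columns ``bout_id,position,phrase``, sorted by bout then
  position, positions contiguous from 0 within each bout.
"""

from __future__ import annotations

import csv as _csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "Bout",
    "SongCorpus",
    "CorpusParseError",
    "EmptyCorpusError",
    "EmptyNetworkError",
    "parse_corpus",
    "corpus_from_bouts",
    "export_network",
]


class CorpusParseError(ValueError):
    """Malformed corpus input (bad CSV layout, missing columns, ...)."""


class EmptyCorpusError(CorpusParseError):
    """A corpus file yielded zero bouts."""


class EmptyNetworkError(ValueError):
    """Refusal to export a network with no nodes."""


@dataclass(frozen=True)
class Bout:
    """One continuous singing sequence, in temporal order."""

    phrases: tuple[str, ...]
    bout_id: str = ""

    def __len__(self) -> int:
        return len(self.phrases)

    def __iter__(self) -> Iterator[str]:
        return iter(self.phrases)


@dataclass(frozen=True)
class SongCorpus:
    """Ordered bouts of phrase labels plus a free-text provenance label."""

    bouts: tuple[Bout, ...]
    source_id: str = ""

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    @property
    def n_tokens(self) -> int:
        """Total phrase tokens, before any repeat collapsing."""
        return sum(len(b) for b in self.bouts)

    @property
    def repertoire(self) -> frozenset[str]:
        """Set of distinct phrase labels observed anywhere in the corpus."""
        return frozenset(p for b in self.bouts for p in b.phrases)

    @property
    def repertoire_size(self) -> int:
        return len(self.repertoire)

    def tokens(self) -> Iterator[str]:
        """All tokens in temporal order (bout order, then position)."""
        for b in self.bouts:
            yield from b.phrases

    def token_counts(self) -> Counter[str]:
        return Counter(self.tokens())


def corpus_from_bouts(
    bouts: Iterable[Iterable[str]], source_id: str = ""
) -> SongCorpus:
    """Build a corpus from nested label sequences; empty bouts are dropped."""
    built = tuple(
        Bout(tuple(str(p) for p in b), bout_id=f"b{i}")
        for i, b in enumerate(bouts)
        if len(tuple(b)) > 0
    )
    return SongCorpus(bouts=built, source_id=source_id)


def _parse_bout_lines(path: Path) -> list[Bout]:
    bouts: list[Bout] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            bouts.append(Bout(tuple(stripped.split()), bout_id=f"line{lineno}"))
    return bouts


def _parse_csv(path: Path) -> list[Bout]:
    required = {"bout_id", "position", "phrase"}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = _csv.DictReader(fh)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise CorpusParseError(
                f"{path}: CSV is missing required column(s): {', '.join(missing)}"
            )
        bouts: list[Bout] = []
        current_id: str | None = None
        current: list[str] = []
        seen_ids: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            bid, pos_s, phrase = row["bout_id"], row["position"], row["phrase"]
            try:
                pos = int(pos_s)
            except (TypeError, ValueError):
                raise CorpusParseError(
                    f"{path}:{lineno}: non-integer position {pos_s!r}"
                ) from None
            if bid != current_id:
                if bid in seen_ids:
                    raise CorpusParseError(
                        f"{path}:{lineno}: bout {bid!r} is not contiguous "
                        "(rows must be sorted by bout then position)"
                    )
                if current_id is not None:
                    bouts.append(Bout(tuple(current), bout_id=current_id))
                current_id = bid
                seen_ids.add(bid)
                current = []
            if pos != len(current):
                raise CorpusParseError(
                    f"{path}:{lineno}: bout {bid!r} expected position "
                    f"{len(current)}, got {pos} (positions must be contiguous from 0)"
                )
            current.append(phrase)
        if current_id is not None:
            bouts.append(Bout(tuple(current), bout_id=current_id))
    return bouts


def parse_corpus(path: str | Path, format: str = "bout-lines") -> SongCorpus:
    """Read a song corpus from *path* in the given dialect.

    Parameters
    ----------
    path
        Input file. Must exist.
    format
        ``"bout-lines"`` (default) or ``"csv"``.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    CorpusParseError
        On malformed CSV (missing column, non-contiguous positions), naming
        the offending line.
    EmptyCorpusError
        If no bouts remain after parsing.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"corpus file not found: {p}")
    if format == "bout-lines":
        bouts = _parse_bout_lines(p)
    elif format == "csv":
        bouts = _parse_csv(p)
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    if not bouts:
        raise EmptyCorpusError(f"{p}: corpus contains zero bouts")
    return SongCorpus(bouts=tuple(bouts), source_id=str(p))


def _as_nx(net) -> nx.Graph | nx.DiGraph:
    """Accept a SongNetwork/SongDigraph wrapper or a bare networkx graph."""
    if isinstance(net, (nx.Graph, nx.DiGraph)):
        return net
    g = getattr(net, "graph", None)
    if not isinstance(g, (nx.Graph, nx.DiGraph)):
        raise TypeError(f"not a network: {type(net).__name__}")
    return g


def export_network(net, format: str, path: str | Path) -> Path:
    """Write a network to *path* as an edge-list TSV or GraphML file.

    The TSV has a ``source<TAB>target`` header; for undirected networks each
    edge appears once as an unordered pair, for digraphs each arc appears
    with its direction preserved. GraphML output round-trips node and edge
    sets exactly.
    """
    g = _as_nx(net)
    if g.number_of_nodes() == 0:
        raise EmptyNetworkError("refusing to export an empty network (0 nodes)")
    p = Path(path)
    if format in ("tsv", "edge-list", "edgelist"):
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\n")
            for u, v in g.edges():
                fh.write(f"{u}\t{v}\n")
    elif format == "graphml":
        nx.write_graphml(g, p, named_key_ids=True)
    else:
        raise ValueError(f"unknown export format: {format!r}")
    return p
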