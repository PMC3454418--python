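"""Robustness analyses: sample-size (rarefaction) and misclassification noise.

Network measures should be usable long before a repertoire is exhaustively
sampled. ``rarefaction`` rebuilds the networks on growing temporal prefixes
of the corpus and records repertoire size alongside the network measures;
repertoire size keeps climbing with sample size while L, C and the motif
proportions stabilise much earlier.

``perturb_phrases`` imitates phrase misclassification: a chosen fraction of
token positions is replaced with a different label drawn uniformly from the
observed repertoire. ``noise_sweep`` repeats this over a grid of noise
rates and summarises each measure's mean and SD over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .construction import build_networks
from .corpus import Bout, SongCorpus
from .measures import (
    UndefinedMeasureError,
    average_degree,
    average_path_length,
    clustering_coefficient,
    degree_histogram,
)
from .motifs import MOTIF_CLASSES, motif_profile
from .nulls import _rebuild_with_tokens, _rng

__all__ = [
    "RarefactionCurve",
    "NoiseSweep",
    "rarefaction",
    "perturb_phrases",
    "noise_sweep",
]


def _analyze_tokens_measures(corpus: SongCorpus) -> dict:
    """One row of measures for a (possibly tiny) corpus; None when undefined."""
    sdn, sun = build_networks(corpus)
    row: dict = {
        "repertoire_size": corpus.repertoire_size,
        "n_nodes": sun.n,
        "n_edges": sun.n_edges,
    }
    if sun.n_edges == 0:
        row.update({"L": None, "C": None, "mean_degree": 0.0})
        row["degree_histogram"] = degree_histogram(sun)
        for cls in MOTIF_CLASSES:
            row[f"motif_prop:{cls}"] = None
        return row
    try:
        row["L"] = average_path_length(sun)
    except UndefinedMeasureError:
        row["L"] = None
    row["C"] = clustering_coefficient(sun)
    row["mean_degree"] = average_degree(sun)
    row["degree_histogram"] = degree_histogram(sun)
    props = motif_profile(sdn).proportions
    for cls in MOTIF_CLASSES:
        row[f"motif_prop:{cls}"] = props[cls]
    return row


def _prefix_corpus(corpus: SongCorpus, n_tokens: int) -> SongCorpus:
    """First *n_tokens* tokens in temporal order; last bout may be truncated."""
    bouts = []
    remaining = n_tokens
    for b in corpus.bouts:
        if remaining <= 0:
            break
        take = min(len(b), remaining)
        bouts.append(Bout(b.phrases[:take], bout_id=b.bout_id))
        remaining -= take
    return SongCorpus(bouts=tuple(bouts), source_id=corpus.source_id)


@dataclass(frozen=True)
class RarefactionCurve:
    """Measures on growing samples; one point per sample size."""

    points: tuple[dict, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {k: v for k, v in p.items() if k != "degree_histogram"}
            for p in self.points
        ])


def rarefaction(
    corpus: SongCorpus,
    step: int,
    mode: str = "prefix",
    seed=None,
) -> RarefactionCurve:
    """Network measures as a function of sample size.

    ``mode="prefix"`` (default) uses temporal prefixes of the corpus — the
    first s tokens for s = step, 2*step, ..., total — matching a cumulative
    sampling design; the final point is the full-corpus analysis exactly.
    ``mode="subsample"`` instead draws s tokens without replacement (order
    preserved) for each size, for comparison.

    Points whose networks are edgeless carry ``None`` markers for the
    undefined measures rather than being dropped.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if mode not in ("prefix", "subsample"):
        raise ValueError(f"unknown rarefaction mode: {mode!r}")
    total = corpus.n_tokens
    sizes = list(range(step, total, step)) + [total]
    rng = _rng(seed)
    points = []
    for s in sizes:
        if mode == "prefix":
            sub = _prefix_corpus(corpus, s)
        else:
            keep = np.sort(rng.choice(total, size=s, replace=False))
            mask = np.zeros(total, dtype=bool)
            mask[keep] = True
            bouts, pos = [], 0
            for b in corpus.bouts:
                kept = tuple(
                    p for p, m in zip(b.phrases, mask[pos : pos + len(b)]) if m
                )
                pos += len(b)
                if kept:
                    bouts.append(Bout(kept, bout_id=b.bout_id))
            sub = SongCorpus(tuple(bouts), source_id=corpus.source_id)
        row = {"sample_size": s}
        row.update(_analyze_tokens_measures(sub))
        points.append(row)
    return RarefactionCurve(points=tuple(points))


def perturb_phrases(
    corpus: SongCorpus, noise_rate: float, seed=None
) -> SongCorpus:
    """Replace a fraction of tokens with other labels from the repertoire.

    Exactly ``round(noise_rate * N)`` token positions (round-half-to-even,
    N the total token count) are chosen uniformly without replacement; each
    chosen token is replaced by a label drawn uniformly from the observed
    repertoire excluding its current label, so the realised
    misclassification rate equals the requested rate. Bout lengths are
    unchanged.
    """
    if not 0 <= noise_rate <= 1:
        raise ValueError(f"noise_rate must be in [0, 1], got {noise_rate}")
    tokens = list(corpus.tokens())
    n = len(tokens)
    n_replace = round(noise_rate * n)
    if n_replace == 0:
        return corpus
    repertoire = sorted(corpus.repertoire)
    if len(repertoire) < 2:
        raise ValueError(
            "cannot perturb: repertoire has a single label, no alternative exists"
        )
    rng = _rng(seed)
    positions = rng.choice(n, size=n_replace, replace=False)
    for pos in positions:
        alternatives = [lab for lab in repertoire if lab != tokens[pos]]
        tokens[pos] = alternatives[rng.integers(len(alternatives))]
    return _rebuild_with_tokens(corpus, tokens, suffix=f"noise={noise_rate}")


@dataclass(frozen=True)
class NoiseSweep:
    """Per-rate mean and SD of each measure over perturbation replicates."""

    rates: tuple[float, ...]
    reps: int
    summary: tuple[dict, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.summary))


_SWEEP_MEASURES = ["L", "C", "mean_degree", "repertoire_size"] + [
    f"motif_prop:{c}" for c in MOTIF_CLASSES
]


def noise_sweep(
    corpus: SongCorpus,
    rates: list[float],
    reps: int = 100,
    seed=None,
) -> NoiseSweep:
    """Recompute all measures under misclassification noise.

    For each rate, *reps* independent perturbations (seeds derived from the
    master seed) are analysed; the sweep reports each measure's mean and SD
    across replicates. At rate 0 the perturbation is the identity, so means
    equal the unperturbed measures and every SD is 0. Deterministic for a
    fixed master seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(not 0 <= r <= 1 for r in rates):
        raise ValueError("rates must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(rates) * reps)
    rows = []
    for ri, rate in enumerate(rates):
        values: dict[str, list[float]] = {m: [] for m in _SWEEP_MEASURES}
        for j in range(reps):
            rng = np.random.default_rng(children[ri * reps + j])
            perturbed = perturb_phrases(corpus, rate, rng)
            row = _analyze_tokens_measures(perturbed)
            for m in _SWEEP_MEASURES:
                v = row[m]
                values[m].append(np.nan if v is None else float(v))
        out: dict = {"noise_rate": rate}
        for m in _SWEEP_MEASURES:
            arr = np.array(values[m])
            if np.isnan(arr).all():
                out[f"{m}:mean"] = None
                out[f"{m}:sd"] = None
                continue
            out[f"{m}:mean"] = float(np.nanmean(arr))
            # identical replicates must report SD exactly 0 (mean round-off)
            if np.nanmin(arr) == np.nanmax(arr):
                out[f"{m}:sd"] = 0.0
            else:
                out[f"{m}:sd"] = float(np.nanstd(arr, ddof=0))
        rows.append(out)
    return NoiseSweep(rates=tuple(rates), reps=reps, summary=tuple(rows))
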