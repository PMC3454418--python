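"""Full-analysis orchestration and the JSON report schema.

``run_full_analysis`` executes the whole pipeline on one corpus:
construction of the SUN and SDN, global measures, motif profile, matched
RUN/RDN null ensembles with Z-scores, the small-world-ness score S, and the
chi-square motif comparison. The report is a pydantic model, so its JSON
schema is published alongside the package and every report validates
against it. For a fixed seed the report is deterministic apart from the
timestamp field.
"""

from __future__ import annotations

import datetime as _dt
import logging
from importlib import metadata as _md

import numpy as np
from pydantic import BaseModel

from .construction import build_networks
from .corpus import SongCorpus, parse_corpus
from .measures import compute_measures, small_worldness, z_score
from .motifs import MOTIF_CLASSES, compare_profiles, motif_profile
from .nulls import NullConfig, ensemble_summary, generate_rdn

log = logging.getLogger("songnet")

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_full_analysis",
    "report_json_schema",
]


class AnalysisConfig(BaseModel):
    """Knobs of the full analysis (null-ensemble size and seeding)."""

    reps: int = 1000
    seed: int = 0
    max_rejects: int = 10**6


class CorpusSummary(BaseModel):
    tokens: int
    bouts: int
    repertoire_size: int
    source_id: str = ""


class EnsembleStat(BaseModel):
    measure: str
    observed: float | None = None
    mean: float
    sd: float
    z: float | None = None


class SunBlock(BaseModel):
    n: int
    edges: int
    L: float | None
    C: float
    mean_degree: float
    degree_histogram: dict[int, int]
    S: float | None = None
    run_ensemble: list[EnsembleStat] = []


class SdnBlock(BaseModel):
    n: int
    arcs: int
    L: float | None
    mean_total_degree: float
    motif_counts: dict[str, int]
    motif_proportions: dict[str, float]
    rdn_ensemble: list[EnsembleStat] = []
    chi2: float | None = None
    df: int | None = None
    pvalue: float | None = None


class Provenance(BaseModel):
    seed: int
    reps: int
    version: str
    timestamp: str


class AnalysisReport(BaseModel):
    """Serializable result of one full song-network analysis."""

    corpus: CorpusSummary
    sun: SunBlock
    sdn: SdnBlock
    provenance: Provenance


def report_json_schema() -> dict:
    """JSON schema the report serialises against."""
    return AnalysisReport.model_json_schema()


def _version() -> str:
    try:
        return _md.version("songnet")
    except _md.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_full_analysis(
    corpus: SongCorpus | str,
    config: AnalysisConfig | None = None,
    corpus_format: str = "bout-lines",
) -> AnalysisReport:
    """Run construction, measures, motifs and null comparisons on a corpus.

    *corpus* may be a :class:`SongCorpus` or a path to a corpus file.
    Deterministic for a fixed ``config.seed`` (modulo the timestamp).
    """
    if config is None:
        config = AnalysisConfig()
    if not isinstance(corpus, SongCorpus):
        corpus = parse_corpus(corpus, format=corpus_format)

    log.info("constructing networks from %d tokens", corpus.n_tokens)
    sdn, sun = build_networks(corpus)
    ms = compute_measures(sun)
    profile = motif_profile(sdn)

    seeds = np.random.SeedSequence(config.seed).spawn(3)

    sun_stats: list[EnsembleStat] = []
    S = None
    if sun.n_edges > 0 and ms.L is not None:
        log.info("RUN ensemble: n=%d edges=%d reps=%d", sun.n, sun.n_edges,
                 config.reps)
        run_cfg = NullConfig(
            n=sun.n, target_edges=sun.n_edges, reps=config.reps,
            seed=int(seeds[0].generate_state(1)[0] % 2**31),
            max_rejects=config.max_rejects,
        )
        summaries = ensemble_summary(
            run_cfg, "run", ["L", "C"], observed={"L": ms.L, "C": ms.C}
        )
        sun_stats = [EnsembleStat(**vars(s)) for s in summaries]
        by = {s.measure: s for s in summaries}
        if by["L"].mean > 0 and by["C"].mean > 0 and ms.C > 0:
            S = small_worldness(ms.C, ms.L, by["C"].mean, by["L"].mean)

    sdn_stats: list[EnsembleStat] = []
    chi2 = df = pvalue = None
    sdn_L = None
    if sdn.n_arcs > 0:
        from .measures import UndefinedMeasureError, average_path_length

        try:
            sdn_L = average_path_length(sdn)
        except UndefinedMeasureError:
            sdn_L = None
        log.info("RDN ensemble: n=%d arcs=%d reps=%d", sdn.n, sdn.n_arcs,
                 config.reps)
        rdn_seed = int(seeds[1].generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(rdn_seed)
        null_profiles = [
            motif_profile(
                generate_rdn(sdn.n, sdn.n_arcs, rng, config.max_rejects)
            )
            for _ in range(config.reps)
        ]
        comparison = compare_profiles(profile, null_profiles)
        chi2, df, pvalue = comparison.chi2, comparison.df, comparison.pvalue
        for cls in MOTIF_CLASSES:
            sdn_stats.append(
                EnsembleStat(
                    measure=f"motif_count:{cls}",
                    observed=float(profile.count(cls)),
                    mean=comparison.null_mean[cls],
                    sd=comparison.null_sd[cls],
                    z=None
                    if not np.isfinite(comparison.z[cls])
                    else comparison.z[cls],
                )
            )

    return AnalysisReport(
        corpus=CorpusSummary(
            tokens=corpus.n_tokens,
            bouts=corpus.n_bouts,
            repertoire_size=corpus.repertoire_size,
            source_id=corpus.source_id,
        ),
        sun=SunBlock(
            n=sun.n,
            edges=sun.n_edges,
            L=ms.L,
            C=ms.C,
            mean_degree=ms.mean_degree,
            degree_histogram=ms.degree_histogram,
            S=S,
            run_ensemble=sun_stats,
        ),
        sdn=SdnBlock(
            n=sdn.n,
            arcs=sdn.n_arcs,
            L=sdn_L,
            mean_total_degree=sdn.mean_total_degree,
            motif_counts={c: profile.count(c) for c in MOTIF_CLASSES},
            motif_proportions=profile.proportions,
            rdn_ensemble=sdn_stats,
            chi2=chi2,
            df=df,
            pvalue=pvalue,
        ),
        provenance=Provenance(
            seed=config.seed,
            reps=config.reps,
            version=_version(),
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        ),
    )
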