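"""Transition-motif classification of directed song networks.

Every node of an SDN is assigned to exactly one of five classes by its
(in-degree, out-degree) pair:

* ``Margin``     — in = 0 or out = 0 (sequence beginnings/ends; takes
  precedence over all other classes, so an isolated node is Margin);
* ``One-way``    — (1, 1): one-to-one, deterministic;
* ``Bottleneck`` — (>=2, 1): many-to-one, deterministic;
* ``Branch``     — (1, >=2): one-to-many, non-deterministic;
* ``Hourglass``  — (>=2, >=2): many-to-many, non-deterministic.

The balance of deterministic vs non-deterministic classes is a local
signature of song structure; it is compared against matched random-digraph
ensembles with per-class Z-scores and a chi-square test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .construction import SongDigraph
from .measures import z_score

__all__ = [
    "MOTIF_CLASSES",
    "MotifProfile",
    "MotifComparison",
    "classify_node",
    "motif_profile",
    "compare_profiles",
]

MOTIF_CLASSES: tuple[str, ...] = (
    "One-way",
    "Bottleneck",
    "Branch",
    "Hourglass",
    "Margin",
)


def classify_node(in_degree: int, out_degree: int) -> str:
    """Motif class for a node with the given in/out degrees."""
    if in_degree < 0 or out_degree < 0:
        raise ValueError(
            f"degrees must be non-negative, got ({in_degree}, {out_degree})"
        )
    if in_degree == 0 or out_degree == 0:
        return "Margin"
    if in_degree == 1:
        return "One-way" if out_degree == 1 else "Branch"
    return "Bottleneck" if out_degree == 1 else "Hourglass"


@dataclass(frozen=True)
class MotifProfile:
    """Per-class node counts for one digraph; counts sum to n."""

    counts: dict[str, int]
    n: int

    @property
    def proportions(self) -> dict[str, float]:
        return {c: self.counts.get(c, 0) / self.n for c in MOTIF_CLASSES}

    def count(self, cls: str) -> int:
        return self.counts.get(cls, 0)


def motif_profile(sdn: SongDigraph) -> MotifProfile:
    """Classify every node of the SDN; returns counts over the five classes."""
    if sdn.n == 0:
        raise ValueError("motif profile undefined for an empty digraph")
    counts = {c: 0 for c in MOTIF_CLASSES}
    g = sdn.graph
    for node in g.nodes():
        counts[classify_node(g.in_degree(node), g.out_degree(node))] += 1
    return MotifProfile(counts=counts, n=sdn.n)


@dataclass(frozen=True)
class MotifComparison:
    """Observed motif counts vs a null ensemble of profiles."""

    z: dict[str, float]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    chi2: float
    df: int
    pvalue: float
    pooled: tuple[str, ...] = ()


def compare_profiles(
    observed: MotifProfile, null_profiles: list[MotifProfile]
) -> MotifComparison:
    """Per-class Z-scores and a chi-square test against a null ensemble.

    Z uses counts: (observed count - null mean count) / null SD. The
    chi-square statistic compares observed counts with expected counts
    (null mean proportions times n) over the five classes, 4 degrees of
    freedom; classes with zero expected count are pooled into the smallest
    non-zero expected class first, reducing the degrees of freedom.
    """
    if len(null_profiles) < 2:
        raise ValueError("need >=2 null profiles for a comparison")
    n = observed.n
    null_counts = {
        c: np.array([p.count(c) for p in null_profiles], dtype=float)
        for c in MOTIF_CLASSES
    }
    null_mean = {c: float(v.mean()) for c, v in null_counts.items()}
    null_sd = {c: float(v.std(ddof=1)) for c, v in null_counts.items()}

    zs: dict[str, float] = {}
    for c in MOTIF_CLASSES:
        obs = observed.count(c)
        if null_sd[c] == 0:
            if obs == null_mean[c]:
                zs[c] = 0.0
            else:
                warnings.warn(
                    f"null SD is 0 for class {c!r} with observed != mean; "
                    "reporting infinite Z",
                    stacklevel=2,
                )
                zs[c] = float(np.sign(obs - null_mean[c]) * np.inf)
        else:
            zs[c] = z_score(obs, null_mean[c], null_sd[c])

    # expected counts from null mean proportions, scaled to observed n
    null_n = null_profiles[0].n
    expected = {c: null_mean[c] / null_n * n for c in MOTIF_CLASSES}
    obs_counts = {c: float(observed.count(c)) for c in MOTIF_CLASSES}

    pooled: list[str] = []
    zero = [c for c in MOTIF_CLASSES if expected[c] == 0]
    if zero:
        nonzero = [c for c in MOTIF_CLASSES if expected[c] > 0]
        if not nonzero:
            raise ValueError("all expected motif counts are zero")
        sink = min(nonzero, key=lambda c: expected[c])
        for c in zero:
            expected[sink] += expected[c]
            obs_counts[sink] += obs_counts[c]
            del expected[c], obs_counts[c]
            pooled.append(c)
        warnings.warn(
            f"pooled zero-expected motif class(es) {pooled} into {sink!r}",
            stacklevel=2,
        )

    cats = sorted(expected)
    f_obs = np.array([obs_counts[c] for c in cats])
    f_exp = np.array([expected[c] for c in cats])
    # chisquare requires matching totals; rescale expected to the observed sum
    f_exp = f_exp * f_obs.sum() / f_exp.sum()
    chi2, pvalue = stats.chisquare(f_obs, f_exp)
    return MotifComparison(
        z=zs,
        null_mean=null_mean,
        null_sd=null_sd,
        chi2=float(chi2),
        df=len(cats) - 1,
        pvalue=float(pvalue),
        pooled=tuple(pooled),
    )
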