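# songnet

Network-based analysis of complex birdsong (and other symbolic vocal
sequences).

Some birds — thrashers, mockingbirds, nightingales — sing songs built from
hundreds of distinct phrase types delivered in long, non-random sequences.
Repertoire size alone says little about how such a song is organised.
`songnet` treats a song as a walk on a *phrase-transition network* and
quantifies its structure with tools from complex-network theory:

* **Song networks.** From a corpus of bouts (ordered phrase-label
  sequences), the ordered transitions between successive phrases define the
  *song directed network* (SDN); forgetting direction gives the *song
  undirected network* (SUN). Immediate repeats of a phrase
  (self-transitions) are collapsed, so the networks have no self-loops, and
  transitions never cross bout boundaries.
* **Global measures.** Average path length *L* (mean shortest-path hops over
  reachable ordered pairs), clustering coefficient
  *C* = (1/n) Σᵢ Eᵢ/(kᵢ(kᵢ−1)/2), degree distribution *P(k)*, and
  small-world-ness *S* = (C/C_rand)/(L/L_rand); *S* > 1 marks a small-world
  song: tightly clustered phrase groups joined by short paths.
* **Transition motifs.** Each SDN node is classed by its (in-degree,
  out-degree): One-way (1,1), Bottleneck (≥2,1), Branch (1,≥2), Hourglass
  (≥2,≥2), Margin (no in- or no out-degree). The deterministic /
  non-deterministic balance of these classes is a local signature of song
  structure.
* **Null models.** Matched Erdős–Rényi-style random networks (RUN/RDN) with
  exactly the observed node count and edge/arc count (exact-count rejection
  sampling) give ensemble means, SDs and Z-scores; shuffled corpora preserve
  phrase frequencies while destroying transition context.
* **Robustness.** Rarefaction (measures on growing temporal prefixes) and
  misclassification-noise sweeps show which measures stabilise long before
  the repertoire is exhaustively sampled.
* **Synthetic ground truth.** Watts–Strogatz-style planted transition
  graphs plus teleporting random walks generate corpora with known
  structure, so the whole pipeline is testable without recordings.

## Worked example

Simulate a 3,000-token corpus from a planted small-world transition graph
(100 phrase types, ring lattice k = 6, 10% rewiring), then analyse it
against 1,000 matched random networks:

```bash
songnet simulate --n 100 --k 6 --beta 0.1 --length 3000 --bouts 7 \
    --restart 0.05 --seed 42 --out demo.txt
songnet analyze demo.txt --reps 1000 --seed 1 --out demo_report.json
```

Key numbers from `demo_report.json`:

```
SUN  n=100  edges=345  L=3.16  C=0.46  S=5.42
  L: observed 3.159   null 2.575 ± 0.014   Z = 42.3
  C: observed 0.456   null 0.069 ± 0.011   Z = 36.7
SDN  arcs=585  L=3.84  chi² = 3.5 (df 4, p = 0.48)
```

The observed clustering (*C* = 0.46) is far above the matched random
ensemble (0.069 ± 0.011, *Z* ≈ 37) while path lengths stay short, so
*S* = 5.42 ≫ 1: the pipeline detects the planted small-world structure. The
motif chi-square is non-significant here because a symmetric planted
lattice, like its matched random digraph, is dominated by Hourglass nodes —
real songs differ from their nulls precisely in this balance.

The same analysis runs on any corpus file with one bout per line and
whitespace-separated phrase labels (or a `bout_id,position,phrase` CSV):

```bash
songnet analyze my_bird.txt --reps 1000 --seed 1 --out report.json
songnet rarefy  my_bird.txt --step 100 --out rarefaction.csv
songnet noise   my_bird.txt --rates 0,0.01,0.05,0.1 --reps 100 --seed 1 --out noise.csv
```

Reports are JSON validating against `docs/report.schema.json`; every
Z-score in a report is recomputable from its observed/mean/SD triple.

## Library use

```python
import songnet as sn

corpus = sn.parse_corpus("my_bird.txt")
sdn, sun = sn.build_networks(corpus)
print(sn.average_path_length(sun), sn.clustering_coefficient(sun))
print(sn.motif_profile(sdn).proportions)
```
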