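# songnet

Sequential organisation of birdsong, analysed as directed syllable networks.

Many songbirds — here the collared flycatcher (*Ficedula albicollis*) — order
the syllables of their 3–5 s songs nonrandomly. `songnet` quantifies that
organisation, asks whether it differs from chance, whether it is an
individual attribute (repeatable across recordings), and whether it relates
to male quality and fitness proxies. It is written for behavioural
ecologists and bioacousticians who already have *labelled* syllable
sequences (audio segmentation and type clustering happen upstream) and want
the full statistical chain from sequences to biology.

## The model

Each recording (≈20 songs of one male) becomes a directed network: nodes are
syllable types, and an edge A→B exists when type A is immediately followed
by type B within a song (transition counts summed over songs; AB and BA are
distinct). Six variables describe each recording: repertoire size *n*,
syllable count, average degree `2E/n`, average shortest path (mean directed
distance over reachable ordered pairs), clustering coefficient (global
transitivity of the undirected projection), and the small-world coefficient
(Humphries & Gurney) `S = (C/C_rand)/(L/L_rand)` with Erdős–Rényi baselines
`C_rand = k̄/n`, `L_rand = ln n / ln k̄`.

Departure from chance is tested with a bout-preserving null: syllable order
is permuted *within* songs (100 replicates per recording), each recording's
deviation is expressed as Cohen's *d* against its null distribution, and the
per-male effects are pooled with a DerSimonian–Laird random-effects
meta-analysis weighted by sampling variances. The same machinery covers the
absolute mean-frequency shift between consecutive syllables (one shuffle,
two-sample *d*) and motif types — syllable subsequences of length 2–10
recurring in ≥2 songs — compared by paired Wilcoxon signed-rank tests.

Consistency is the adjusted repeatability `R = V_between/(V_between +
V_within)` from a REML random-intercept mixed model (age as covariate) on
size-corrected variables (residuals on repertoire size and syllable count),
with percentile CIs from a fully parametric bootstrap. Quality (age,
condition, arrival date) and fitness (pairing success, survival) models are
Gaussian LMs and binomial GLMs with likelihood-ratio tests.

Because the original field recordings are not public, the package ships a
seeded generator (`songnet.synthgen`) producing corpora with the same
statistical anatomy — individual grammars with chain backbones and Poisson
branching, spliced cross-song motifs, a frequency-alternation bias, grammar
perturbation between repeated recordings, and an age effect on branching —
with full ground truth for recovery tests.

## Worked example

```python
from songnet import seqnet, nullmodels
from songnet.song_data import recording_from_sequences

rec = recording_from_sequences([["A", "B", "C"], ["A", "B", "D"]])
m = seqnet.compute_metrics(rec)
print(m.repertoire_size, m.n_syllables, m.average_degree,
      m.average_shortest_path)
# 4 6 1.5 1.4
```

Four nodes and three directed edges (A→B counted twice in the weight matrix)
give mean total degree 2·3/4 = 1.5; the five reachable ordered pairs have
distances (1,2,2,1,1), mean 1.4.

The numbered scripts under `analysis/` run the full study on a synthetic
corpus (60 males plus 34/24/13 repeated pairs at the three time scales) and
write their tables to `results/`. On the default seed, `analysis/03` prints

```
pooled effect sizes (original vs within-song-randomized):
  average_degree             d =   -18.93 [-19.67, -18.19]  (original lower)
  average_shortest_path      d =   +19.79 [+18.31, +21.26]  (original higher)
  clustering_coefficient     d =    -6.59 [-7.16, -6.02]  (original lower)
  small_worldness            d =    -3.54 [-4.26, -2.81]  (original lower)
  freq_shift                 d =    +0.08 [+0.05, +0.11]  (original higher)
```

i.e. structured songs have sparser, longer-path networks than their
within-song shuffles and larger frequency jumps between consecutive
syllables, and `analysis/06` recovers the simulated negative age effect on
size-corrected average degree (LRT χ² = 7.98, p = 0.005) while the fitness
models stay null, as simulated. `songnet` is also a console tool
(`songnet simulate | metrics | nulltest | motifs | repeatability | all`).

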