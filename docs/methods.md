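# Methods

## From sequences to networks

The unit of analysis is a *recording*: an ordered collection of songs, each
an ordered sequence of syllable tokens carrying a type label and five
acoustic measurements (duration; minimum, maximum and mean frequency;
bandwidth). Networks are first-order: the weight matrix counts type A
immediately followed by type B within a song, summed over the recording's
songs, with no adjacency across song boundaries. Direction is preserved
(the matrix is asymmetric). Immediate repetitions of a type (self-loop
transitions) are always counted in the weight matrix but excluded from the
derived unweighted directed graph by default; `include_self_loops=True`
adds them as graph edges. Exclusion matches the usual conventions of graph
toolkits for degree/clustering, and the original treatment is not
documented, so the flag is exposed.

Metric conventions, chosen where the source material is silent:

- **Average degree** is mean *total* (in+out) degree of the unweighted
  directed graph, `2E/n`. Total degree is consistent with observed corpus
  scales (mean degree ≈3.5 at repertoire ≈47) and with reading connections
  as undirected adjacencies.
- **Average shortest path** is the mean *directed* distance over all
  reachable ordered pairs `u ≠ v`. Unreachable pairs are excluded rather
  than imputed so that the common disconnected-chain topologies still give
  finite values; a graph with no reachable pair yields NaN.
- **Clustering coefficient** is global transitivity (3·triangles /
  connected triples) of the undirected projection, 0 when no triple exists.
- **Small-worldness** is `S = (C/C_rand)/(L/L_rand)` on the undirected
  projection. The default baseline is analytic Erdős–Rényi (`C_rand = k̄/n`,
  `L_rand = ln n/ln k̄`); `montecarlo-er` instead averages transitivity and
  reachable-pair path length over `B` seeded G(n, m) graphs of identical
  size. `S` is NaN when `k̄ ≤ 1` (logarithm undefined / baseline degenerate)
  and 0 when `C = 0`. Undefined values propagate as NaN and are dropped,
  with a warning, wherever aggregation happens.

## Randomization null models and effect sizes

The null preserves everything except within-song order: each song's tokens
are permuted independently and uniformly (acoustic measurements travel with
their tokens), so song count, song lengths and per-song type multisets are
conserved. Each variable's deviation is summarised per recording as
Cohen's `d = (observed − null mean)/null SD` (sample SD over the default
100 replicates). Its sampling variance uses the standard two-group
small-sample form with `n1 = 1, n2 = n_reps`:
`var_d = (n1+n2)/(n1·n2) + d²/(2(n1+n2))`. A null distribution with zero
spread makes `d` undefined; the recording is excluded from pooling with a
warning.

Pooling is a DerSimonian–Laird random-effects meta-analysis: inverse-
variance weights give the fixed-effect mean and Cochran's Q; `τ² = max(0,
(Q − (k−1))/c)`; final weights `1/(var_d + τ²)`; 95% CI = pooled ± 1.96·SE.
Random effects (rather than fixed) reflect genuinely heterogeneous males; a
fixed-effect mode is exposed. The frequency-shift test compares the series
of |Δ mean frequency| of consecutive within-song pairs between the original
sequence and a *single* shuffled copy (each arm already holds ~190 pairs),
using the pooled-SD two-sample d with
`var_d = (n1+n2)/(n1·n2) + d²/(2(n1+n2))`.

All randomness flows from one top-level seed; each recording gets a
substream keyed by CRC32 of its identifier, so results are independent of
processing order and bit-reproducible.

## Motifs

A motif type of length L (2–10) is a contiguous type sequence occurring as
an exact substring in ≥2 *distinct* songs of a recording; repetition inside
a single song does not qualify by default (flag `count_within_song`
reverses this), and no gap or mismatch tolerance is applied. Counts are of
distinct types, not occurrences. Original and one-shuffle counts are
compared per length by the Wilcoxon signed-rank matched-pair test; the
reported W is the sum of positive ranks (ties receive average ranks, zero
differences are dropped), with the two-sided P from scipy. All-zero
differences at a length leave that test undefined (NaN).

## Repeatability

Consistency is estimated on a balanced design of exactly two recordings per
individual, for three time scales. The model is a Gaussian random-intercept
LMM (individual as random factor, male age as fixed covariate), estimated
by REML, and `R = V_between/(V_between+V_within)` — the adjusted
repeatability. The REML fit profiles the criterion over the variance ratio
`γ = V_between/V_within`: for a single random intercept, `V = σ²(I+γZZᵀ)`
has closed-form per-group inverse and determinant, so each evaluation is
O(n) and the fit is a bounded 1-D minimisation over `log γ ∈ [−16, 16]`
(boundary optima are mapped to `V_between = 0`, i.e. R = 0 without error).
This profile solver matches statsmodels' MixedLM REML to ~1e-5 on the same
data (asserted in the test suite) while being ~300× faster, which is what
makes fully parametric bootstrap CIs cheap: responses are re-simulated from
the fitted fixed effects and Gaussian variance components, refitted, and
the 2.5/97.5 percentiles of the bootstrap R taken (the basic-bootstrap
alternative is exposed). An estimate is called significant when the lower
CI bound exceeds 1e-6. At this design size the estimator is noisy by
nature: for 200 individuals × 2 records at true R = 0.5 its sampling SD is
≈0.054, so single-study estimates routinely move by ±0.1.

Variables are size-corrected before repeatability and trait modelling:
OLS residuals on repertoire size and syllable count (intercept included;
collinear covariates fall back to the minimum-norm solution with a
warning). Small-worldness is log-transformed first because its
distribution is strongly right-skewed; zeros become missing.

## Quality and fitness models

Quality models are Gaussian LMs of one size-corrected network variable on
condition, age and arrival date (continuous) and year (discrete, n_years−1
df). Fitness models are binomial (logit) GLMs of pairing success or
next-year survival on *both* candidate network variables together plus the
same covariates. Every term is tested by a likelihood-ratio χ² of the model
with vs without it; coefficient t/z values accompany 1-df terms. The
binomial pseudo-R² is McFadden's `1 − D/D₀`. Complete separation is
detected (all fitted probabilities at 0/1) and flagged rather than
penalised-refit. By default only variables with significant repeatability
at ≥1 time scale are candidate responses — a non-repeatable variable cannot
act as an individual signature — with an override flag. Bonferroni family
size defaults to the 2 responses tested. Arrival dates are centred on each
year's population median before modelling. The within-individual age
question uses a paired t-test across the between-year pairs; the default
tail is two-sided, with one-sided options exposed (at t = −2.0, df = 12 the
one-sided P is 0.034 and the two-sided 0.069, so reported borderline values
can depend on this choice).

## The synthetic corpus

The generator emulates the structure the analysis assumes, with analytic
ground truth rather than learned realism:

- **Grammar**: repertoire drawn from N(47, 19.8²) truncated to [12, 105];
  each type gets a mean frequency ~U(2, 8) kHz, duration ~U(0.05, 0.25) s
  and bandwidth ~U(0.5, 3) kHz. Transitions form a cyclic chain backbone
  plus Poisson(λ) distinct extra out-edges per type, λ = max(0, 1.0 −
  0.15·(age−1)) by default — branching falls with age, which is what makes
  older males' networks sparser. Transition probabilities are uniform over
  out-neighbours, optionally reweighted ∝ exp(β·|Δf|/1000) (β = 0.5
  default) to favour large frequency jumps.
- **Songs**: 20 per recording, lengths ~N(9.7, 3²) clipped at ≥2 (≈195
  syllables per recording, matching the observed 99–374 envelope); with
  probability 0.6 a song has one motif from the male's library (6 fixed
  sequences, lengths 3–8) spliced at a random position. Token acoustics
  jitter mildly around the type values with bandwidth/min/max kept exactly
  consistent.
- **Repeats and noise**: repeated recordings redraw each type's out-edges
  and each motif with probability ε/2 per session (ε = 0.05 within day,
  0.15 between days, 0.5 between years; between-year repeats also advance
  age). ε = 0 gives identical grammars, ε = 1 a full topological redraw.
- **Traits**: ages ~ truncated geometric (mean ≈1.9, max 7), arrival
  ~N(120, 7) days, condition ~N(0, 1); pairing and survival are Bernoulli
  with logistic intercepts 0.9/−0.4 (base rates ≈0.71/0.40) and
  configurable coefficients (zero by default, so fitness models are null by
  construction and serve as calibration).

What the generator does *not* emulate: higher-order (non-Markovian)
syntax beyond spliced motifs, social/neighbour context, population song
sharing, repertoire change with age, and measurement/segmentation error.
Passing recovery tests therefore shows the statistical chain is correct
under the assumed data-generating process, not that real corpora satisfy
those assumptions. Note also that even under a *full* grammar redraw some
individual signal persists in raw variables via repertoire size, age and
type acoustics — which is precisely why repeatability is computed on
size-corrected residuals.

## Problem sizes and runtime

The analysis scripts use 60 primary males and 34/24/13 repeat pairs with
100 null replicates and 1000 bootstrap iterations (minutes on one core).
The acceptance script uses 60 males, 100 replicates, 200 bootstrap
iterations. The test suite exercises reduced designs (10–50 individuals,
5–200 replicates) chosen to keep the full suite under a minute of compute
for the deterministic parts and a few minutes overall.
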