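"""Bout-preserving randomization tests for sequence organisation.

The null hypothesis is that syllables follow each other randomly *within*
songs.  Each randomized replicate permutes the token order independently in
every song, preserving song count, song lengths and each song's multiset of
syllable types (acoustic measurements travel with their tokens).  A network
variable's deviation from this null is summarised per recording as Cohen's d
against the null distribution, and the per-recording effect sizes are pooled
across males with a random-effects (DerSimonian-Laird) meta-analysis weighted
by their sampling variances.

The same machinery covers the spectral test: the absolute mean-frequency
shift between consecutive syllables, compared between the original sequence
and a single randomized copy with a two-sample Cohen's d.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import seqnet
from .song_data import Recording

__all__ = [
    "EffectSize",
    "MetaResult",
    "METRICS",
    "recording_rng",
    "shuffle_within_songs",
    "cohens_d_one_vs_null",
    "cohens_d_two_sample",
    "null_effects",
    "null_distribution",
    "pool_effect_sizes",
    "freq_shift_series",
    "freq_shift_effect",
    "effects_table",
]

#: Network variables testable against the within-song shuffle null.
METRICS: Mapping[str, Callable[[seqnet.SyllableNetwork], float]] = {
    "average_degree": seqnet.average_degree,
    "average_shortest_path": seqnet.average_shortest_path,
    "clustering_coefficient": seqnet.clustering_coefficient,
    "small_worldness": seqnet.small_worldness,
}


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d for one recording x variable, with its sampling variance."""

    recording_id: str
    variable_name: str
    observed: float
    null_mean: float
    null_sd: float
    n_null: int
    d: float
    var_d: float


@dataclass(frozen=True)
class MetaResult:
    """Random-effects pooled effect size across recordings."""

    variable_name: str
    k_studies: int
    pooled_d: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float


def recording_rng(seed: int, recording_id: str) -> np.random.Generator:
    """Stable per-recording RNG substream.

    Derived from the top-level seed and a CRC32 of the recording id, so the
    null draws for a recording do not depend on corpus processing order.
    """
    return np.random.default_rng([seed, zlib.crc32(recording_id.encode())])


def shuffle_within_songs(recording: Recording, rng: np.random.Generator) -> Recording:
    """Permute the token order independently and uniformly in every song."""
    new_songs = []
    for song in recording.songs:
        order = rng.permutation(len(song))
        new_songs.append(
            tuple(
                replace(song[j], position=pos) for pos, j in enumerate(order)
            )
        )
    return replace(recording, songs=tuple(new_songs))


def cohens_d_one_vs_null(observed: float, null_values: Sequence[float]) -> tuple[float, float]:
    """d of one observation against a null sample, with sampling variance.

    d = (observed - mean) / sd with the sample SD (ddof=1); the variance uses
    the standard two-group small-sample formula with n1 = 1, n2 = n:
    var_d = (n1+n2)/(n1*n2) + d^2 / (2*(n1+n2)).  NaN when the null sample
    has zero spread.
    """
    x = np.asarray(null_values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 null replicates")
    m = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return float("nan"), float("nan")
    d = (observed - m) / sd
    var_d = (1 + n) / n + d * d / (2 * (1 + n))
    return float(d), float(var_d)


def cohens_d_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Cohen's d with pooled SD, and its sampling variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 values per sample")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        return float("nan"), float("nan")
    d = (x.mean() - y.mean()) / np.sqrt(s2)
    var_d = (n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2))
    return float(d), float(var_d)


def null_effects(
    recording: Recording,
    metrics: Mapping[str, Callable] | Sequence[str] = ("average_degree", "average_shortest_path"),
    n_reps: int = 100,
    rng: np.random.Generator | None = None,
    include_self_loops: bool = False,
) -> list[EffectSize]:
    """Effect sizes of several variables against a shared set of shuffles.

    All requested metrics are evaluated on the *same* randomized replicates,
    mirroring an analysis where each randomized sequence yields all network
    variables at once.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not isinstance(metrics, Mapping):
        metrics = {name: METRICS[name] for name in metrics}
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")

    net = seqnet.build_network(recording, include_self_loops)
    observed = {name: fn(net) for name, fn in metrics.items()}
    nulls = {name: np.empty(n_reps) for name in metrics}
    for r in range(n_reps):
        shuf = shuffle_within_songs(recording, rng)
        snet = seqnet.build_network(shuf, include_self_loops)
        for name, fn in metrics.items():
            nulls[name][r] = fn(snet)

    out = []
    for name in metrics:
        vals = nulls[name][np.isfinite(nulls[name])]
        if vals.size < 2 or not np.isfinite(observed[name]):
            d = var_d = m = sd = float("nan")
            n_used = int(vals.size)
        else:
            d, var_d = cohens_d_one_vs_null(observed[name], vals)
            m, sd, n_used = float(vals.mean()), float(vals.std(ddof=1)), int(vals.size)
        out.append(
            EffectSize(recording.recording_id, name, float(observed[name]),
                       m, sd, n_used, d, var_d)
        )
    return out


def null_distribution(
    recording: Recording,
    metric: str,
    n_reps: int = 100,
    rng: np.random.Generator | None = None,
    include_self_loops: bool = False,
) -> EffectSize:
    """Effect size of one network variable against the within-song null."""
    return null_effects(recording, [metric], n_reps, rng, include_self_loops)[0]


def pool_effect_sizes(effects: Iterable[EffectSize], method: str = "DL") -> MetaResult:
    """Random-effects meta-analytic pooling of per-recording effect sizes.

    DerSimonian-Laird between-recording variance tau^2, inverse-variance
    weights 1/(var_d + tau^2), 95% normal CI.  ``method="FE"`` gives the
    fixed-effect model (tau^2 forced to 0).  Effects with undefined d are
    dropped with a warning.
    """
    effects = list(effects)
    names = {e.variable_name for e in effects}
    name = names.pop() if len(names) == 1 else "mixed"
    d = np.array([e.d for e in effects], dtype=float)
    v = np.array([e.var_d for e in effects], dtype=float)
    ok = np.isfinite(d) & np.isfinite(v) & (v > 0)
    if ok.sum() < len(effects):
        import warnings

        warnings.warn(
            f"pool_effect_sizes({name}): dropped {len(effects) - int(ok.sum())} "
            "recordings with undefined effect size"
        )
    d, v = d[ok], v[ok]
    k = d.size
    if k < 2:
        raise ValueError("need at least 2 usable effect sizes to pool")

    w = 1.0 / v
    mu_fe = float(np.sum(w * d) / np.sum(w))
    if method == "FE":
        tau2 = 0.0
    elif method == "DL":
        q = float(np.sum(w * (d - mu_fe) ** 2))
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    else:
        raise ValueError(f"unknown pooling method: {method!r}")

    ws = 1.0 / (v + tau2)
    mu = float(np.sum(ws * d) / np.sum(ws))
    se = float(1.0 / np.sqrt(np.sum(ws)))
    return MetaResult(name, k, mu, se, mu - 1.96 * se, mu + 1.96 * se, tau2)


def freq_shift_series(recording: Recording) -> np.ndarray:
    """|mean-frequency difference| of consecutive within-song syllable pairs."""
    out = []
    for song in recording.songs:
        freqs = np.array([t.mean_freq for t in song])
        out.append(np.abs(np.diff(freqs)))
    return np.concatenate(out) if out else np.array([])


def freq_shift_effect(recording: Recording, rng: np.random.Generator) -> EffectSize:
    """Original vs one-shuffle frequency-shift contrast as two-sample d.

    One randomized copy suffices here because every recording already
    contributes many consecutive pairs to each arm.
    """
    orig = freq_shift_series(recording)
    rand = freq_shift_series(shuffle_within_songs(recording, rng))
    if orig.size < 2:
        raise ValueError("need at least 2 consecutive pairs")
    d, var_d = cohens_d_two_sample(orig, rand)
    return EffectSize(
        recording.recording_id, "freq_shift", float(orig.mean()),
        float(rand.mean()), float(rand.std(ddof=1)), int(rand.size), d, var_d,
    )


def effects_table(effects: Iterable[EffectSize]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in effects])
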