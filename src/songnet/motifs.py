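"""Motif-type detection in categorical syllable sequences.

A *motif type* of length L is a contiguous sequence of syllable-type labels
that occurs, as an exact substring, in at least two distinct songs of the
same recording.  Repetition inside a single song does not qualify by default
(the signal of interest is cross-song reuse); an optional flag relaxes this
to "at least two occurrences anywhere".  Counts are of distinct motif types
per length, not of occurrences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .song_data import Recording

__all__ = ["MotifTable", "find_motifs", "compare_motif_counts"]


@dataclass(frozen=True)
class MotifTable:
    """Distinct motif-type counts per motif length for one recording."""

    recording_id: str
    counts: Mapping[int, int]

    def has_motif(self, length: int) -> bool:
        return self.counts.get(length, 0) >= 1


def find_motifs(
    recording: Recording,
    min_len: int = 2,
    max_len: int = 10,
    count_within_song: bool = False,
) -> MotifTable:
    """Count distinct motif types at each length in ``min_len..max_len``.

    With ``count_within_song=True`` a sequence repeated >= 2 times within one
    song also qualifies as a motif even if confined to that song.
    """
    if not (2 <= min_len <= max_len):
        raise ValueError("need 2 <= min_len <= max_len")
    sequences = [tuple(s) for s in recording.type_sequences()]
    counts: dict[int, int] = {}
    for L in range(min_len, max_len + 1):
        song_sets = []
        multi_within: set[tuple, ...] = set()
        for seq in sequences:
            subs = [seq[i : i + L] for i in range(len(seq) - L + 1)]
            if count_within_song:
                seen: set = set()
                for s in subs:
                    if s in seen:
                        multi_within.add(s)
                    seen.add(s)
            song_sets.append(set(subs))
        tally: dict[tuple, int] = {}
        for ss in song_sets:
            for s in ss:
                tally[s] = tally.get(s, 0) + 1
        motifs = {s for s, c in tally.items() if c >= 2} | multi_within
        counts[L] = len(motifs)
    return MotifTable(recording.recording_id, counts)


def _signed_rank_W(diffs: np.ndarray) -> float:
    """Sum of positive ranks T+ with average ranks for ties, zeros dropped."""
    nz = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(nz))
    return float(ranks[nz > 0].sum())


def compare_motif_counts(
    original: Sequence[MotifTable], randomized: Sequence[MotifTable]
) -> pd.DataFrame:
    """Per-length paired comparison of motif counts, original vs randomized.

    Tables are matched by recording_id.  For each motif length the Wilcoxon
    signed-rank statistic W (sum of positive ranks) and two-sided P are
    reported together with mean, SD and the percentage of recordings holding
    at least one motif, per arm.  Lengths where every paired difference is
    zero get NaN statistics.
    """
    orig_by_id = {t.recording_id: t for t in original}
    rand_by_id = {t.recording_id: t for t in randomized}
    ids = sorted(orig_by_id.keys() & rand_by_id.keys())
    if len(ids) < len(original) or len(ids) < len(randomized):
        warnings.warn("compare_motif_counts: unmatched recording ids dropped")
    if not ids:
        raise ValueError("no matched recording ids")

    lengths = sorted(
        {L for t in list(orig_by_id.values()) + list(rand_by_id.values()) for L in t.counts}
    )
    rows = []
    for L in lengths:
        x = np.array([orig_by_id[i].counts.get(L, 0) for i in ids], dtype=float)
        y = np.array([rand_by_id[i].counts.get(L, 0) for i in ids], dtype=float)
        diffs = x - y
        if np.all(diffs == 0):
            w_stat, p = float("nan"), float("nan")
        else:
            w_stat = _signed_rank_W(diffs)
            p = float(
                stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided").pvalue
            )
        rows.append(
            {
                "length": L,
                "n_pairs": len(ids),
                "mean_original": x.mean(),
                "sd_original": x.std(ddof=1) if len(x) > 1 else float("nan"),
                "min_original": x.min(),
                "max_original": x.max(),
                "pct_with_motif_original": 100.0 * (x >= 1).mean(),
                "mean_randomized": y.mean(),
                "sd_randomized": y.std(ddof=1) if len(y) > 1 else float("nan"),
                "min_randomized": y.min(),
                "max_randomized": y.max(),
                "pct_with_motif_randomized": 100.0 * (y >= 1).mean(),
                "W": w_stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def motif_table_frame(tables: Iterable[MotifTable], arm: str) -> pd.DataFrame:
    """Long-format motif counts (recording_id, arm, length, n_motif_types)."""
    rows = [
        {"recording_id": t.recording_id, "arm": arm, "length": L, "n_motif_types": c}
        for t in tables
        for L, c in sorted(t.counts.items())
    ]
    return pd.DataFrame(rows)
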