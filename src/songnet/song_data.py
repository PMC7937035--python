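"""Domain types, tabular I/O and validation for syllable sequences and male traits.

A *recording* is one sampled bout of a single male: an ordered collection of
songs, each an ordered sequence of syllable tokens.  Every token carries the
syllable-type label assigned upstream (by spectrographic clustering) together
with its five classical acoustic measurements.  The pipeline starts here, at
labelled sequences; audio handling and syllable segmentation are out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SyllableToken",
    "Recording",
    "SchemaError",
    "ValidationError",
    "SYLLABLE_COLUMNS",
    "TRAIT_COLUMNS",
    "read_syllable_table",
    "write_syllable_table",
    "recording_from_sequences",
    "truncate_songs",
    "read_traits_table",
    "standardize_arrival",
    "condition_index",
]

#: Required columns of the flat one-row-per-syllable table.
SYLLABLE_COLUMNS = [
    "recording_id",
    "individual_id",
    "year",
    "song_index",
    "position",
    "type_id",
    "duration_s",
    "min_freq_hz",
    "max_freq_hz",
    "mean_freq_hz",
    "bandwidth_hz",
]

#: Required columns of the male-trait table.
TRAIT_COLUMNS = [
    "individual_id",
    "year",
    "age",
    "arrival_raw",
    "condition",
    "pairing_success",
    "survival_next_year",
]

_BANDWIDTH_TOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row or recording violates a structural invariant."""


@dataclass(frozen=True)
class SyllableToken:
    """One performed syllable: type label plus acoustic measurements.

    Frequencies are in Hz, duration in seconds.  ``position`` is 0-based
    within the song.
    """

    song_index: int
    position: int
    type_id: str
    duration: float
    min_freq: float
    max_freq: float
    mean_freq: float
    bandwidth: float

    def validate(self) -> None:
        if self.song_index < 0 or self.position < 0:
            raise ValidationError(
                f"song_index/position must be non-negative, got "
                f"({self.song_index}, {self.position})"
            )
        if not self.duration > 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if not (self.min_freq <= self.mean_freq <= self.max_freq):
            raise ValidationError(
                f"frequency ordering violated: min={self.min_freq}, "
                f"mean={self.mean_freq}, max={self.max_freq}"
            )
        if abs(self.bandwidth - (self.max_freq - self.min_freq)) > _BANDWIDTH_TOL:
            raise ValidationError(
                f"bandwidth {self.bandwidth} != max-min "
                f"{self.max_freq - self.min_freq}"
            )


@dataclass(frozen=True)
class Recording:
    """An individual's sampled bout: ordered songs of ordered tokens."""

    recording_id: str
    individual_id: str
    year: int
    songs: tuple[tuple[SyllableToken, ...], ...]
    session_time: object | None = field(default=None, compare=False)

    @property
    def n_songs(self) -> int:
        return len(self.songs)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.songs)

    @property
    def syllable_types(self) -> list[str]:
        """Distinct type labels, sorted; their count is the repertoire size."""
        return sorted({t.type_id for s in self.songs for t in s})

    def type_sequences(self) -> list[list[str]]:
        return [[t.type_id for t in song] for song in self.songs]

    def validate(self) -> None:
        if not self.songs:
            raise ValidationError(f"recording {self.recording_id} has no songs")
        for song in self.songs:
            if not song:
                raise ValidationError(
                    f"recording {self.recording_id} contains an empty song"
                )
            idx = song[0].song_index
            for pos, tok in enumerate(song):
                tok.validate()
                if tok.song_index != idx:
                    raise ValidationError(
                        f"recording {self.recording_id}, song {idx}: token at "
                        f"position {pos} carries song_index {tok.song_index}"
                    )
                if tok.position != pos:
                    raise ValidationError(
                        f"recording {self.recording_id}, song {idx}: positions "
                        f"must be consecutive from 0 (expected {pos}, got "
                        f"{tok.position})"
                    )


def recording_from_sequences(
    sequences: Sequence[Sequence[str]],
    recording_id: str = "r0",
    individual_id: str = "i0",
    year: int = 2000,
    mean_freqs: dict[str, float] | None = None,
) -> Recording:
    """Build a :class:`Recording` from bare type-label sequences.

    Convenience for tests and examples; acoustic fields are filled with
    consistent placeholder values (or per-type ``mean_freqs`` if given).
    """
    songs = []
    for si, seq in enumerate(sequences):
        song = []
        for pos, label in enumerate(seq):
            f = (mean_freqs or {}).get(label, 4000.0)
            song.append(
                SyllableToken(
                    song_index=si,
                    position=pos,
                    type_id=str(label),
                    duration=0.1,
                    min_freq=f - 500.0,
                    max_freq=f + 500.0,
                    mean_freq=f,
                    bandwidth=1000.0,
                )
            )
        songs.append(tuple(song))
    rec = Recording(recording_id, individual_id, year, tuple(songs))
    rec.validate()
    return rec


def _check_columns(df: pd.DataFrame, required: Iterable[str]) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column '{col}' is missing")


def read_syllable_table(path, dialect: str = "csv") -> list[Recording]:
    """Read a flat syllable table into validated :class:`Recording` objects.

    One row per syllable token.  Recordings are grouped by ``recording_id``,
    songs ordered by ``song_index`` (gaps between song indices are allowed),
    tokens by ``position`` (which must be consecutive from 0 within a song).

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with the columns in :data:`SYLLABLE_COLUMNS`.
    dialect : {"csv", "tsv"}
        Field separator convention.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, SYLLABLE_COLUMNS)
    if df.empty:
        warnings.warn(f"{path}: table has a header but no rows")
        return []

    dup = df.duplicated(subset=["recording_id", "song_index", "position"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"duplicate (recording_id, song_index, position) at data row {row}"
        )

    recordings = []
    for rec_id, grp in df.groupby("recording_id", sort=True):
        ind = grp["individual_id"].iloc[0]
        year = int(grp["year"].iloc[0])
        songs = []
        for _, sgrp in grp.sort_values(["song_index", "position"]).groupby(
            "song_index", sort=True
        ):
            song = []
            for row_idx, row in sgrp.iterrows():
                tok = SyllableToken(
                    song_index=int(row["song_index"]),
                    position=int(row["position"]),
                    type_id=str(row["type_id"]),
                    duration=float(row["duration_s"]),
                    min_freq=float(row["min_freq_hz"]),
                    max_freq=float(row["max_freq_hz"]),
                    mean_freq=float(row["mean_freq_hz"]),
                    bandwidth=float(row["bandwidth_hz"]),
                )
                try:
                    tok.validate()
                except ValidationError as err:
                    raise ValidationError(f"data row {row_idx}: {err}") from None
                song.append(tok)
            songs.append(tuple(song))
        rec = Recording(str(rec_id), str(ind), year, tuple(songs))
        rec.validate()
        recordings.append(rec)
    return recordings


def recordings_to_frame(recordings: Iterable[Recording]) -> pd.DataFrame:
    rows = []
    for rec in recordings:
        for song in rec.songs:
            for tok in song:
                rows.append(
                    (
                        rec.recording_id,
                        rec.individual_id,
                        rec.year,
                        tok.song_index,
                        tok.position,
                        tok.type_id,
                        tok.duration,
                        tok.min_freq,
                        tok.max_freq,
                        tok.mean_freq,
                        tok.bandwidth,
                    )
                )
    return pd.DataFrame(rows, columns=SYLLABLE_COLUMNS)


def write_syllable_table(recordings: Iterable[Recording], path, dialect="csv") -> None:
    """Write recordings back to the flat one-row-per-syllable format."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    recordings_to_frame(recordings).to_csv(path, sep=sep, index=False)


def truncate_songs(recording: Recording, n_songs: int) -> Recording:
    """Keep the first ``n_songs`` songs (sample-size standardisation).

    Recordings with fewer songs are returned unchanged with a warning, so a
    corpus can be standardised to a common song count without dropping males.
    """
    if n_songs < 1:
        raise ValueError(f"n_songs must be >= 1, got {n_songs}")
    if recording.n_songs <= n_songs:
        if recording.n_songs < n_songs:
            warnings.warn(
                f"recording {recording.recording_id} has only "
                f"{recording.n_songs} songs (< {n_songs}); kept unchanged"
            )
        return recording
    return replace(recording, songs=recording.songs[:n_songs])


def read_traits_table(path, dialect: str = "csv") -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, TRAIT_COLUMNS)
    for col in ("pairing_success", "survival_next_year"):
        bad = ~df[col].dropna().isin([0, 1])
        if bad.any():
            raise ValidationError(f"column '{col}' must be binary 0/1")
    return df


def standardize_arrival(traits: pd.DataFrame) -> pd.DataFrame:
    """Centre arrival day on the yearly population median.

    Adds ``arrival_std = arrival_raw - median(arrival_raw | year)`` so that
    zero marks the median arrival of that year's population.  Rows with a
    missing ``arrival_raw`` get NaN and are excluded from the median.
    """
    out = traits.copy()
    med = out.groupby("year")["arrival_raw"].transform("median")
    out["arrival_std"] = out["arrival_raw"] - med
    n_missing = int(out["arrival_raw"].isna().sum())
    if n_missing:
        logger.warning("standardize_arrival: %d rows missing arrival_raw", n_missing)
    return out


def condition_index(weight: np.ndarray, tarsus: np.ndarray) -> np.ndarray:
    """Optional size-corrected body-condition score from weight and tarsus.

    Residuals of log weight regressed on log tarsus length.  The study's own
    condition index came from an external method whose formula is not part of
    this pipeline's inputs; normally ``condition`` arrives precomputed and
    this helper is only for corpora that ship raw morphometrics.
    """
    w = np.log(np.asarray(weight, dtype=float))
    t = np.log(np.asarray(tarsus, dtype=float))
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, w, rcond=None)
    return w - X @ beta
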