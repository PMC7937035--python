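import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from songnet import song_data, synthgen

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_song_recording():
    """Songs [A,B,C] and [A,B,D]: the canonical worked example."""
    return song_data.recording_from_sequences([["A", "B", "C"], ["A", "B", "D"]])


@pytest.fixture(scope="session")
def small_population():
    """10 synthetic individuals at reduced song count, for smoke tests."""
    cfg = synthgen.SimulationConfig(n_individuals=10, songs_per_recording=10,
                                    n_within_day=4, n_between_days=4,
                                    n_between_years=4, seed=42)
    return synthgen.simulate_population(cfg)


def random_recording(rng: np.random.Generator, n_songs=None, max_types=15,
                     max_len=12, rec_id="rX"):
    """A recording of uniformly random type sequences (no structure)."""
    n_songs = n_songs if n_songs is not None else int(rng.integers(1, 8))
    n_types = int(rng.integers(2, max_types + 1))
    seqs = [
        [f"t{v}" for v in rng.integers(0, n_types, size=int(rng.integers(1, max_len)))]
        for _ in range(n_songs)
    ]
    return song_data.recording_from_sequences(seqs, recording_id=rec_id)
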