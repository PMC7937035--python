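"""Shared configuration for the numbered analysis scripts.

The corpus is a scaled-down synthetic population (60 primary males; 34/24/13
repeated-recording pairs at the three time scales, mirroring the field
design) generated by ``01_simulate.py`` into ``results/corpus/``.  All
scripts are deterministic given SEED.
"""

from pathlib import Path

from songnet import synthgen

SEED = 20260929
RESULTS = Path(__file__).resolve().parent.parent / "results"
CORPUS = RESULTS / "corpus"

SIM_CONFIG = synthgen.SimulationConfig(
    n_individuals=60,
    n_within_day=34,
    n_between_days=24,
    n_between_years=13,
    seed=SEED,
)

SCALES = ("within_day", "between_days", "between_years")
NETWORK_VARS = ("average_degree", "average_shortest_path",
                "clustering_coefficient", "small_worldness")


def load_recordings():
    from songnet import song_data

    recs = song_data.read_syllable_table(CORPUS / "syllables.csv")
    primary = [r for r in recs if r.recording_id.endswith("_p")]
    pairs = {}
    for scale in SCALES:
        a = sorted((r for r in recs if r.recording_id.endswith(f"_{scale}_a")),
                   key=lambda r: r.recording_id)
        b = sorted((r for r in recs if r.recording_id.endswith(f"_{scale}_b")),
                   key=lambda r: r.recording_id)
        pairs[scale] = list(zip(a, b))
    return primary, pairs


def load_traits():
    import pandas as pd

    return pd.read_csv(CORPUS / "traits.csv")
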