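"""Network metrics and descriptive statistics of the primary corpus.

Builds the directed syllable network of every primary recording and writes
the six sequence-organisation variables (results/metrics.csv) plus the
degree/direction/weight percentage summaries (results/descriptives.csv).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import dataclasses

import pandas as pd
from common import RESULTS, load_recordings

from songnet import seqnet


def main():
    primary, _ = load_recordings()
    mt = seqnet.metrics_table(primary)
    mt.to_csv(RESULTS / "metrics.csv", index=False)
    desc = pd.DataFrame([
        dataclasses.asdict(
            seqnet.descriptive_stats(seqnet.build_network(r), r.recording_id))
        for r in primary
    ])
    desc.to_csv(RESULTS / "descriptives.csv", index=False)

    summ = mt[["repertoire_size", "n_syllables", "average_degree",
               "average_shortest_path", "clustering_coefficient",
               "small_worldness"]].agg(["mean", "std", "min", "max"]).T
    print(f"n = {len(mt)} recordings")
    print(summ.round(2).to_string())
    print(f"\nnodes with degree < 3: {desc.pct_nodes_degree_lt3.mean():.1f}% "
          f"| bidirectional connections: {desc.pct_edges_bidirectional.mean():.1f}% "
          f"| edges with weight > 1: {desc.pct_edges_weight_gt1.mean():.1f}%")


if __name__ == "__main__":
    main()
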