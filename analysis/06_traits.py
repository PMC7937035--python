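"""Quality and fitness models for the size-corrected network variables.

Gaussian LMs of size-corrected average degree and (log) small-worldness on
age, arrival date, condition and year; binomial GLMs of pairing success and
next-year survival on both network variables plus the same covariates; and
the paired t-test of within-individual change in average degree across the
between-year recording pairs.  Writes results/models.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
import pandas as pd
from common import RESULTS, load_recordings, load_traits

from songnet import consistency, seqnet, traits


def main():
    primary, pairs = load_recordings()
    tr = load_traits()
    mt = pd.read_csv(RESULTS / "metrics.csv")
    resid = pd.read_csv(RESULTS / "residuals.csv")
    mt["individual_id"] = [r.individual_id for r in primary]
    merged = mt.merge(resid, on="recording_id").merge(tr, on="individual_id")

    reports = []
    for name in ("average_degree", "small_worldness"):
        reports.append(traits.fit_quality_model(
            merged[name + "_resid"], merged, response_name=name))
    net = merged[["average_degree_resid", "small_worldness_resid"]]
    for fit_name in ("pairing_success", "survival_next_year"):
        reports.append(traits.fit_fitness_model(
            merged[fit_name], net, merged, response_name=fit_name))
    table = traits.model_report_frame(reports)
    table.to_csv(RESULTS / "models.csv", index=False)

    print("quality models (Gaussian LM, LRT):")
    for _, r in table[table.family == "gaussian"].iterrows():
        print(f"  {r.response:<16s} {r.term:<12s} est = {r.estimate:+7.3f} "
              f"chi2 = {r.lrt_chi2:6.2f} (df {int(r.df)}) p = {r.p_raw:.3g}")
    print("fitness models (binomial GLM, LRT):")
    for _, r in table[table.family == "binomial"].iterrows():
        print(f"  {r.response:<20s} {r.term:<22s} chi2 = {r.lrt_chi2:6.2f} "
              f"p = {r.p_raw:.3g}")

    by = pairs["between_years"]
    if len(by) >= 2:
        def size_corrected_degree(recs):
            ms = [seqnet.compute_metrics(r) for r in recs]
            return consistency.residualize(
                np.array([m.average_degree for m in ms]),
                np.array([m.repertoire_size for m in ms], float),
                np.array([m.n_syllables for m in ms], float))
        all_recs = [r for ab in by for r in ab]
        rv = size_corrected_degree(all_recs)
        t, df, p = traits.paired_within_individual_test(rv[0::2], rv[1::2])
        print(f"\nwithin-individual change in average degree across years: "
              f"paired t = {t:.2f}, df = {df}, p = {p:.3f} (two-sided)")


if __name__ == "__main__":
    main()
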