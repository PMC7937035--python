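"""Inter-correlations, size correction, and repeatability across time scales.

Pearson correlations (Bonferroni-adjusted over the 15 pairs) among the six
variables; residualization of the four network variables on repertoire size
and syllable count; adjusted repeatability (REML random-intercept model with
age, 1000-iteration parametric bootstrap) of the size-corrected variables at
the within-day, between-day and between-year scales.  Writes
results/correlations.csv, results/residuals.csv, results/repeatability.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import dataclasses

import numpy as np
import pandas as pd
from common import NETWORK_VARS, RESULTS, SCALES, SEED, load_recordings, load_traits

from songnet import consistency, seqnet


def main():
    primary, pairs = load_recordings()
    traits = load_traits()
    age_by_ind = dict(zip(traits.individual_id, traits.age))

    mt = pd.read_csv(RESULTS / "metrics.csv")
    rho, padj = consistency.correlation_matrix(
        mt[["repertoire_size", "n_syllables", *NETWORK_VARS]])
    pd.concat({"rho": rho, "p_bonferroni": padj}, names=["quantity"]).to_csv(
        RESULTS / "correlations.csv")

    resid = mt[["recording_id"]].copy()
    for name in NETWORK_VARS:
        vals = mt[name].to_numpy(float)
        if name == "small_worldness":
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.log(vals)  # right-skewed; matches the LM stage
            vals[~np.isfinite(vals)] = np.nan
        ok = np.isfinite(vals)
        col = np.full(len(mt), np.nan)
        col[ok] = consistency.residualize(
            vals[ok], mt.repertoire_size.to_numpy(float)[ok],
            mt.n_syllables.to_numpy(float)[ok])
        resid[name + "_resid"] = col
    resid.to_csv(RESULTS / "residuals.csv", index=False)
    print("strongest size confound (|rho| of raw variables vs repertoire):")
    for name in NETWORK_VARS:
        print(f"  {name:<26s} rho = {rho.loc['repertoire_size', name]:+.2f}")

    rows = []
    print("\nadjusted repeatability of size-corrected variables:")
    for scale in SCALES:
        recs = [r for ab in pairs[scale] for r in ab]
        ms = [seqnet.compute_metrics(r) for r in recs]
        reps = np.array([m.repertoire_size for m in ms], float)
        nsyl = np.array([m.n_syllables for m in ms], float)
        ids = np.array([r.individual_id for r in recs])
        ages = np.array([age_by_ind[i] for i in ids], float)
        for name in NETWORK_VARS:
            vals = np.array([getattr(m, name) for m in ms])
            ok = np.isfinite(vals)
            keep = {i for i in np.unique(ids) if (ok & (ids == i)).sum() == 2}
            mask = ok & np.isin(ids, sorted(keep))
            if len(keep) < 2:
                continue
            rv = consistency.residualize(vals[mask], reps[mask], nsyl[mask])
            res = consistency.repeatability(
                rv, ids[mask], ages[mask], n_boot=1000,
                rng=np.random.default_rng([SEED, 2, len(rows)]),
                variable_name=name, time_scale=scale)
            rows.append(dataclasses.asdict(res))
            star = "*" if res.significant else " "
            print(f"  {scale:<14s} {name:<26s} R = {res.r:.2f} "
                  f"[{res.ci_low:.2f}, {res.ci_high:.2f}]{star} "
                  f"(n = {res.n_individuals})")
    pd.DataFrame(rows).to_csv(RESULTS / "repeatability.csv", index=False)


if __name__ == "__main__":
    main()
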