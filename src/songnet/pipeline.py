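"""End-to-end orchestration of the sequence-organisation analysis.

Stages: (simulate) -> validate/truncate -> networks & metrics -> descriptive
stats -> randomization null test -> frequency-shift test -> motifs ->
size-correction & correlations -> repeatability -> trait and fitness models.
Each stage writes a CSV artifact so stages are independently inspectable; a
run manifest records the configuration hash, seed and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consistency, motifs, nullmodels, seqnet, song_data, synthgen, traits

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Defaults reproduce the analysis constants: 100 randomized sequences per
    recording, 1000 bootstrap iterations, 20 songs per recording, motif
    lengths 2-10.
    """

    out_dir: str = "results"
    syllables_path: str | None = None
    traits_path: str | None = None
    simulate: bool = False
    sim: synthgen.SimulationConfig | None = None
    seed: int = 0
    n_null_reps: int = 100
    n_boot: int = 1000
    songs_per_recording: int = 20
    motif_min_len: int = 2
    motif_max_len: int = 10
    include_self_loops: bool = False
    sw_mode: str = "analytic-er"
    paired_tail: str = "two-sided"
    restrict_to_repeatable: bool = True
    bonferroni_m: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = synthgen.SimulationConfig(**sim)
        return cfg

    def manifest(self) -> dict:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return {
            "config": payload,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }


def _pooled_row(meta: nullmodels.MetaResult) -> dict:
    return dataclasses.asdict(meta)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and return the map of written artifacts.

    Any stage failure aborts with an error naming the stage; artifacts
    already written are retained.  Missing trait data skips the trait and
    fitness stages with a warning.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        # ---- input acquisition -------------------------------------------
        stage = "simulate" if config.simulate else "load"
        repeats: dict[str, list[tuple]] = {}
        traits_df = None
        if config.simulate:
            sim = config.sim or synthgen.SimulationConfig(seed=config.seed)
            pop = synthgen.simulate_population(sim)
            recordings = pop.recordings
            repeats = pop.repeats
            traits_df = pop.traits
            synthgen.write_population(pop, out / "corpus")
        else:
            recordings = song_data.read_syllable_table(config.syllables_path)
            if config.traits_path and Path(config.traits_path).exists():
                traits_df = song_data.read_traits_table(config.traits_path)
                if "arrival_std" not in traits_df:
                    traits_df = song_data.standardize_arrival(traits_df)
            else:
                warnings.warn("no traits table: trait/fitness stages will be skipped")

        stage = "truncate"
        recordings = [
            song_data.truncate_songs(r, config.songs_per_recording) for r in recordings
        ]

        # ---- networks and metrics ----------------------------------------
        stage = "metrics"
        mt = seqnet.metrics_table(
            recordings, config.include_self_loops, config.sw_mode,
            rng=np.random.default_rng([config.seed, 1]),
        )
        artifacts["metrics"] = out / "metrics.csv"
        mt.to_csv(artifacts["metrics"], index=False)

        stage = "descriptives"
        rows = []
        for rec in recordings:
            net = seqnet.build_network(rec, config.include_self_loops)
            rows.append(dataclasses.asdict(seqnet.descriptive_stats(net, rec.recording_id)))
        artifacts["descriptives"] = out / "descriptives.csv"
        pd.DataFrame(rows).to_csv(artifacts["descriptives"], index=False)

        # ---- null models --------------------------------------------------
        stage = "nulltest"
        all_effects = []
        for rec in recordings:
            rng = nullmodels.recording_rng(config.seed, rec.recording_id)
            all_effects.extend(
                nullmodels.null_effects(
                    rec, list(nullmodels.METRICS), config.n_null_reps, rng,
                    config.include_self_loops,
                )
            )
        eff_df = nullmodels.effects_table(all_effects)
        artifacts["effects"] = out / "effects.csv"
        eff_df.to_csv(artifacts["effects"], index=False)

        meta_rows = []
        for name in nullmodels.METRICS:
            es = [e for e in all_effects if e.variable_name == name]
            try:
                meta_rows.append(_pooled_row(nullmodels.pool_effect_sizes(es)))
            except ValueError:
                warnings.warn(f"pooling skipped for {name}: too few usable effects")

        stage = "freq_shift"
        fs_effects = []
        for rec in recordings:
            rng = nullmodels.recording_rng(config.seed + 1, rec.recording_id)
            try:
                fs_effects.append(nullmodels.freq_shift_effect(rec, rng))
            except ValueError:
                pass
        if len(fs_effects) >= 2:
            meta_rows.append(_pooled_row(nullmodels.pool_effect_sizes(fs_effects)))
        artifacts["meta"] = out / "meta.csv"
        pd.DataFrame(meta_rows).to_csv(artifacts["meta"], index=False)

        # ---- motifs -------------------------------------------------------
        stage = "motifs"
        orig_tables, rand_tables = [], []
        for rec in recordings:
            rng = nullmodels.recording_rng(config.seed + 2, rec.recording_id)
            orig_tables.append(
                motifs.find_motifs(rec, config.motif_min_len, config.motif_max_len)
            )
            rand_tables.append(
                motifs.find_motifs(
                    nullmodels.shuffle_within_songs(rec, rng),
                    config.motif_min_len, config.motif_max_len,
                )
            )
        artifacts["motifs"] = out / "motifs.csv"
        pd.concat(
            [
                motifs.motif_table_frame(orig_tables, "original"),
                motifs.motif_table_frame(rand_tables, "randomized"),
            ]
        ).to_csv(artifacts["motifs"], index=False)
        artifacts["motif_tests"] = out / "motif_tests.csv"
        motifs.compare_motif_counts(orig_tables, rand_tables).to_csv(
            artifacts["motif_tests"], index=False
        )

        # ---- size correction and correlations ----------------------------
        stage = "consistency"
        varnames = [
            "average_degree", "average_shortest_path",
            "clustering_coefficient", "small_worldness",
        ]
        corr_cols = ["repertoire_size", "n_syllables"] + varnames
        rho, padj = consistency.correlation_matrix(mt[corr_cols])
        artifacts["correlations"] = out / "correlations.csv"
        pd.concat({"rho": rho, "p_bonferroni": padj}, names=["quantity"]).to_csv(
            artifacts["correlations"]
        )

        resid = mt[["recording_id"]].copy()
        for name in varnames:
            vals = mt[name].to_numpy(float)
            if name == "small_worldness":
                with np.errstate(divide="ignore", invalid="ignore"):
                    vals = np.log(vals)
                vals[~np.isfinite(vals)] = np.nan
            ok = np.isfinite(vals)
            col = np.full(len(mt), np.nan)
            if ok.sum() >= 4:
                col[ok] = consistency.residualize(
                    vals[ok],
                    mt["repertoire_size"].to_numpy(float)[ok],
                    mt["n_syllables"].to_numpy(float)[ok],
                )
            resid[name + "_resid"] = col
        artifacts["residuals"] = out / "residuals.csv"
        resid.to_csv(artifacts["residuals"], index=False)

        # ---- repeatability ------------------------------------------------
        stage = "repeatability"
        rep_results = []
        age_by_ind = (
            dict(zip(traits_df["individual_id"], traits_df["age"]))
            if traits_df is not None else {}
        )
        for scale, pairs in repeats.items():
            if len(pairs) < 2:
                continue
            pair_metrics = []
            for a, b in pairs:
                for rec in (a, b):
                    m = seqnet.compute_metrics(rec, config.include_self_loops,
                                               config.sw_mode)
                    pair_metrics.append((rec.individual_id, m))
            for name in varnames:
                vals = np.array([getattr(m, name) for _, m in pair_metrics])
                ids = np.array([i for i, _ in pair_metrics])
                ok = np.isfinite(vals)
                keep_ids = {i for i in np.unique(ids) if (ok & (ids == i)).sum() == 2}
                mask = np.array([i in keep_ids for i in ids]) & ok
                if len(keep_ids) < 2:
                    continue
                ages = (
                    np.array([age_by_ind.get(i, np.nan) for i in ids[mask]])
                    if age_by_ind else None
                )
                if ages is not None and not np.isfinite(ages).all():
                    ages = None
                res = consistency.repeatability(
                    vals[mask], ids[mask], ages, n_boot=config.n_boot,
                    rng=np.random.default_rng(
                        [config.seed, 3, zlib.crc32(scale.encode())]
                    ),
                    variable_name=name, time_scale=scale,
                )
                rep_results.append(res)
        artifacts["repeatability"] = out / "repeatability.csv"
        pd.DataFrame([dataclasses.asdict(r) for r in rep_results]).to_csv(
            artifacts["repeatability"], index=False
        )

        # ---- trait and fitness models ------------------------------------
        if traits_df is not None:
            stage = "traits"
            merged = mt.copy()
            merged["individual_id"] = [r.individual_id for r in recordings]
            merged = merged.merge(resid, on="recording_id")
            merged = merged.merge(traits_df, on="individual_id", how="inner")
            responses = ["average_degree", "small_worldness"]
            if config.restrict_to_repeatable and rep_results:
                eligible = traits.select_repeatable_responses(rep_results)
                responses = [r for r in responses if r in eligible] or responses
            reports = []
            for name in responses:
                col = name + "_resid"
                sub = merged.dropna(subset=[col])
                reports.append(
                    traits.fit_quality_model(
                        sub[col], sub, response_name=name,
                        bonferroni_m=config.bonferroni_m,
                    )
                )
            netv = merged[[r + "_resid" for r in responses]]
            for fit_name in ("pairing_success", "survival_next_year"):
                try:
                    reports.append(
                        traits.fit_fitness_model(
                            merged[fit_name], netv, merged, response_name=fit_name,
                            bonferroni_m=config.bonferroni_m,
                        )
                    )
                except ValueError as err:
                    warnings.warn(f"fitness model {fit_name} skipped: {err}")
            artifacts["models"] = out / "models.csv"
            traits.model_report_frame(reports).to_csv(artifacts["models"], index=False)
        else:
            logger.warning("trait stages skipped (no traits table)")

        stage = "manifest"
        manifest = config.manifest()
        manifest["artifacts"] = {k: str(v) for k, v in artifacts.items()}
        artifacts["manifest"] = out / "manifest.json"
        artifacts["manifest"].write_text(json.dumps(manifest, indent=1, default=str))
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    return artifacts
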