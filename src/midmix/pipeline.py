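"""End-to-end pipeline: simulate → prep → select → mix → lisst → report.

Configuration is a flat mapping (typically loaded from YAML); a single
global seed deterministically derives every stage's random stream, so a
rerun with the same config is byte-identical.  Each stage writes its CSV/JSON
outputs under the configured output directory and the run manifest records
seeds, stage timings and input hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import foodweb, isotope_prep, particle_field, tracer_selection
from .mixing_model import (MixingModelSpec, run_mcmc, summarize_sources)
from .synthetic import StudyConfig, generate_study

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "fit_consumers"]

ALL_STAGES = ("simulate", "prep", "select", "mix", "lisst", "report")


@dataclass
class PipelineConfig:
    outdir: str = "midmix_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    schedule: str = "reduced"  # "paper" (3x100k/50) or "reduced"
    alpha: float = 0.05
    max_missing: int = 4
    n_perm: int = 999
    outlier_rule: str = "tukey"
    census_threshold: float = 0.5
    measurement_sd: float = 0.5
    write_draws: bool = False

    def mixing_spec(self) -> MixingModelSpec:
        kw = dict(measurement_sd=self.measurement_sd, seed=self.seed)
        if self.schedule == "paper":
            return MixingModelSpec(**kw)
        return MixingModelSpec.reduced(**kw)


_FIELD_TYPES = {f.name: f.type for f in PipelineConfig.__dataclass_fields__.values()}


def validate_config(raw: dict) -> PipelineConfig:
    """Typed, defaulted config; all problems are reported in one error."""
    errors = []
    raw = dict(raw or {})
    known = set(PipelineConfig.__dataclass_fields__)
    for key in sorted(set(raw) - known):
        errors.append(f"unknown config key: {key!r}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if "seed" not in raw:
        warnings.warn("no seed given; defaulting to 0")
    if cfg.schedule not in ("paper", "reduced"):
        errors.append(f"schedule must be 'paper' or 'reduced', got {cfg.schedule!r}")
    if not 0 < cfg.alpha <= 1:
        errors.append(f"alpha must be in (0, 1], got {cfg.alpha}")
    if cfg.max_missing < 1:
        errors.append(f"max_missing must be >= 1, got {cfg.max_missing}")
    if cfg.n_perm < 1:
        errors.append(f"n_perm must be >= 1, got {cfg.n_perm}")
    if cfg.outlier_rule not in ("tukey", "none"):
        errors.append(f"outlier_rule must be 'tukey' or 'none', got {cfg.outlier_rule!r}")
    if not 0 <= cfg.census_threshold <= 1:
        errors.append(f"census_threshold must be in [0, 1], got {cfg.census_threshold}")
    if cfg.measurement_sd <= 0:
        errors.append(f"measurement_sd must be positive, got {cfg.measurement_sd}")
    unknown_stages = set(cfg.stages) - set(ALL_STAGES)
    if unknown_stages:
        errors.append(f"unknown stages: {sorted(unknown_stages)}")
    if errors:
        raise ValueError("invalid pipeline config:\n- " + "\n- ".join(errors))
    return cfg


def fit_consumers(consumer_table: pd.DataFrame, src, spec: MixingModelSpec,
                  tracers: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the mixing model for every consumer row.

    Returns (summary table, stacked retained draws).  Each consumer gets its
    own seeded spec derived from (spec.seed, consumer index) so results are
    order-independent and reproducible.
    """
    from dataclasses import replace

    summaries, draw_frames = [], []
    for i, row in consumer_table.reset_index(drop=True).iterrows():
        sub_seed = int(np.random.SeedSequence(spec.seed, spawn_key=(100 + i,))
                       .generate_state(1)[0] % (2 ** 31))
        post = run_mcmc(row[tracers].to_numpy(dtype=float), src,
                        replace(spec, seed=sub_seed),
                        consumer_id=str(row["consumer_id"]))
        pooled = post.pooled
        flat = pooled.flat
        rec = {
            "consumer_id": row["consumer_id"],
            "group": row.get("group"),
            "depth_m": row.get("depth_m", np.nan),
        }
        for j, frac in enumerate(post.fractions):
            rec[f"p_{frac}_mean"] = post.mean[j]
            rec[f"p_{frac}_sd"] = post.sd[j]
        lab_small = pooled.fractions.index("small")
        lab_large = pooled.fractions.index("large")
        rec["p_small_mean"] = pooled.mean[lab_small]
        rec["p_large_mean"] = pooled.mean[lab_large]
        rec["p_large_sd"] = pooled.sd[lab_large]
        rec["p_large_prob_ge_half"] = float(np.mean(flat[:, lab_large] >= 0.5))
        rec["rhat_max"] = float(np.nanmax(post.rhat)) if post.rhat is not None else np.nan
        rec["converged"] = post.converged
        summaries.append(rec)
        n_chains, n_draws, K = post.draws.shape
        dd = pd.DataFrame(post.draws.reshape(-1, K),
                          columns=[f"p_{f}" for f in post.fractions])
        dd.insert(0, "consumer_id", row["consumer_id"])
        dd.insert(1, "chain", np.repeat(np.arange(n_chains), n_draws))
        dd.insert(2, "draw", np.tile(np.arange(n_draws), n_chains))
        draw_frames.append(dd)
    return pd.DataFrame(summaries), pd.concat(draw_frames, ignore_index=True)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | dict,
                 study_config: StudyConfig | None = None) -> dict:
    """Execute the configured stages and return the run manifest."""
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config),
                      "stages": {}, "outputs": {}}
    t_all = time.time()
    study = None

    def _need_study():
        nonlocal study
        if study is None:
            sc = study_config or StudyConfig(seed=config.seed)
            study = generate_study(sc)
        return study

    def _save(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False)
        manifest["outputs"][name] = _hash_file(path)
        return path

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        if stage == "simulate":
            st = _need_study()
            _save(st.source_table, "source_samples.csv")
            _save(st.consumer_table, "consumers.csv")
            _save(st.aa_conc_table, "aa_conc.csv")
            _save(st.trait_table, "traits.csv")
            _save(st.tracer_table, "tracer_table.csv")
            for cast in st.lisst_casts:
                _save(cast.data, f"lisst_cast_{cast.cast_id}.csv")
        elif stage == "prep":
            st = _need_study()
            flagged = isotope_prep.flag_outliers(st.aa_conc_table,
                                                 rule=config.outlier_rule)
            _save(flagged, "aa_conc_flagged.csv")
            results = [isotope_prep.compare_groups_anova(flagged, frac)
                       for frac in ("small", "medium", "large")]
            _save(pd.DataFrame([asdict_anova(r) for r in results]), "aa_anova.csv")
            manifest["aa_contrasts"] = [asdict_anova(r) for r in results]
        elif stage == "select":
            st = _need_study()
            ts = tracer_selection.select_tracers(
                st.tracer_table, alpha=config.alpha,
                max_missing=config.max_missing, n_perm=config.n_perm,
                seed=config.seed)
            (outdir / "tracer_set.json").write_text(
                json.dumps(ts.to_dict(), indent=2, default=str))
            manifest["outputs"]["tracer_set.json"] = _hash_file(outdir / "tracer_set.json")
            manifest["tracers"] = ts.selected
        elif stage == "mix":
            st = _need_study()
            tracers = manifest.get("tracers") or list(st.config.tracer_names)
            available = set(st.source_table["tracer"].unique())
            tracers = [t for t in tracers if t in available]
            src = summarize_sources(st.source_table, tracers)
            spec = config.mixing_spec()
            summary, draws = fit_consumers(st.consumer_table, src, spec, tracers)
            _save(summary, "mixing_summary.csv")
            if config.write_draws:
                _save(draws, "posterior_draws.csv")
            manifest["n_consumers"] = len(summary)
        elif stage == "lisst":
            st = _need_study()
            profiles, modes = [], []
            for cast in st.lisst_casts:
                cal = particle_field.baseline_calibrate(
                    particle_field.bin_to_depth(cast))
                fr = particle_field.aggregate_fractions(cal)
                fr.insert(0, "cast_id", cast.cast_id)
                fr.insert(1, "cast_type", cast.cast_type)
                profiles.append(fr)
                window = ((st.config.lisst.plume_center - 25,
                           st.config.lisst.plume_center + 25)
                          if cast.cast_type == "plume"
                          else (cal.depths.min(), cal.depths.max()))
                mx = particle_field.psd_maxima(cal, window)
                modes.append({"cast_id": cast.cast_id, "cast_type": cast.cast_type,
                              "modal_um": float(mx[0]) if len(mx) else np.nan})
            _save(pd.concat(profiles, ignore_index=True), "fraction_profiles.csv")
            _save(pd.DataFrame(modes), "psd_modes.csv")
        elif stage == "report":
            st = _need_study()
            mix_path = outdir / "mixing_summary.csv"
            if not mix_path.exists():
                raise RuntimeError("report stage requires the mix stage outputs")
            summary = pd.read_csv(mix_path)
            census = foodweb.threshold_census(summary,
                                              threshold=config.census_threshold)
            groups = foodweb.group_contributions(summary)
            guilds = pd.concat([foodweb.guild_proportions(st.trait_table),
                                foodweb.guild_proportions(st.trait_table,
                                                          weights="density")],
                               ignore_index=True)
            report = foodweb.build_report(
                census, groups, guilds,
                aa_contrasts=None, seed=config.seed)
            if "aa_contrasts" in manifest:
                report["aa_contrasts"] = manifest["aa_contrasts"]
            (outdir / "report.json").write_text(json.dumps(report, indent=2))
            (outdir / "report.md").write_text(foodweb.render_report_md(report))
            manifest["outputs"]["report.json"] = _hash_file(outdir / "report.json")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def asdict_anova(r) -> dict:
    return {"fraction": r.fraction, "F": r.F, "p": r.p,
            "df_between": r.df_between, "df_within": r.df_within,
            "group_sizes": list(r.group_sizes)}
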