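"""End-to-end orchestration: simulate -> calibrate -> quantify -> stats.

Each stage is independently re-runnable from the documented file formats;
the run manifest records the seed, a hash of the configuration and
per-stage row counts, so identical config + seed yields identical
manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .bias import (ModelSpec, atrophy_target_analysis,
                   factor_age_correlations, fit_gee, marginal_means,
                   pairwise_deltas, stratify_amyloid, wald_type3)
from .calibration import CalibrationConfig, calibrate
from .cohort import CohortConfig, generate_cohort
from .errors import ConfigError, StageError
from .phantom import PhantomSpec
from .precision import (bland_altman, ci_profile, icc_agreement,
                        variance_decomposition)
from .quantify import enumerate_pipelines, quantify_cohort

logger = logging.getLogger("centistress")

STAGE_EXIT_CODES = {"simulate": 10, "calibrate": 11, "quantify": 12,
                    "stratify": 13, "bias": 14, "precision": 15, "export": 16}


@dataclass
class RunConfig:
    """Configuration of a full stress-testing run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    pipelines: str | list[str] = "all"
    models: tuple[str, ...] = ("main", "precision")
    out_dir: str = "centistress-out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        phantom_raw = cohort_raw.pop("phantom", None)
        if phantom_raw is not None:
            phantom_raw["grid_shape"] = tuple(phantom_raw.get(
                "grid_shape", (48, 48, 48)))
            cohort_raw["phantom"] = PhantomSpec(**phantom_raw)
        calib_raw = raw.pop("calibration", {})
        if "cl_levels" in calib_raw:
            calib_raw["cl_levels"] = tuple(calib_raw["cl_levels"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(cohort=CohortConfig(**cohort_raw),
                   calibration=CalibrationConfig(**calib_raw), **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def pipeline_specs(self):
        specs = enumerate_pipelines()
        if self.pipelines == "all":
            return specs
        wanted = set(self.pipelines)
        specs = [s for s in specs if s.pipeline_id in wanted]
        missing = wanted - {s.pipeline_id for s in specs}
        if missing:
            raise ConfigError(f"unknown pipeline ids: {sorted(missing)}")
        return specs


_MODEL_SPECS = {"main": ModelSpec.main_bias, "age": ModelSpec.with_age,
                "atrophy": ModelSpec.with_atrophy,
                "harmonization": ModelSpec.with_harmonization}


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(name, exc) from exc
            logger.info("stage=%s elapsed=%.1fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def _bias_results(table: pd.DataFrame, models: tuple[str, ...],
                  stratum: str) -> dict:
    results = {}
    for model_name in models:
        if model_name not in _MODEL_SPECS:
            continue
        spec = _MODEL_SPECS[model_name]()
        data = table
        if model_name == "harmonization":
            dual = table.groupby("subject_id")["harmonized"].nunique()
            data = table[table["subject_id"].isin(dual[dual == 2].index)]
            if data.empty:
                continue
        else:
            data = table[table["harmonized"] == True]  # noqa: E712
        fit = fit_gee(data, spec)
        results[f"wald_table_{model_name}_{stratum}"] = wald_type3(fit)
        mm_frames, delta_frames = [], []
        reference = {"rr": "WCB", "rr_type": "GAAIN", "t_type": "GAAIN",
                     "space": "MNI", "harmonized": "False"}
        for factor in ("tracer", "diagnosis") + spec.within_factors:
            mm = marginal_means(fit, factor)
            mm_frames.append(mm.to_frame())
            if factor in reference:
                delta_frames.append(pairwise_deltas(mm, reference[factor]))
        results[f"marginal_means_{model_name}_{stratum}"] = pd.concat(
            mm_frames, ignore_index=True)
        if delta_frames:
            results[f"deltas_{model_name}_{stratum}"] = pd.concat(
                delta_frames, ignore_index=True)
    return results


def _agreement_table(table: pd.DataFrame) -> pd.DataFrame:
    """Harmonized-vs-original agreement per RR for the GAAIN/MNI designs."""
    rows = []
    dual = table.groupby("subject_id")["harmonized"].nunique()
    dual_table = table[table["subject_id"].isin(dual[dual == 2].index)]
    for (rr, rr_type), sub in dual_table.groupby(["rr", "rr_type"]):
        sub = sub[(sub["t_type"] == rr_type)
                  & (sub["space"] == ("MNI" if rr_type == "GAAIN" else "native"))]
        wide = sub.pivot_table(index="subject_id", columns="harmonized",
                               values="cl")
        if wide.shape[1] < 2 or len(wide) < 3:
            continue
        ba = bland_altman(wide[False], wide[True])
        icc = icc_agreement(wide[False], wide[True])
        rows.append({"rr": rr, "pipeline_style": rr_type,
                     "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                     "ci_low": ba.ci_of_mean[0], "ci_high": ba.ci_of_mean[1],
                     "icc": icc.icc, "n": ba.n_pairs})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain and write all outputs; returns the manifest."""
    logging.basicConfig(level=cfg.log_level)
    rng_seed = cfg.seed
    specs = cfg.pipeline_specs()

    cohort = _stage("simulate")(generate_cohort)(cfg.cohort, seed=rng_seed)
    bank = _stage("calibrate")(calibrate)(
        cohort.template, specs, cohort.tracers, cfg.calibration,
        seed=rng_seed + 1)
    table = _stage("quantify")(quantify_cohort)(cohort, specs, bank)

    results: dict = {"calibration_bank": bank, "long_table": table,
                     "truth": cohort.truth}

    full_factorial = len(specs) == 32
    if full_factorial:
        negative, positive = _stage("stratify")(stratify_amyloid)(table)
        strata = {"negative": negative, "positive": positive}
        bias_models = tuple(m for m in cfg.models if m in _MODEL_SPECS)

        def bias_stage():
            out = {}
            for stratum, sub in strata.items():
                if sub["subject_id"].nunique() >= 8:
                    out.update(_bias_results(sub, bias_models, stratum))
            if {"WCB", "Pons"} <= set(table["rr"].unique()):
                for stratum, sub in strata.items():
                    if sub["subject_id"].nunique() >= 3:
                        out[f"age_correlations_{stratum}"] = \
                            factor_age_correlations(sub)
                out["atrophy_target"] = {
                    k: v for k, v in
                    vars(atrophy_target_analysis(positive)).items()}
            return out

        if bias_models:
            results.update(_stage("bias")(bias_stage)())

        if "precision" in cfg.models:
            def precision_stage():
                harm = {s: t[t["harmonized"] == True]  # noqa: E712
                        for s, t in strata.items()}
                res = {s: variance_decomposition(t, s)
                       for s, t in harm.items() if t["subject_id"].nunique() >= 2}
                out = {}
                if set(res) == {"negative", "positive"}:
                    rows = [{
                        "stratum": s, "n": r.n_subjects,
                        "within_sd": r.within_sd, "between_sd": r.between_sd,
                        "within_ci": r.within_ci_halfwidth,
                        "between_ci": r.between_ci_halfwidth,
                        "mean_cl": r.stratum_mean_cl,
                    } for s, r in res.items()]
                    out["precision"] = pd.DataFrame(rows)
                    out["ci_at_cutoffs"] = ci_profile(res["negative"],
                                                      res["positive"])
                out["agreement"] = _agreement_table(table)
                return out
            results.update(_stage("precision")(precision_stage)())

    written = _stage("export")(cio.export_report)(results, cfg.out_dir)

    n_dual = int((table.groupby("subject_id")["harmonized"].nunique() == 2).sum())
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_pipelines": len(specs),
        "n_subjects": len(cohort.subjects),
        "n_rows": int(len(table)),
        "n_dual_image_subjects": n_dual,
        "rows_per_dual_subject": 2 * len(specs),
        "outputs": sorted(p.name for p in written),
        "table_sha256": hashlib.sha256(
            table.to_csv(index=False).encode()).hexdigest(),
    }
    (Path(cfg.out_dir) / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
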