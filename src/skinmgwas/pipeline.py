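"""End-to-end orchestration with content-addressed stage caching.

``run_pipeline`` executes simulate -> qc -> features -> assoc -> meta ->
finemap -> mr on a synthetic study described by a config mapping.  Each
stage records digests of its inputs and outputs in a JSON manifest; a
rerun skips stages whose input digests are unchanged, and corrupting one
input reruns only the downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from skinmgwas import io as sio
from skinmgwas.assoc import (
    FeatureSkipped,
    beta_diversity_scan,
    univariate_feature_scan,
)
from skinmgwas.features import (
    bray_curtis,
    build_feature_set,
    prefixed_feature_tables,
    rarefy,
)
from skinmgwas.finemap import finemap_locus
from skinmgwas.meta import ThresholdConfig, meta_analyze_site_tables
from skinmgwas.mr import fdr_correct, results_table, run_mr
from skinmgwas.qc import genetic_pcs, variant_filters
from skinmgwas.sim import MICROENV_SITES, SimulationConfig, simulate_mr_summary, simulate_study

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "features", "assoc", "meta", "finemap", "mr"]

DEFAULT_CONFIG = {
    "seed": 0,
    "simulation": {},
    "rarefaction_depth": 5000,
    "feature_filters": {"median_min": 50, "prevalence_min": 100, "rho_cut": 0.985},
    "qc": {"maf_min": 0.05, "miss_max": 0.05, "hwe_alpha": 1e-5, "n_pcs": 10},
    "assoc": {"min_samples": 50},
    "thresholds": {"genome_wide": 5e-8, "nominal": 0.05, "n_features": 80},
    "mr": {"causal_beta": 0.3, "n_instruments": 20, "pleiotropy_sd": 0.0},
}


class ConfigError(ValueError):
    """Pipeline config does not validate against the schema."""


def validate_config(config: dict) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if key not in DEFAULT_CONFIG:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(DEFAULT_CONFIG[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            merged[key].update(val)
        else:
            merged[key] = val
    if merged["rarefaction_depth"] <= 0:
        raise ConfigError("rarefaction_depth must be positive")
    return merged


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _digest_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class RunManifest:
    """Per-stage input/output digests, seeds and wall times."""

    def __init__(self, out_dir: Path, config: dict):
        self.path = out_dir / "manifest.json"
        self.data = {
            "config_hash": _digest_obj(config),
            "seed": config["seed"],
            "stages": {},
        }
        self.previous = {}
        if self.path.exists():
            try:
                self.previous = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                self.previous = {}

    def stage_cached(self, stage: str, input_digests: dict) -> bool:
        prev = self.previous.get("stages", {}).get(stage)
        if prev is None or self.previous.get("config_hash") != self.data["config_hash"]:
            return False
        if prev.get("inputs") != input_digests:
            return False
        return all(Path(p).exists() for p in prev.get("outputs", {}))

    def record(self, stage: str, inputs: dict, outputs: list[Path],
               elapsed: float, cached: bool) -> None:
        self.data["stages"][stage] = {
            "inputs": inputs,
            "outputs": {str(p): _digest(Path(p)) for p in outputs},
            "seconds": round(elapsed, 3),
            "cached": cached,
        }

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2))


def run_pipeline(config: dict, out_dir: Path | str) -> RunManifest:
    """Run every stage on a synthetic study; returns the manifest."""
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out, config)
    seed = int(config["seed"])
    ctx: dict = {}

    for stage in STAGES:
        fn = globals()[f"_stage_{stage}"]
        inputs = fn(None, config, out, seed, probe_inputs=True, ctx=ctx)
        cached = manifest.stage_cached(stage, inputs)
        t0 = time.time()
        outputs = fn(cached, config, out, seed, probe_inputs=False, ctx=ctx)
        manifest.record(stage, inputs, outputs, time.time() - t0, cached)
        logger.info("stage %s %s (%.1fs)", stage,
                    "cached" if cached else "computed", time.time() - t0)
    manifest.save()
    return manifest


# --- stages ----------------------------------------------------------------
# Each stage function is called twice: once with probe_inputs=True to list
# input digests (for cache checks), once to produce outputs.  Stage outputs
# always live under fixed names so downstream digests are well-defined.
# Cheap stages rebuild their in-memory context even when cached (they are
# deterministic, so files are not rewritten); the expensive association and
# meta stages reload their outputs from disk instead.

def _stage_simulate(cached, config, out, seed, probe_inputs, ctx):
    if probe_inputs:
        return {"config": _digest_obj({k: config[k] for k in ("seed", "simulation")})}
    sim_cfg = SimulationConfig(**{**config["simulation"], "seed": seed})
    ctx["sim_cfg"] = sim_cfg
    genos, covs, tables = simulate_study(sim_cfg)
    ctx.update(genotypes=genos, covariates=covs, tables=tables)
    outputs = []
    for cohort, g in genos.items():
        if not cached:
            sio.write_dosage_tsv(g, out / f"geno_{cohort}.x")
            sio.write_covariates(covs[cohort], out / f"covariates_{cohort}.tsv")
        outputs += [out / f"geno_{cohort}.dosage.tsv", out / f"geno_{cohort}.variants.tsv",
                    out / f"covariates_{cohort}.tsv"]
    for key, table in tables.items():
        if not cached:
            sio.write_abundance(table, out / f"abund_{key}.x")
        outputs.append(out / f"abund_{key}.counts.tsv")
    return outputs


def _stage_qc(cached, config, out, seed, probe_inputs, ctx):
    deps = sorted(p for p in out.glob("geno_*.dosage.tsv")
                  if not p.name.startswith("geno_qc_"))
    if probe_inputs:
        return {str(p): _digest(p) for p in deps if p.exists()} | {
            "params": _digest_obj(config["qc"])}
    qc_cfg = config["qc"]
    outputs = []
    ctx["qc_genotypes"] = {}
    ctx["pcs"] = {}
    for cohort, g in ctx["genotypes"].items():
        filtered, log = variant_filters(
            g, maf_min=qc_cfg["maf_min"], miss_max=qc_cfg["miss_max"],
            hwe_alpha=qc_cfg["hwe_alpha"])
        pcs = genetic_pcs(filtered, k=min(qc_cfg["n_pcs"], filtered.n_variants,
                                          filtered.n_samples))
        ctx["qc_genotypes"][cohort] = filtered
        ctx["pcs"][cohort] = pcs
        if not cached:
            sio.write_dosage_tsv(filtered, out / f"geno_qc_{cohort}.x")
            sio.write_matrix(pcs.scores, out / f"pcs_{cohort}.tsv", "pcs")
            sio.write_table(log.reset_index(), out / f"qc_log_{cohort}.tsv", "qc_log")
        outputs += [out / f"geno_qc_{cohort}.dosage.tsv", out / f"pcs_{cohort}.tsv",
                    out / f"qc_log_{cohort}.tsv"]
    return outputs


def _stage_features(cached, config, out, seed, probe_inputs, ctx):
    deps = sorted(out.glob("abund_*.counts.tsv"))
    if probe_inputs:
        return {str(p): _digest(p) for p in deps if p.exists()} | {
            "params": _digest_obj({"filters": config["feature_filters"],
                                   "depth": config["rarefaction_depth"]})}
    ff = config["feature_filters"]
    outputs = []
    ctx["feature_sets"] = {}
    ctx["rarefied"] = {}
    for microenv, site_keys in MICROENV_SITES.items():
        site_tables = {k: ctx["tables"][k] for k in site_keys if k in ctx["tables"]}
        if len(site_tables) != 2:
            continue
        fs = build_feature_set(site_tables, microenv,
                               median_min=ff["median_min"],
                               prevalence_min=ff["prevalence_min"],
                               rho_cut=ff["rho_cut"])
        ctx["feature_sets"][microenv] = fs
        if not cached:
            rows = [{"feature": rep, "microenv": microenv,
                     "members": ";".join(fs.clusters[rep])} for rep in fs.features]
            sio.write_table(pd.DataFrame(rows, columns=["feature", "microenv", "members"]),
                            out / f"features_{microenv}.tsv", "feature_set")
        outputs.append(out / f"features_{microenv}.tsv")
    for key, table in ctx["tables"].items():
        ctx["rarefied"][key] = rarefy(table, config["rarefaction_depth"], seed=seed)
    return outputs


def _stage_assoc(cached, config, out, seed, probe_inputs, ctx):
    deps = sorted(out.glob("features_*.tsv")) + sorted(out.glob("geno_qc_*.dosage.tsv"))
    if probe_inputs:
        return {str(p): _digest(p) for p in deps if p.exists()} | {
            "params": _digest_obj(config["assoc"])}
    min_samples = config["assoc"]["min_samples"]
    outputs = []
    ctx["assoc"] = {}
    if cached:
        for path in sorted(out.glob("assoc_*.tsv")):
            site_key = path.stem.removeprefix("assoc_")
            ctx["assoc"][site_key] = sio.read_table(path, "assoc")
            outputs.append(path)
        return outputs
    for microenv, site_keys in MICROENV_SITES.items():
        fs = ctx["feature_sets"].get(microenv)
        if fs is None:
            continue
        for site_key in site_keys:
            table = ctx["tables"][site_key]
            cohort = site_key.split("@")[1]
            g = ctx["qc_genotypes"][cohort]
            pcs = ctx["pcs"][cohort]
            covs = pd.concat([ctx["covariates"][cohort], pcs.scores], axis=1)
            prefixed = prefixed_feature_tables(table)
            rare = ctx["rarefied"][site_key]
            rare_prefixed = prefixed_feature_tables(rare)
            frames = []
            for feature in fs.features:
                if feature not in prefixed.columns:
                    continue
                try:
                    frames.append(univariate_feature_scan(
                        prefixed[feature],
                        rare_prefixed[feature] if feature in rare_prefixed.columns
                        else prefixed[feature] * np.nan,
                        covs, table.sample_totals, g.dosages, g.variants,
                        feature=feature, site=site_key,
                        seed=seed + zlib.crc32(f"{feature}@{site_key}".encode()) % 100_000,
                        min_samples=min_samples))
                except FeatureSkipped as exc:
                    logger.info("assoc: skipped %s at %s (%s)", feature, site_key, exc)
            # beta diversity on the rarefied table
            try:
                d = bray_curtis(rare)
                shared = [s for s in d.ids if s in covs.index]
                if len(shared) >= min_samples:
                    dsub = rare.counts.loc[shared]
                    from skinmgwas.datatypes import AbundanceTable
                    d2 = bray_curtis(AbundanceTable(counts=dsub))
                    frames.append(beta_diversity_scan(
                        d2, covs.loc[shared], g.dosages.loc[shared], g.variants,
                        site=site_key, seed=seed))
            except ValueError as exc:
                logger.warning("assoc: beta diversity failed at %s (%s)", site_key, exc)
            if frames:
                stats_frame = pd.concat(frames, ignore_index=True)
                ctx["assoc"][site_key] = stats_frame
                sio.write_table(stats_frame, out / f"assoc_{site_key}.tsv", "assoc")
                outputs.append(out / f"assoc_{site_key}.tsv")
    return outputs


def _stage_meta(cached, config, out, seed, probe_inputs, ctx):
    deps = sorted(out.glob("assoc_*.tsv"))
    if probe_inputs:
        return {str(p): _digest(p) for p in deps if p.exists()} | {
            "params": _digest_obj(config["thresholds"])}
    th = ThresholdConfig(**config["thresholds"])
    outputs = []
    ctx["meta"] = {}
    if cached:
        for path in sorted(out.glob("meta_*.tsv")):
            ctx["meta"][path.stem.removeprefix("meta_")] = sio.read_table(path, "meta")
            outputs.append(path)
        return outputs
    for microenv, site_keys in MICROENV_SITES.items():
        frames = {k: ctx["assoc"][k] for k in site_keys if k in ctx.get("assoc", {})}
        if len(frames) != 2:
            continue
        meta_frame = meta_analyze_site_tables(frames, microenv, th)
        ctx["meta"][microenv] = meta_frame
        sio.write_table(meta_frame, out / f"meta_{microenv}.tsv", "meta")
        outputs.append(out / f"meta_{microenv}.tsv")
    return outputs


def _stage_finemap(cached, config, out, seed, probe_inputs, ctx):
    deps = sorted(out.glob("meta_*.tsv"))
    if probe_inputs:
        return {str(p): _digest(p) for p in deps if p.exists()}
    if cached:
        ctx["finemap"] = sio.read_table(out / "finemap.tsv", "finemap")
        return [out / "finemap.tsv"]
    outputs = []
    rows = []
    for microenv, meta_frame in ctx.get("meta", {}).items():
        hits = meta_frame[meta_frame["VERDICT"] != "not_significant"]
        for feature in hits["FEATURE"].unique():
            sub = meta_frame[meta_frame["FEATURE"] == feature].rename(
                columns={"P_META": "P"})
            cohort = MICROENV_SITES[microenv][0].split("@")[1]
            g = ctx["qc_genotypes"][cohort]
            stat_type = sub["STAT_TYPE"].iloc[0]
            fl = finemap_locus(sub[["SNP", "POS", "BETA", "SE", "P"]], g.dosages,
                               stat_type=stat_type)
            fl.insert(0, "FEATURE", feature)
            fl.insert(1, "MICROENV", microenv)
            rows.append(fl.reset_index(names="SNP"))
    frame = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["FEATURE", "MICROENV", "SNP"]))
    ctx["finemap"] = frame
    sio.write_table(frame, out / "finemap.tsv", "finemap")
    outputs.append(out / "finemap.tsv")
    return outputs


def _stage_mr(cached, config, out, seed, probe_inputs, ctx):
    if probe_inputs:
        return {"params": _digest_obj(config["mr"]),
                "seed": seed}
    if cached:
        return [out / "mr_exposure.tsv", out / "mr_outcome.tsv", out / "mr_results.tsv"]
    mr_cfg = config["mr"]
    sim_cfg = ctx.get("sim_cfg") or SimulationConfig(seed=seed)
    exposure, outcome = simulate_mr_summary(
        sim_cfg, causal_beta=mr_cfg["causal_beta"],
        n_instruments=mr_cfg["n_instruments"],
        pleiotropy_sd=mr_cfg["pleiotropy_sd"])
    sio.write_summary_stats(exposure, out / "mr_exposure.tsv")
    sio.write_summary_stats(outcome, out / "mr_outcome.tsv")
    res = run_mr(exposure, outcome, "synthetic_exposure", "synthetic_outcome",
                 seed=seed)
    results = fdr_correct([res]) if res is not None else []
    frame = results_table(results)
    sio.write_table(frame, out / "mr_results.tsv", "mr")
    return [out / "mr_exposure.tsv", out / "mr_outcome.tsv", out / "mr_results.tsv"]
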