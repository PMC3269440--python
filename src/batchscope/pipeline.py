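"""End-to-end pipeline: simulate -> preprocess -> decompose -> correct ->
re-decompose -> calibrator evaluation -> probe properties -> differential
expression, driven by a validated YAML/dict configuration.

Every stage logs its inputs and parameters, writes its artifacts into the run
directory, and contributes to a machine-readable ``report.json``.  The report
is deterministic given the seed (no timestamps inside it), so identical
configurations produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import io as bio
from .calibrators import batch_shifts, calibrator_fidelity, compare_calibrators
from .correct import combat_sequential, mean_center
from .datamodel import DataError, ExpressionMatrix
from .diffexp import de_test, list_concordance
from .preprocess import detection_filter, quantile_normalize
from .probeprops import gc_sd_enrichment, position_sd_association
from .simulate import (
    DesignSpec,
    GCModel,
    GroupSpec,
    replicate_control_design,
    simulate_experiment,
    tumour_duplicate_design,
)
from .variance import NestedModelSpec, decompose

log = logging.getLogger("batchscope")

# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, Any] = {
    "seed": int,
    "design": {
        "kind": str,  # replicate_control | tumour_duplicate
        "n_probes": int,
        "kappa": float,
        "level_sd": dict,
        "residual_sd": float,
        "gc_multiplier": float,
        "gc_cutoff": float,
        "gc_levels": list,
    },
    "preprocess": {
        "detection_filter": bool,
        "conf_threshold": float,
        "max_fail_fraction": float,
        "quantile_normalize": bool,
    },
    "variance": {
        "random_levels": list,
        "fixed_factor": (str, type(None)),
        "estimator": str,
    },
    "correct": {
        "method": str,  # combat | mean-center
        "batch_levels": list,
        "covariates": list,
    },
    "calibrators": {"batch_level": str},
    "probeprops": {"level": str, "gc_cut": float},
    "diffexp": {"design": str, "fc_min": float, "p_max": float},
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "design": {"kind": "replicate_control", "n_probes": 500},
    "preprocess": {
        "detection_filter": True,
        "conf_threshold": 0.95,
        "max_fail_fraction": 0.20,
        "quantile_normalize": True,
    },
    "variance": {
        "random_levels": ["experiment", "run", "chip"],
        "fixed_factor": None,
        "estimator": "reml",
    },
    "correct": {"method": "combat", "batch_levels": ["experiment", "run"],
                "covariates": []},
    "calibrators": {"batch_level": "run"},
    "probeprops": {"level": "run", "gc_cut": 0.55},
    "diffexp": {"design": "two_group", "fc_min": 1.5, "p_max": 0.01},
}


class ConfigError(DataError):
    """Configuration violates the published schema."""


def validate_config(cfg: Mapping[str, Any]) -> dict[str, Any]:
    """Merge a user config over the defaults, rejecting unknown keys."""

    def check(node: Mapping, schema: Mapping, path: str) -> None:
        for key, val in node.items():
            if key not in schema:
                raise ConfigError(f"unknown configuration key: {path}{key}")
            expected = schema[key]
            if isinstance(expected, dict):
                if not isinstance(val, Mapping):
                    raise ConfigError(f"{path}{key} must be a mapping")
                check(val, expected, f"{path}{key}.")
            elif not isinstance(val, expected if isinstance(expected, tuple)
                                 else (expected,)):
                if expected is float and isinstance(val, int):
                    continue
                raise ConfigError(
                    f"{path}{key} has type {type(val).__name__}, "
                    f"expected {expected}"
                )

    check(cfg, _SCHEMA, "")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, val in cfg.items():
        if isinstance(val, Mapping):
            merged.setdefault(section, {}).update(val)
        else:
            merged[section] = val
    if "seed" not in cfg and cfg.get("seed") is None and "seed" not in merged:
        raise ConfigError("a seed is mandatory")
    return merged


def load_config(path: str | os.PathLike) -> dict[str, Any]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _design_from_config(cfg: Mapping[str, Any], seed: int) -> DesignSpec:
    d = cfg["design"]
    kind = d.get("kind", "replicate_control")
    gc = GCModel(
        multiplier=float(d.get("gc_multiplier", 1.0)),
        cutoff=float(d.get("gc_cutoff", 0.55)),
        levels=tuple(d["gc_levels"]) if d.get("gc_levels") else None,
    )
    if kind == "replicate_control":
        return replicate_control_design(
            n_probes=int(d.get("n_probes", 500)),
            level_sd=d.get("level_sd"),
            residual_sd=float(d.get("residual_sd", 0.20)),
            seed=seed,
            gc_model=gc,
            expression_coupling=float(d.get("kappa", 0.0)),
        )
    if kind == "tumour_duplicate":
        return tumour_duplicate_design(
            n_probes=int(d.get("n_probes", 2000)),
            kappa=float(d.get("kappa", 0.5)),
            seed=seed,
            level_sd=d.get("level_sd"),
            residual_sd=float(d.get("residual_sd", 0.20)),
            gc_model=gc,
        )
    raise ConfigError(f"unknown design kind {kind!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(
    config: Mapping[str, Any] | str | os.PathLike,
    out_dir: str | os.PathLike,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run every stage, writing artifacts and a deterministic report."""
    cfg = (
        load_config(config)
        if isinstance(config, (str, os.PathLike))
        else validate_config(config)
    )
    if seed is not None:
        cfg["seed"] = int(seed)
    run_seed = int(cfg["seed"])

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    report: dict[str, Any] = {"config": cfg, "stages": {}}
    digests: dict[str, str] = {}

    def fail(stage: str, exc: Exception) -> None:
        log.error("stage %s failed: %s", stage, exc)
        raise DataError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- simulate ------------------------------------------------------
    stage = "simulate"
    try:
        spec = _design_from_config(cfg, _stage_seed(run_seed, 0))
        m, sheet, probes, truth = simulate_experiment(spec)
        bio.write_expression(m, out / "expression.tsv", out / "detection.tsv")
        bio.write_sample_sheet(sheet, out / "samples.tsv")
        bio.write_probe_sheet(probes, out / "probes.tsv")
        bio.write_probe_fasta(probes, out / "probes.fasta")
        for f in ("expression.tsv", "detection.tsv", "samples.tsv", "probes.tsv"):
            digests[f] = _sha256(out / f)
        report["stages"][stage] = {
            "n_probes": m.shape[0],
            "n_samples": m.shape[1],
            "design_kind": cfg["design"].get("kind", "replicate_control"),
        }
        log.info("simulated %d probes x %d samples", *m.shape)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- preprocess ----------------------------------------------------
    stage = "preprocess"
    try:
        pp = cfg["preprocess"]
        removed: list[str] = []
        work = m
        if pp.get("detection_filter", True):
            work, removed = detection_filter(
                work,
                conf_threshold=float(pp.get("conf_threshold", 0.95)),
                max_fail_fraction=float(pp.get("max_fail_fraction", 0.20)),
            )
        raw = work
        if pp.get("quantile_normalize", True):
            work = quantile_normalize(work)
        bio.write_expression(work, out / "normalized.tsv")
        digests["normalized.tsv"] = _sha256(out / "normalized.tsv")
        report["stages"][stage] = {
            "probes_removed": len(removed),
            "probes_kept": work.shape[0],
        }
        log.info("filter removed %d probes; %d kept", len(removed), work.shape[0])
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- variance decomposition (pre-correction) ------------------------
    stage = "decompose"
    try:
        vc = cfg["variance"]
        levels = [l for l in vc["random_levels"]
                  if sheet.frame[l].nunique() > 1]
        mspec = NestedModelSpec(
            random_levels=tuple(levels), fixed_factor=vc.get("fixed_factor")
        )
        dec_pre = decompose(work, sheet, mspec,
                            estimator=vc.get("estimator", "reml"))
        dec_pre.per_probe.to_csv(out / "variance_pre.tsv", sep="\t")
        report["stages"][stage] = {
            "percent_pre": {k: round(v, 4) for k, v in dec_pre.percent.items()},
            "mean_sd_pre": {k: round(v, 6) for k, v in dec_pre.mean_sd.items()},
            "pooled_sd_pre": {k: round(v, 6) for k, v in dec_pre.pooled_sd.items()},
        }
        log.info("pre-correction percent contributions: %s",
                 dec_pre.percent.to_dict())
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- correction ------------------------------------------------------
    stage = "correct"
    try:
        cc = cfg["correct"]
        covs = list(cc.get("covariates", []))
        if cc.get("method", "combat") == "combat":
            corrected = combat_sequential(work, sheet, cc["batch_levels"], covs)
        elif cc["method"] == "mean-center":
            corrected = work
            for lvl in cc["batch_levels"]:
                corrected = mean_center(corrected, sheet, lvl)
        else:
            raise ConfigError(f"unknown correction method {cc['method']!r}")
        bio.write_expression(corrected, out / "corrected.tsv")
        digests["corrected.tsv"] = _sha256(out / "corrected.tsv")
        rms = float(
            np.sqrt(
                ((corrected.values.to_numpy() - work.values.to_numpy()) ** 2).mean()
            )
        )
        dec_post = decompose(corrected, sheet, mspec,
                             estimator=vc.get("estimator", "reml"))
        dec_post.per_probe.to_csv(out / "variance_post.tsv", sep="\t")
        report["stages"][stage] = {
            "method": cc.get("method", "combat"),
            "batch_levels": list(cc["batch_levels"]),
            "rms_change": round(rms, 9),
            "percent_post": {k: round(v, 4) for k, v in dec_post.percent.items()},
            "mean_sd_post": {k: round(v, 6) for k, v in dec_post.mean_sd.items()},
            "pooled_sd_post": {k: round(v, 6)
                               for k, v in dec_post.pooled_sd.items()},
        }
        log.info("correction RMS change %.4g", rms)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- calibrators -----------------------------------------------------
    stage = "calibrate-eval"
    try:
        lvl = cfg["calibrators"]["batch_level"]
        shifts = batch_shifts(work, sheet, lvl)
        dup = [t for t in shifts if t.kind == "sample_duplicate"]
        gen = [t for t in shifts if t.kind == "generic_control"]
        pool = [t for t in shifts if t.kind == "pooled_control"]
        if dup and gen and pool:
            fid_gen, fid_pool = [], []
            for d in dup:
                gs = [t for t in gen if t.batch_pair == d.batch_pair]
                ps = [t for t in pool if t.batch_pair == d.batch_pair]
                if not gs or not ps:
                    continue
                rg = [calibrator_fidelity(g, d)[0.0] for g in gs]
                rp = [calibrator_fidelity(p, d)[0.0] for p in ps]
                rg = [r for r in rg if r is not None]
                rp = [r for r in rp if r is not None]
                if rg and rp:
                    fid_gen.append(float(np.mean(rg)))
                    fid_pool.append(float(np.mean(rp)))
            if len(fid_gen) >= 2:
                mean_diff, p = compare_calibrators(fid_pool, fid_gen)
                report["stages"][stage] = {
                    "n_duplicate_pairs": len(fid_gen),
                    "mean_fidelity_generic": round(float(np.mean(fid_gen)), 4),
                    "mean_fidelity_pooled": round(float(np.mean(fid_pool)), 4),
                    "pooled_minus_generic": round(mean_diff, 4),
                    "p_value": p,
                }
            else:
                report["stages"][stage] = {"skipped": "too few comparable pairs"}
        else:
            report["stages"][stage] = {
                "skipped": "design lacks duplicates or both calibrator types"
            }
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- probe properties -------------------------------------------------
    stage = "probe-props"
    try:
        ppc = cfg["probeprops"]
        lvl = ppc.get("level", "run")
        gc = probes.gc().loc[dec_pre.per_probe.index]
        if lvl in dec_pre.per_probe.columns:
            enr = gc_sd_enrichment(
                dec_pre.per_probe[lvl], gc, gc_cut=float(ppc.get("gc_cut", 0.55))
            )
            trend = position_sd_association(
                dec_pre.per_probe[lvl], probes, seed=_stage_seed(run_seed, 6)
            )
            report["stages"][stage] = {
                "level": lvl,
                "chi2": round(enr.statistic, 6),
                "p_value": enr.p_value,
                "sd_cut": round(enr.sd_cut, 6),
                "table": enr.table.to_numpy().tolist(),
                "position_rho": round(trend.rho, 6),
                "position_p": trend.p_value,
            }
        else:
            report["stages"][stage] = {"skipped": f"no SD estimates at {lvl}"}
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- differential expression ------------------------------------------
    stage = "de"
    try:
        de_cfg = cfg["diffexp"]
        groups = sheet.frame["group"].dropna().unique()
        if len(groups) == 2:
            de_pre = de_test(work, sheet, design=de_cfg.get("design", "two_group"),
                             fc_min=float(de_cfg.get("fc_min", 1.5)),
                             p_max=float(de_cfg.get("p_max", 0.01)))
            de_post = de_test(corrected, sheet,
                              design=de_cfg.get("design", "two_group"),
                              fc_min=float(de_cfg.get("fc_min", 1.5)),
                              p_max=float(de_cfg.get("p_max", 0.01)))
            conc = list_concordance(
                {"pre": de_pre.significant, "post": de_post.significant}
            )
            report["stages"][stage] = {
                "n_significant_pre": len(de_pre.significant),
                "n_significant_post": len(de_post.significant),
                "common": conc["common"],
            }
        else:
            report["stages"][stage] = {"skipped": "design has no two-group contrast"}
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    report["artifact_digests"] = digests
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    log.removeHandler(handler)
    handler.close()
    return report
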