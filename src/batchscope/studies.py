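"""End-to-end study recipes over synthetic experiments.

Each function runs one of the package's headline analyses at its canonical
study conditions and returns plain dictionaries of measured quantities, so
tests, scripts, and reports all recompute the same way.  Problem sizes are
documented per study in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .calibrators import batch_shifts, calibrator_fidelity, compare_calibrators
from .correct import combat
from .diffexp import de_test, list_concordance
from .preprocess import detection_filter, quantile_normalize
from .probeprops import gc_sd_enrichment
from .simulate import (
    DesignSpec,
    GCModel,
    GroupSpec,
    inject_location_scale,
    replicate_control_design,
    simulate_experiment,
    tumour_duplicate_design,
)
from .variance import (
    RESIDUAL,
    NestedModelSpec,
    decompose,
    fit_nested_mom,
    fit_nested_reml,
)

TRUE_LEVEL_SD = {"experiment": 0.30, "run": 0.15, "chip": 0.10}
TRUE_RESIDUAL_SD = 0.20


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# 1. variance-component recovery
# ---------------------------------------------------------------------------

def variance_recovery_study(seed: int = 0, n_probes: int = 1000) -> dict:
    """Recover level SDs on a balanced 3x2x2x2 replicate-control design
    (kappa = 0, no GC vulnerability), and quantify REML/EMS agreement."""
    spec = replicate_control_design(
        n_probes=n_probes,
        level_sd=TRUE_LEVEL_SD,
        residual_sd=TRUE_RESIDUAL_SD,
        seed=seed,
    )
    m, sheet, probes, truth = simulate_experiment(spec)
    mspec = NestedModelSpec(("experiment", "run", "chip"))
    dec = decompose(m, sheet, mspec, estimator="reml")

    truth_sd = dict(TRUE_LEVEL_SD, **{RESIDUAL: TRUE_RESIDUAL_SD})
    rel_err = {
        lvl: float(abs(dec.pooled_sd[lvl] - sd) / sd) for lvl, sd in truth_sd.items()
    }

    # REML vs expected-mean-squares oracle on interior solutions
    mom_fits = fit_nested_mom(m.values.to_numpy(), sheet, mspec)
    max_rel_diff = 0.0
    n_interior = 0
    for pid, fit in zip(m.probe_ids, mom_fits):
        raw = np.array([fit.variances_raw[l] for l in mspec.random_levels + (RESIDUAL,)])
        if (raw > 1e-4).all():
            n_interior += 1
            reml_sd = dec.per_probe.loc[pid, list(mspec.random_levels) + [RESIDUAL]]
            mom_sd = np.sqrt(raw)
            max_rel_diff = max(
                max_rel_diff,
                float(np.max(np.abs(reml_sd.to_numpy() - mom_sd) / mom_sd)),
            )
    return {
        "pooled_sd": {k: float(v) for k, v in dec.pooled_sd.items()},
        "mean_sd": {k: float(v) for k, v in dec.mean_sd.items()},
        "percent": {k: float(v) for k, v in dec.percent.items()},
        "rel_err": rel_err,
        "max_rel_err": max(rel_err.values()),
        "reml_mom_max_rel_diff": max_rel_diff,
        "n_interior": n_interior,
        "n_probes": n_probes,
    }


# ---------------------------------------------------------------------------
# 2. correction efficacy
# ---------------------------------------------------------------------------

def correction_efficacy_study(seed: int = 0, n_probes: int = 2000) -> dict:
    """Inject location/scale batch effects over four balanced batches and
    measure how much of the between-batch component the empirical-Bayes
    correction removes, and how well group fold-changes survive."""
    spec = DesignSpec(
        n_probes=n_probes,
        nesting=(("experiment", 1), ("run", 4), ("chip", 1), ("array_position", 10)),
        level_sd={"experiment": 0.0, "run": 0.0, "chip": 0.0},
        residual_sd=TRUE_RESIDUAL_SD,
        groups=(GroupSpec("a", 20), GroupSpec("b", 20, 0.25, 1.0)),
        seed=seed,
    )
    m, sheet, probes, truth = simulate_experiment(spec)
    injected, gamma, delta = inject_location_scale(
        m, truth, sheet, "run", add_sd=0.5, scale_log_sd=0.2, seed=_sub_seed(seed, 1)
    )
    mspec = NestedModelSpec(("run",), fixed_factor="group")
    dec_pre = decompose(injected, sheet, mspec, estimator="reml")
    corrected = combat(injected, sheet, "run", covariates=["group"])
    dec_post = decompose(corrected, sheet, mspec, estimator="reml")
    ratio = float(dec_post.pooled_sd["run"] / dec_pre.pooled_sd["run"])

    planted = truth.group_effects["b"]
    strong = planted.index[planted.abs() >= 0.5]
    lfc_pre = de_test(injected, sheet, p_max=1.0, fc_min=1.0).table["log2fc"]
    lfc_post = de_test(corrected, sheet, p_max=1.0, fc_min=1.0).table["log2fc"]
    fc_drift = float(
        (np.abs(lfc_post[strong] - lfc_pre[strong]) / np.abs(lfc_pre[strong])).mean()
    )
    fc_vs_truth = float(
        (np.abs(lfc_post[strong] - planted[strong]) / np.abs(planted[strong])).median()
    )
    return {
        "batch_sd_pre": float(dec_pre.pooled_sd["run"]),
        "batch_sd_post": float(dec_post.pooled_sd["run"]),
        "batch_sd_ratio": ratio,
        "fc_rel_drift": fc_drift,
        "fc_rel_err_vs_truth": fc_vs_truth,
        "n_strong_probes": int(len(strong)),
        "n_probes": n_probes,
    }


# ---------------------------------------------------------------------------
# 3. normalisation invariants
# ---------------------------------------------------------------------------

def normalization_invariance_study(seed: int = 0, n_probes: int = 1000) -> dict:
    """Quantile normalisation: exact multiset identity, idempotence, and the
    stability of the relative variance structure."""
    spec = replicate_control_design(
        n_probes=n_probes,
        level_sd=TRUE_LEVEL_SD,
        residual_sd=TRUE_RESIDUAL_SD,
        seed=seed,
    )
    m, sheet, probes, truth = simulate_experiment(spec)
    qn = quantile_normalize(m)
    cols = [np.sort(qn.values[c].to_numpy()) for c in qn.sample_ids]
    multiset_identical = all(np.array_equal(cols[0], c) for c in cols[1:])
    qn2 = quantile_normalize(qn)
    idem = float(np.abs(qn2.values.to_numpy() - qn.values.to_numpy()).max())

    mspec = NestedModelSpec(("experiment", "run", "chip"))
    pct_raw = decompose(m, sheet, mspec, estimator="reml").percent
    pct_qn = decompose(qn, sheet, mspec, estimator="reml").percent
    delta_pct = {k: float(abs(pct_qn[k] - pct_raw[k])) for k in pct_raw.index}
    return {
        "multiset_identical": bool(multiset_identical),
        "idempotence_max_abs": idem,
        "percent_raw": {k: float(v) for k, v in pct_raw.items()},
        "percent_qn": {k: float(v) for k, v in pct_qn.items()},
        "max_percent_shift": max(delta_pct.values()),
        "n_probes": n_probes,
    }


# ---------------------------------------------------------------------------
# 4. detection-filter boundary semantics
# ---------------------------------------------------------------------------

def detection_boundary_study() -> dict:
    """Constructed toy matrix exercising the strict filter boundaries."""
    from .datamodel import ExpressionMatrix

    n_samples = 10
    samples = [f"s{i}" for i in range(n_samples)]
    values = pd.DataFrame(
        np.zeros((3, n_samples)), index=["clean", "edge20", "fail30"], columns=samples
    )
    det = pd.DataFrame(1.0, index=values.index, columns=samples)
    det.loc["edge20", samples[:2]] = 0.95  # exactly 20% at the threshold
    det.loc["fail30", samples[:3]] = 0.95  # 30% > 20%
    m = ExpressionMatrix(values, det)
    kept, removed = detection_filter(m, conf_threshold=0.95, max_fail_fraction=0.20)
    return {
        "removed": removed,
        "kept": kept.probe_ids,
        "edge20_retained": "edge20" in kept.probe_ids,
        "fail30_removed": "fail30" in removed,
    }


# ---------------------------------------------------------------------------
# 5. GC-vulnerability detection
# ---------------------------------------------------------------------------

def gc_vulnerability_study(
    seed: int = 0,
    n_reps: int = 100,
    n_probes: int = 5000,
    multiplier: float = 2.0,
) -> dict:
    """Rejection rate of the GC/SD enrichment test when low-GC probes carry a
    doubled run-level SD (power), or no extra SD (null calibration)."""
    rejections_001 = 0
    rejections_005 = 0
    mspec = NestedModelSpec(("experiment", "run", "chip"))
    for r in range(n_reps):
        spec = replicate_control_design(
            n_probes=n_probes,
            level_sd=TRUE_LEVEL_SD,
            residual_sd=TRUE_RESIDUAL_SD,
            seed=_sub_seed(seed, 1000 + r),
            gc_model=GCModel(multiplier=multiplier, cutoff=0.55, levels=("run",)),
        )
        m, sheet, probes, truth = simulate_experiment(spec)
        dec = decompose(m, sheet, mspec, estimator="mom")
        enr = gc_sd_enrichment(dec.per_probe["run"], probes.gc(), gc_cut=0.55)
        rejections_001 += enr.p_value < 0.01
        rejections_005 += enr.p_value < 0.05
    return {
        "multiplier": multiplier,
        "rate_p001": rejections_001 / n_reps,
        "rate_p005": rejections_005 / n_reps,
        "n_reps": n_reps,
        "n_probes": n_probes,
    }


# ---------------------------------------------------------------------------
# 6. calibrator ordering
# ---------------------------------------------------------------------------

def _experiment_fidelities(
    m, sheet, batch_level: str = "run"
) -> tuple[list[float], list[float]]:
    shifts = batch_shifts(m, sheet, batch_level)
    dup = [t for t in shifts if t.kind == "sample_duplicate"]
    gen = [t for t in shifts if t.kind == "generic_control"]
    pool = [t for t in shifts if t.kind == "pooled_control"]
    fid_gen, fid_pool = [], []
    for d in dup:
        rg = [calibrator_fidelity(g, d)[0.0] for g in gen
              if g.batch_pair == d.batch_pair]
        rp = [calibrator_fidelity(p, d)[0.0] for p in pool
              if p.batch_pair == d.batch_pair]
        rg = [r for r in rg if r is not None]
        rp = [r for r in rp if r is not None]
        if rg and rp:
            fid_gen.append(float(np.mean(rg)))
            fid_pool.append(float(np.mean(rp)))
    return fid_gen, fid_pool


def calibrator_ordering_study(
    seed: int = 0,
    n_reps: int = 100,
    n_probes: int = 1000,
    kappa: float = 0.5,
) -> dict:
    """Across replicate experiments, how often do pooled calibrators track
    duplicate-sample batch shifts better than generic (UHRR-like) ones?"""
    wins = 0
    sig = 0
    diffs = []
    for r in range(n_reps):
        spec = tumour_duplicate_design(
            n_probes=n_probes, kappa=kappa, seed=_sub_seed(seed, 2000 + r)
        )
        m, sheet, probes, truth = simulate_experiment(spec)
        fid_gen, fid_pool = _experiment_fidelities(m, sheet, "run")
        mean_diff, p = compare_calibrators(fid_pool, fid_gen)
        diffs.append(mean_diff)
        wins += mean_diff > 0
        sig += (p < 0.05) and (mean_diff > 0)
    n_pos = sum(d > 0 for d in diffs)
    sign_p = float(stats.binomtest(n_pos, n_reps, 0.5).pvalue)
    return {
        "kappa": kappa,
        "frac_pooled_better": wins / n_reps,
        "frac_significant": sig / n_reps,
        "mean_improvement_pct": float(np.mean(diffs)),
        "sign_test_p": sign_p,
        "n_reps": n_reps,
        "n_probes": n_probes,
    }


# ---------------------------------------------------------------------------
# 7. DE concordance under correction
# ---------------------------------------------------------------------------

def concordance_study(
    seed: int = 0,
    n_reps: int = 20,
    n_probes: int = 1500,
    n_experiments: int = 2,
) -> dict:
    """Replicate experiments share planted biology but draw independent batch
    noise; compare cross-experiment DE-list intersections before vs after
    empirical-Bayes correction (batches blocked across groups)."""
    improved = 0
    pre_sizes, post_sizes = [], []
    for r in range(n_reps):
        bio_seed = _sub_seed(seed, 3000 + r)
        lists_pre, lists_post = [], []
        for e in range(n_experiments):
            spec = DesignSpec(
                n_probes=n_probes,
                nesting=(("experiment", 1), ("run", 2), ("chip", 2),
                         ("array_position", 4)),
                level_sd={"experiment": 0.0, "run": 0.5, "chip": 0.2},
                residual_sd=TRUE_RESIDUAL_SD,
                groups=(GroupSpec("a", 8), GroupSpec("b", 8, 0.15, 1.2)),
                seed=_sub_seed(bio_seed, 10 + e),
                biology_seed=bio_seed,
            )
            m, sheet, probes, truth = simulate_experiment(spec)
            qn = quantile_normalize(m)
            lists_pre.append(de_test(qn, sheet).significant)
            corrected = combat(qn, sheet, "run", covariates=["group"])
            lists_post.append(de_test(corrected, sheet).significant)
        pre = list_concordance(lists_pre)["common"]
        post = list_concordance(lists_post)["common"]
        pre_sizes.append(pre)
        post_sizes.append(post)
        improved += post > pre
    return {
        "frac_improved": improved / n_reps,
        "mean_common_pre": float(np.mean(pre_sizes)),
        "mean_common_post": float(np.mean(post_sizes)),
        "n_reps": n_reps,
        "n_probes": n_probes,
    }
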