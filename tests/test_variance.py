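"""Nested variance-component estimators: EMS oracle, REML, decomposition."""

import numpy as np
import pandas as pd
import pytest

from batchscope.datamodel import ExpressionMatrix
from batchscope.simulate import replicate_control_design, simulate_experiment
from batchscope.variance import (
    RESIDUAL,
    NestedModelSpec,
    UnbalancedDesignError,
    decompose,
    fit_nested_mom,
    fit_nested_reml,
)
from tests.conftest import make_sheet, nested_sheet


def two_chip_sheet():
    return make_sheet([
        {"sample_id": "a", "chip": "C1", "array_position": "A1"},
        {"sample_id": "b", "chip": "C1", "array_position": "A2"},
        {"sample_id": "c", "chip": "C2", "array_position": "A1"},
        {"sample_id": "d", "chip": "C2", "array_position": "A2"},
    ])


class TestMomOracle:
    def test_hand_computed_two_groups(self):
        # groups {0,0} and {2,2}: between MS 4, within MS 0 -> var (4-0)/2 = 2
        fit = fit_nested_mom(
            np.array([0.0, 0.0, 2.0, 2.0]), two_chip_sheet(),
            NestedModelSpec(("chip",)),
        )
        assert fit.variances_raw["chip"] == pytest.approx(2.0)
        assert fit.sds["chip"] == pytest.approx(np.sqrt(2.0))
        assert fit.sds[RESIDUAL] == 0.0

    def test_all_equal_gives_zero_components(self):
        fit = fit_nested_mom(
            np.full(4, 7.5), two_chip_sheet(), NestedModelSpec(("chip",))
        )
        assert all(v == 0.0 for v in fit.sds.values())

    def test_unbalanced_design_redirects_to_reml(self):
        sheet = make_sheet([
            {"sample_id": "a", "chip": "C1", "array_position": "A1"},
            {"sample_id": "b", "chip": "C1", "array_position": "A2"},
            {"sample_id": "c", "chip": "C2", "array_position": "A1"},
        ])
        with pytest.raises(UnbalancedDesignError, match="fit_nested_reml"):
            fit_nested_mom(np.zeros(3), sheet, NestedModelSpec(("chip",)))

    def test_simulated_components_recovered_within_5_percent(self):
        spec = replicate_control_design(n_probes=5000, seed=11)
        m, sheet, probes, truth = simulate_experiment(spec)
        dec = decompose(
            m, sheet, NestedModelSpec(("experiment", "run", "chip")),
            estimator="mom",
        )
        truth_sd = {"experiment": 0.30, "run": 0.15, "chip": 0.10, RESIDUAL: 0.20}
        for lvl, sd in truth_sd.items():
            assert dec.pooled_sd[lvl] == pytest.approx(sd, rel=0.05)


class TestReml:
    def test_agrees_with_mom_on_balanced_interior(self, rng):
        sheet = nested_sheet(3, 2, 2, 1)
        spec = NestedModelSpec(("experiment", "run"))
        checked = 0
        for _ in range(50):
            y = (
                np.repeat(rng.normal(0, 0.7, 3), 4)
                + np.repeat(rng.normal(0, 0.5, 6), 2)
                + rng.normal(0, 0.3, 12)
            )
            mom = fit_nested_mom(y, sheet, spec)
            if any(v <= 1e-4 for v in mom.variances_raw.values()):
                continue
            checked += 1
            reml = fit_nested_reml(y, sheet, spec)
            for lvl in ("experiment", "run", RESIDUAL):
                assert reml.sds[lvl] == pytest.approx(mom.sds[lvl], rel=1e-6)
        assert checked >= 10

    def test_null_component_converges_to_boundary(self, rng):
        # chip-level truth is zero: whenever the unconstrained EMS solution
        # goes negative, REML must land exactly on the boundary; overall the
        # boundary is hit for a substantial share of null probes and the
        # remaining positive estimates stay small
        sheet = nested_sheet(3, 2, 2, 2)
        spec = NestedModelSpec(("experiment", "run", "chip"))
        n_negative = n_boundary = 0
        positives = []
        for _ in range(100):
            y = (
                np.repeat(rng.normal(0, 0.4, 3), 8)
                + np.repeat(rng.normal(0, 0.3, 6), 4)
                + rng.normal(0, 0.3, 24)
            )
            mom = fit_nested_mom(y, sheet, spec)
            fit = fit_nested_reml(y, sheet, spec)
            if mom.variances_raw["chip"] < 0:
                n_negative += 1
                n_boundary += fit.variances_raw["chip"] <= 1e-6
            else:
                positives.append(fit.variances_raw["chip"])
        assert n_negative >= 20
        assert n_boundary >= 0.95 * n_negative
        assert np.median(positives) < 0.3**2

    def test_all_equal_converges_to_zero(self):
        fit = fit_nested_reml(
            np.full(4, 1.0), two_chip_sheet(), NestedModelSpec(("chip",))
        )
        assert fit.converged and all(v == 0.0 for v in fit.sds.values())

    def test_unbalanced_design_fits_densely(self, rng):
        sheet = make_sheet([
            {"sample_id": f"s{i}", "chip": f"C{i // 3 if i < 6 else 2}",
             "array_position": f"A{i}"}
            for i in range(8)
        ])
        chips = sheet.frame["chip"].astype("category").cat.codes.to_numpy()
        y = np.array([0.0, 0.0, 0.0, 3.0, 3.0, 3.0, 6.0, 6.0])[np.argsort(chips,
                                                                 kind="stable")]
        fit = fit_nested_reml(y, sheet, NestedModelSpec(("chip",)))
        assert fit.sds["chip"] > fit.sds[RESIDUAL]

    def test_single_unit_level_reported_absent(self, rng):
        sheet = nested_sheet(1, 2, 2, 2)
        y = rng.normal(0, 1, 8)
        fit = fit_nested_reml(
            y, sheet, NestedModelSpec(("experiment", "run", "chip"))
        )
        assert np.isnan(fit.sds["experiment"])
        assert np.isfinite(fit.sds["run"])


class TestDecompose:
    def test_percent_contributions_sum_to_100(self, rng):
        spec = replicate_control_design(n_probes=40, seed=2)
        m, sheet, probes, truth = simulate_experiment(spec)
        dec = decompose(m, sheet, NestedModelSpec(("experiment", "run", "chip")))
        assert dec.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_no_random_levels_reduces_to_residual_about_fixed_fit(self, rng):
        sheet = nested_sheet(1, 1, 1, 8, group_cycle=["a", "b"])
        y = rng.normal(0, 1, (5, 8))
        m = ExpressionMatrix(pd.DataFrame(
            y, index=[f"p{i}" for i in range(5)], columns=sheet.sample_ids
        ))
        dec = decompose(m, sheet, NestedModelSpec((), fixed_factor="group"))
        ga = [s for i, s in enumerate(sheet.sample_ids) if i % 2 == 0]
        gb = [s for i, s in enumerate(sheet.sample_ids) if i % 2 == 1]
        for i, pid in enumerate(m.probe_ids):
            resid = np.concatenate([
                y[i, ::2] - y[i, ::2].mean(), y[i, 1::2] - y[i, 1::2].mean()
            ])
            expected = np.sqrt((resid**2).sum() / (8 - 2))
            assert dec.per_probe.loc[pid, RESIDUAL] == pytest.approx(expected)

    def test_zero_variance_probe_flagged_not_fitted(self):
        sheet = nested_sheet(1, 1, 2, 2)
        vals = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]],
            index=["flat", "ok"], columns=sheet.sample_ids,
        )
        dec = decompose(ExpressionMatrix(vals), sheet, NestedModelSpec(("chip",)))
        assert not dec.per_probe.loc["flat", "converged"]
        assert dec.per_probe.loc["ok", "converged"]

    def test_estimator_consistency_improves_with_units(self):
        # mean absolute relative error of the experiment SD shrinks as the
        # number of experiments doubles
        errs = []
        for n_exp, seed in ((2, 21), (4, 22), (8, 23)):
            spec = replicate_control_design(
                n_probes=300,
                nesting=(("experiment", n_exp), ("run", 2), ("chip", 1),
                         ("array_position", 2)),
                level_sd={"experiment": 0.4, "run": 0.2, "chip": 0.0},
                seed=seed,
            )
            m, sheet, probes, truth = simulate_experiment(spec)
            dec = decompose(
                m, sheet, NestedModelSpec(("experiment", "run")), estimator="mom"
            )
            err = np.abs(dec.per_probe["experiment"] - 0.4) / 0.4
            errs.append(float(err.mean()))
        assert errs[0] > errs[1] > errs[2]

    def test_fixed_factor_estimates_group_means(self, rng):
        sheet = nested_sheet(2, 2, 2, 2, group_cycle=["a", "b"])
        base = rng.normal(0, 0.2, (3, 16))
        effect = np.array([0.0, 1.0, 2.0])
        groups = np.array([0, 1] * 8)
        y = base + effect[:, None] * (groups == 1)
        m = ExpressionMatrix(pd.DataFrame(
            y, index=["p0", "p1", "p2"], columns=sheet.sample_ids
        ))
        dec = decompose(
            m, sheet, NestedModelSpec(("experiment", "run"), fixed_factor="group")
        )
        est = dec.fixed_effects
        diffs = est["b"] - est["a"]
        assert np.allclose(diffs.to_numpy(), effect, atol=0.25)
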