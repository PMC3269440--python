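"""Empirical-Bayes batch correction: recovery, null behaviour, priors,
limiting cases, confounding guard, and an independent R reference check."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from batchscope.correct import (
    ConfoundingError,
    combat,
    combat_apply,
    combat_fit,
    invgamma_match,
    mean_center,
)
from batchscope.datamodel import DataError, ExpressionMatrix
from batchscope.simulate import (
    DesignSpec,
    GroupSpec,
    inject_location_scale,
    simulate_experiment,
)
from batchscope.variance import NestedModelSpec, decompose
from tests.conftest import make_sheet, nested_sheet


def two_batch_matrix(rng, n_probes=2000, n_per_batch=10, shift=0.0, scale=1.0):
    """Flat data, batch 2 shifted by +shift and scaled by *scale*."""
    sheet = make_sheet([
        {"sample_id": f"s{i}", "run": f"E1.R{i // n_per_batch}",
         "chip": f"E1.R{i // n_per_batch}.C0", "array_position": f"A{i}"}
        for i in range(2 * n_per_batch)
    ])
    base = rng.normal(0, 1.0, (n_probes, 2 * n_per_batch))
    base[:, n_per_batch:] = base[:, n_per_batch:] * scale + shift
    m = ExpressionMatrix(pd.DataFrame(
        base, index=[f"p{i}" for i in range(n_probes)],
        columns=sheet.sample_ids,
    ))
    return m, sheet


class TestFit:
    def test_injected_mean_shift_recovered_with_small_shrinkage(self, rng):
        c = 0.8
        m, sheet = two_batch_matrix(rng, shift=c)
        model = combat_fit(m, sheet, "run")
        # additive estimates on the original scale: gamma* x sigma
        got = (model.gamma_star.loc["E1.R1"] * model.sigma).mean()
        # batches are balanced, so each batch carries +/- c/2 about the mean
        assert got == pytest.approx(c / 2, rel=0.05)
        assert (model.gamma_star.loc["E1.R0"] * model.sigma).mean() == pytest.approx(
            -c / 2, rel=0.05
        )

    def test_null_batches_give_zero_gamma_unit_delta(self, rng):
        m, sheet = two_batch_matrix(rng, n_probes=5000)
        model = combat_fit(m, sheet, "run")
        assert abs(model.gamma_star.to_numpy().mean()) < 0.01
        # the pooled sigma divides by N while batch variances use ddof=1, so
        # the null expectation of delta^2 is ~N/(N-2), slightly above 1
        assert 0.95 < model.delta_star_sq.to_numpy().mean() < 1.15

    def test_weighted_gamma_hat_sums_to_zero(self, rng):
        m, sheet = two_batch_matrix(rng, n_probes=50, shift=0.5)
        model = combat_fit(m, sheet, "run")
        weighted = (model.batch_sizes.to_numpy()[:, None]
                    * model.gamma_hat.to_numpy()).sum(axis=0)
        assert np.abs(weighted).max() < 1e-8

    def test_single_sample_batch_rejected(self, rng):
        sheet = make_sheet([
            {"sample_id": "a", "run": "R1", "chip": "R1.C"},
            {"sample_id": "b", "run": "R1", "chip": "R1.C"},
            {"sample_id": "c", "run": "R2", "chip": "R2.C"},
        ])
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(0, 1, (5, 3)), index=[f"p{i}" for i in range(5)],
            columns=["a", "b", "c"],
        ))
        with pytest.raises(DataError, match="single sample"):
            combat_fit(m, sheet, "run")

    def test_confounded_covariate_rejected(self, rng):
        # group identical to batch: correction would erase the biology
        sheet = make_sheet([
            {"sample_id": f"s{i}", "run": f"R{i // 3}",
             "chip": f"R{i // 3}.C", "group": "pre" if i < 3 else "post",
             "array_position": f"A{i}"}
            for i in range(6)
        ])
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(0, 1, (10, 6)), index=[f"p{i}" for i in range(10)],
            columns=sheet.sample_ids,
        ))
        with pytest.raises(ConfoundingError):
            combat_fit(m, sheet, "run", covariates=["group"])

    def test_inverse_gamma_moment_matching_recovers_parameters(self, rng):
        lam_true, theta_true = 5.0, 4.0
        draws = stats.invgamma(a=lam_true, scale=theta_true).rvs(
            10_000, random_state=rng
        )
        lam, theta = invgamma_match(draws.mean(), draws.var(ddof=1))
        assert lam == pytest.approx(lam_true, rel=0.10)
        assert theta == pytest.approx(theta_true, rel=0.10)


class TestApply:
    def test_between_batch_component_collapses(self, rng):
        m, sheet = two_batch_matrix(rng, shift=0.8)
        spec = NestedModelSpec(("run",))
        pre = decompose(m, sheet, spec, estimator="mom").pooled_sd["run"]
        corrected = combat(m, sheet, "run")
        post = decompose(corrected, sheet, spec, estimator="mom").pooled_sd["run"]
        assert post < 0.05 * pre

    def test_order_preserved_and_shapes_equal(self, rng):
        m, sheet = two_batch_matrix(rng, n_probes=30, shift=0.3)
        out = combat(m, sheet, "run")
        assert out.probe_ids == m.probe_ids
        assert out.sample_ids == m.sample_ids

    def test_repeated_application_contracts(self, rng):
        # EB shrinkage leaves a residue (~half of each probe's sampling
        # deviation), so refitting is a contraction rather than an exact
        # fixed point: each pass changes far less than the one before
        m, sheet = two_batch_matrix(rng, shift=0.6, scale=1.3)
        once = combat(m, sheet, "run")
        twice = combat(once, sheet, "run")
        thrice = combat(twice, sheet, "run")

        def rms(a, b):
            return np.sqrt(((a.values.to_numpy() - b.values.to_numpy()) ** 2).mean())

        first, second, third = rms(once, m), rms(twice, once), rms(thrice, twice)
        assert second < 0.25 * first
        assert third < second

    def test_unknown_sample_rejected(self, rng):
        m, sheet = two_batch_matrix(rng, n_probes=20)
        model = combat_fit(m, sheet, "run")
        renamed = ExpressionMatrix(
            m.values.rename(columns={m.sample_ids[0]: "mystery"})
        )
        with pytest.raises(DataError, match="mystery"):
            combat_apply(renamed, model)

    def test_group_fold_change_preserved_when_blocked(self):
        spec = DesignSpec(
            n_probes=1000,
            nesting=(("experiment", 1), ("run", 3), ("chip", 1),
                     ("array_position", 8)),
            level_sd={"experiment": 0.0, "run": 0.4, "chip": 0.0},
            residual_sd=0.2,
            groups=(GroupSpec("a", 12), GroupSpec("b", 12, 0.3, 1.0)),
            seed=17,
        )
        m, sheet, probes, truth = simulate_experiment(spec)
        from batchscope.diffexp import de_test

        lfc_pre = de_test(m, sheet, p_max=1.0, fc_min=1.0).table["log2fc"]
        corrected = combat(m, sheet, "run", covariates=["group"])
        lfc_post = de_test(corrected, sheet, p_max=1.0, fc_min=1.0).table["log2fc"]
        planted = truth.group_effects["b"]
        strong = planted.index[planted.abs() >= 0.5]
        rel = (np.abs(lfc_post[strong] - lfc_pre[strong])
               / np.abs(lfc_pre[strong])).mean()
        assert rel < 0.10


class TestMeanCenter:
    def test_single_batch_is_identity(self, rng):
        sheet = nested_sheet(1, 1, 1, 4)
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(0, 1, (5, 4)), index=[f"p{i}" for i in range(5)],
            columns=sheet.sample_ids,
        ))
        out = mean_center(m, sheet, "run")
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_batches_recentred_at_grand_mean(self):
        sheet = nested_sheet(1, 2, 1, 2)
        vals = pd.DataFrame(
            [[1.0, 3.0, 3.0, 5.0]], index=["p1"], columns=sheet.sample_ids
        )
        out = mean_center(ExpressionMatrix(vals), sheet, "run")
        assert out.values.to_numpy().mean() == pytest.approx(3.0)
        assert out.values.iloc[0, :2].mean() == pytest.approx(3.0)
        assert out.values.iloc[0, 2:].mean() == pytest.approx(3.0)

    def test_combat_reduces_to_mean_center_without_scale_or_shrinkage(self, rng):
        m, sheet = two_batch_matrix(rng, n_probes=300, shift=0.5)
        model = combat_fit(m, sheet, "run")
        # freeze the limit tau^2 -> infinity (no shrinkage), delta* = 1
        model.gamma_star = model.gamma_hat
        model.delta_star_sq = model.delta_hat_sq * 0 + 1.0
        out = combat_apply(m, model)
        mc = mean_center(m, sheet, "run")
        assert np.abs(out.values.to_numpy() - mc.values.to_numpy()).max() < 1e-6


class TestAgainstReferenceImplementation:
    def test_matches_sva_combat_on_small_fixture(self, rng, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; reference comparison cannot run")
        m, sheet = two_batch_matrix(rng, n_probes=80, n_per_batch=6,
                                    shift=0.7, scale=1.4)
        ours = combat(m, sheet, "run")
        dat = tmp_path / "m.tsv"
        m.values.to_csv(dat, sep="\t")
        batch = ",".join(
            "1" if r == "E1.R0" else "2"
            for r in sheet.frame.set_index("sample_id").loc[
                m.sample_ids, "run"
            ]
        )
        script = tmp_path / "ref.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(sva))
            x <- as.matrix(read.delim("{dat}", row.names = 1))
            batch <- c({batch})
            out <- ComBat(dat = x, batch = batch, par.prior = TRUE)
            write.table(out, "{tmp_path / 'ref.tsv'}", sep = "\\t",
                        quote = FALSE, col.names = NA)
        """))
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True, text=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0)
        diff = np.abs(ours.values.to_numpy() - ref.to_numpy())
        assert diff.max() < 1e-3
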