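"""Generative-model contracts: determinism, moments, controls, duplicates."""

import numpy as np
import pandas as pd
import pytest

from batchscope.datamodel import DataError
from batchscope.simulate import (
    DesignSpec,
    GCModel,
    GroupSpec,
    inject_location_scale,
    make_pooled_control,
    replicate_control_design,
    simulate_experiment,
    tumour_duplicate_design,
)


class TestDegenerateAndDeterminism:
    def test_zero_noise_reproduces_baseline_in_every_column(self):
        spec = replicate_control_design(
            n_probes=30,
            level_sd={"experiment": 0.0, "run": 0.0, "chip": 0.0},
            residual_sd=0.0,
            seed=9,
        )
        m, sheet, probes, truth = simulate_experiment(spec)
        for sid in m.sample_ids:
            assert np.allclose(m.values[sid], truth.baselines)

    def test_same_seed_bit_identical(self):
        spec = tumour_duplicate_design(n_probes=50, seed=42)
        m1, s1, p1, t1 = simulate_experiment(spec)
        m2, s2, p2, t2 = simulate_experiment(spec)
        assert (m1.values.to_numpy() == m2.values.to_numpy()).all()
        assert (m1.detection.to_numpy() == m2.detection.to_numpy()).all()
        pd.testing.assert_frame_equal(s1.frame, s2.frame)

    def test_different_seed_differs(self):
        a = simulate_experiment(replicate_control_design(n_probes=20, seed=1))[0]
        b = simulate_experiment(replicate_control_design(n_probes=20, seed=2))[0]
        assert not np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_shared_biology_seed_shares_truth_not_noise(self):
        s1 = replicate_control_design(n_probes=20, seed=5, biology_seed=77)
        s2 = replicate_control_design(n_probes=20, seed=6, biology_seed=77)
        _, _, _, t1 = simulate_experiment(s1)
        m1, _, _, _ = simulate_experiment(s1)
        m2, _, _, t2 = simulate_experiment(s2)
        assert np.allclose(t1.baselines, t2.baselines)
        assert not np.allclose(m1.values.to_numpy(), m2.values.to_numpy())


class TestMoments:
    def test_realized_level_variances_match_level_sd(self):
        # >= 10,000 draws per level: relative error of the variance < 5%
        spec = replicate_control_design(n_probes=4000, seed=3)
        _, _, _, truth = simulate_experiment(spec)
        for lvl, sd in {"experiment": 0.30, "run": 0.15, "chip": 0.10}.items():
            draws = truth.random_effects[lvl].to_numpy().ravel()
            assert draws.size >= 10_000
            assert np.var(draws) == pytest.approx(sd**2, rel=0.05)

    def test_batch_shift_composition_consistent_with_truth(self):
        spec = replicate_control_design(n_probes=25, seed=8)
        m, sheet, probes, truth = simulate_experiment(spec)
        # kappa = 0 and v = 1: shift is exactly the sum of the unit draws
        row = sheet.frame.iloc[0]
        total = np.zeros(25)
        for lvl in ("experiment", "run", "chip"):
            total += truth.random_effects[lvl].loc[row[lvl]].to_numpy()
        assert np.allclose(truth.batch_shift[row["sample_id"]], total)


class TestControlsAndDuplicates:
    def test_make_pooled_control_examples(self):
        profiles = pd.DataFrame(
            {"s1": [2.0, 1.0], "s2": [4.0, 5.0]}, index=["p1", "p2"]
        )
        assert make_pooled_control(profiles, ["s1"]).tolist() == [2.0, 1.0]
        assert make_pooled_control(profiles, ["s1", "s2"]).tolist() == [3.0, 3.0]
        with pytest.raises(DataError, match="at least one member"):
            make_pooled_control(profiles, [])

    def test_seven_member_pool_matches_independent_mean(self, rng):
        profiles = pd.DataFrame(
            rng.normal(8, 1, (10, 7)),
            index=[f"p{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(7)],
        )
        pool = make_pooled_control(profiles, list(profiles.columns))
        assert np.allclose(pool.to_numpy(), profiles.to_numpy().mean(axis=1))

    def test_pooled_control_profile_is_group_mean(self):
        spec = tumour_duplicate_design(n_probes=40, seed=4)
        m, sheet, probes, truth = simulate_experiment(spec)
        df = sheet.frame
        pre_pool = df[(df["role"] == "pooled_control")
                      & (df["duplicate_id"] == "pool-pre")]["sample_id"].iloc[0]
        members = df[(df["role"] == "biological") & (df["group"] == "pre")][
            "sample_id"
        ].tolist()
        expected = truth.true_profiles[members].mean(axis=1)
        assert np.allclose(truth.true_profiles[pre_pool], expected)

    def test_duplicates_share_truth_but_span_two_runs(self):
        spec = tumour_duplicate_design(n_probes=30, seed=4)
        m, sheet, probes, truth = simulate_experiment(spec)
        dups = sheet.duplicate_groups()
        pair = dups["T01"]
        assert len(pair) == 2
        runs = sheet.frame.set_index("sample_id").loc[pair, "run"]
        assert runs.nunique() == 2
        assert np.allclose(
            truth.true_profiles[pair[0]], truth.true_profiles[pair[1]]
        )
        assert not np.allclose(m.values[pair[0]], m.values[pair[1]])

    def test_duplicate_plan_exceeding_capacity_errors(self):
        with pytest.raises(DataError):
            DesignSpec(
                n_probes=10,
                nesting=(("experiment", 1), ("run", 1), ("chip", 1),
                         ("array_position", 4)),
                groups=(GroupSpec("g", 0),),
                duplicate_plan=2,
                duplicate_level="run",
            ).n_samples_required and simulate_experiment(
                DesignSpec(
                    n_probes=10,
                    nesting=(("experiment", 1), ("run", 1), ("chip", 1),
                             ("array_position", 4)),
                    groups=(GroupSpec("g", 0),),
                    duplicate_plan=2,
                    duplicate_level="run",
                )
            )

    def test_sample_demand_must_match_arrays(self):
        spec = DesignSpec(
            n_probes=5,
            groups=(GroupSpec("g", 3),),  # 24 arrays available, 3 requested
        )
        with pytest.raises(DataError, match="arrays"):
            simulate_experiment(spec)


class TestVulnerabilityAndDetection:
    def test_gc_multiplier_inflates_low_gc_shift_variance(self):
        spec = replicate_control_design(
            n_probes=800, seed=6,
            gc_model=GCModel(multiplier=2.0, cutoff=0.55, levels=("run",)),
        )
        m, sheet, probes, truth = simulate_experiment(spec)
        gc = probes.gc().to_numpy()
        run_draw = truth.random_effects["run"]
        # realized run-level contribution for one sample
        sid = sheet.frame.iloc[0]
        contrib = run_draw.loc[sid["run"]].to_numpy()
        shift_var_low = np.var(truth.batch_shift.to_numpy()[gc < 0.55])
        shift_var_high = np.var(truth.batch_shift.to_numpy()[gc >= 0.55])
        assert shift_var_low > shift_var_high

    def test_detection_confidence_increases_with_expression(self):
        spec = replicate_control_design(n_probes=500, seed=7)
        m, sheet, probes, truth = simulate_experiment(spec)
        conf = m.detection.to_numpy().ravel()
        expr = truth.true_profiles.to_numpy().ravel()
        r = np.corrcoef(expr, conf)[0, 1]
        assert r > 0.5
        assert conf.min() >= 0.0 and conf.max() <= 1.0

    def test_kappa_weights_shift_by_expression_rank(self):
        spec = replicate_control_design(
            n_probes=400, seed=12, expression_coupling=1.0
        )
        m, sheet, probes, truth = simulate_experiment(spec)
        sid = sheet.sample_ids[0]
        # with kappa = 1 the lowest-expressed probe gets weight ~0, so its
        # shift must be ~0 regardless of the unit draws
        prof = truth.true_profiles[sid]
        lowest = prof.idxmin()
        assert abs(truth.batch_shift.loc[lowest, sid]) < 1e-9


class TestInjection:
    def test_injected_location_recovered_in_batch_means(self, rng):
        spec = DesignSpec(
            n_probes=200,
            nesting=(("experiment", 1), ("run", 2), ("chip", 1),
                     ("array_position", 10)),
            level_sd={"experiment": 0.0, "run": 0.0, "chip": 0.0},
            residual_sd=0.05,
            groups=(GroupSpec("g", 20),),
            seed=3,
        )
        m, sheet, probes, truth = simulate_experiment(spec)
        injected, gamma, delta = inject_location_scale(
            m, truth, sheet, "run", add_sd=0.6, scale_log_sd=0.0, seed=1
        )
        df = sheet.frame
        for run in df["run"].unique():
            cols = df[df["run"] == run]["sample_id"]
            observed = (
                injected.values[cols].mean(axis=1)
                - truth.true_profiles[cols].mean(axis=1)
            )
            assert np.corrcoef(observed, gamma.loc[run])[0, 1] > 0.99
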