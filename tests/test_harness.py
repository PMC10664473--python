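"""Monte-Carlo harness: metrics, seeding contracts, grid construction, reports."""

import numpy as np
import pandas as pd
import pytest

import slopesim as ss


class TestMcFunctions:
    def test_mc_se_reference_values(self):
        assert round(ss.mc_se(0.8, 5000), 1) == 0.6
        assert round(ss.mc_se(0.05, 5000), 1) == 0.3
        assert ss.mc_se(0.0, 123) == 0.0
        with pytest.raises(ValueError):
            ss.mc_se(1.2, 100)

    def test_mc_ci_bounds_reference_values(self):
        assert ss.mc_ci_bounds(0.05, 5000, 1) == (4.4, 5.6)
        assert ss.mc_ci_bounds(0.8, 5000, 1) == (78.8, 81.2)

    def test_mc_ci_collapses_at_large_n(self):
        lo, hi = ss.mc_ci_bounds(0.8, 10**12, 3)
        assert lo == pytest.approx(80.0, abs=1e-6)
        assert hi == pytest.approx(80.0, abs=1e-6)

    def test_se_pct_bias(self):
        assert ss.se_pct_bias(1.0, 1.0) == 0.0
        assert ss.se_pct_bias(1.1, 1.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            ss.se_pct_bias(1.0, 0.0)


class TestScenarioConfig:
    def test_sign_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same sign"):
            ss.ScenarioConfig(effect_kind="proportional_time", gamma=0.05, d=-0.05)

    def test_delayed_decline_only_steady(self):
        with pytest.raises(ValueError, match="steady"):
            ss.ScenarioConfig(shape="early", effect_kind="delayed_decline", delay=1.25)

    def test_yaml_round_trip(self, tmp_path):
        cfg = ss.ScenarioConfig(shape="late", effect_kind="proportional_control_change",
                                gamma=-0.05, trial_years=3.0, n_reps=10, base_seed=3)
        p = tmp_path / "scenario.yaml"
        cfg.to_yaml(p)
        assert ss.ScenarioConfig.from_yaml(p) == cfg


class TestBuildGrid:
    def test_factorial_layout(self):
        grid = ss.build_grid()
        # 2 sigma2_e x 4 shapes x 2 lengths x 3 effect families
        assert len(grid) == 48

    def test_large_residual_scenarios_use_larger_effect(self):
        grid = ss.build_grid()
        for cfg in grid:
            if cfg.sigma2_e == 2.0:
                assert cfg.d == -0.1
                if cfg.effect_kind in ("proportional_time", "proportional_control_change"):
                    assert cfg.gamma == -0.1
                if cfg.effect_kind == "delayed_decline":
                    assert cfg.delay == 2.5
            elif cfg.effect_kind == "delayed_decline":
                assert cfg.delay == 1.25

    def test_delayed_decline_only_for_steady(self):
        grid = ss.build_grid()
        assert all(c.shape == "steady" for c in grid if c.effect_kind == "delayed_decline")
        # non-steady shapes get the proportional-to-control-change effect instead
        assert any(c.effect_kind == "proportional_control_change" for c in grid)

    def test_fctfc_only_in_equivalence_scenario(self):
        grid = ss.build_grid()
        with_fctfc = [c for c in grid if "fctfc" in c.models]
        assert len(with_fctfc) == 1
        c = with_fctfc[0]
        assert (c.shape, c.effect_kind, c.trial_years, c.sigma2_e) == (
            "steady", "proportional_time", 5.0, 0.15
        )

    def test_unknown_residual_variance_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            ss.build_grid(sigma2_es=(0.3,))


@pytest.fixture(scope="module")
def small_scenario():
    return ss.ScenarioConfig(
        shape="steady", effect_kind="proportional_time", gamma=-0.05, d=-0.05,
        sigma2_e=0.15, trial_years=5.0, n_reps=30, base_seed=5, models=("rs", "ftfc"),
    )


@pytest.fixture(scope="module")
def small_run(small_scenario):
    return ss.run_scenario(small_scenario, keep_reps=True)


class TestRunReplicate:
    def test_deterministic(self, small_scenario):
        a = ss.run_replicate(small_scenario, 3)
        b = ss.run_replicate(small_scenario, 3)
        assert a.n_trial == b.n_trial
        assert a.obs_vc_hat == b.obs_vc_hat
        for m in small_scenario.models:
            assert a.estimates[m].effect_final == b.estimates[m].effect_final

    def test_sample_size_shared_across_effect_kinds(self, small_scenario):
        """Same observational studies (hence N) for every treatment-effect option."""
        null_cfg = ss.ScenarioConfig(
            shape="steady", effect_kind="none", gamma=0.0, d=-0.05,
            sigma2_e=0.15, trial_years=5.0, n_reps=30, base_seed=5, models=("rs",),
        )
        delayed_cfg = ss.ScenarioConfig(
            shape="steady", effect_kind="delayed_decline", delay=1.25, d=-0.05,
            sigma2_e=0.15, trial_years=5.0, n_reps=30, base_seed=5, models=("rs",),
        )
        for rep in range(4):
            n_ref = ss.run_replicate(small_scenario, rep).n_trial
            assert ss.run_replicate(null_cfg, rep).n_trial == n_ref
            assert ss.run_replicate(delayed_cfg, rep).n_trial == n_ref

    def test_n_trial_near_analytic_value(self, small_run, vc_default, sched5):
        """Observational-stage sizes concentrate near the true-parameter N."""
        _, reps = small_run
        n_true = ss.sample_size(ss.SampleSizeInputs(-0.05, 0.05, 0.8, vc_default, sched5))
        ns = np.array([r.n_trial for r in reps if r.usable])
        assert abs(ns.mean() - n_true) / n_true < 0.10
        assert np.all(ns % 2 == 0) and np.all(ns >= 2)


class TestRunScenario:
    def test_metric_identities(self, small_run):
        """Summary metrics equal their definitions applied to the replicates."""
        summary, reps = small_run
        complete = [r for r in reps if r.usable and all(r.converged.values())]
        assert summary.n_reps_used == len(complete)
        for m in ("rs", "ftfc"):
            eff = np.array([r.estimates[m].effect_final for r in complete])
            ses = np.array([r.estimates[m].se for r in complete])
            rej = np.mean([r.estimates[m].reject for r in complete])
            perf = summary.models[m]
            assert perf.reject_pct == pytest.approx(100 * rej)
            assert perf.reject_mc_se == pytest.approx(ss.mc_se(rej, len(complete)))
            assert perf.empirical_se == pytest.approx(eff.std(ddof=1))
            assert perf.mean_model_se == pytest.approx(np.sqrt(np.mean(ses**2)))
            assert perf.se_bias_pct == pytest.approx(
                ss.se_pct_bias(perf.mean_model_se, perf.empirical_se)
            )
            assert perf.mean_effect == pytest.approx(eff.mean())

    def test_boundary_filter_only_removes_replicates(self):
        """Filtering drops whole replicates; surviving estimates are unchanged."""
        base = dict(shape="early", effect_kind="proportional_control_change",
                    gamma=-0.05, d=-0.05, sigma2_e=0.15, trial_years=5.0,
                    n_reps=12, base_seed=2, models=("rs",))
        cfg_all = ss.ScenarioConfig(**base)
        cfg_filt = ss.ScenarioConfig(**base, boundary_filter="exclude_obs_boundary")
        _, reps_all = ss.run_scenario(cfg_all, keep_reps=True)
        _, reps_filt = ss.run_scenario(cfg_filt, keep_reps=True)
        by_rep = {r.rep_index: r for r in reps_all}
        for r in reps_filt:
            ref = by_rep[r.rep_index]
            assert r.n_trial == ref.n_trial
            if r.usable and ref.usable:
                assert r.estimates["rs"].effect_final == ref.estimates["rs"].effect_final

    def test_rejects_too_few_reps(self, small_scenario):
        with pytest.raises(ValueError):
            ss.run_scenario(small_scenario, n_reps=1)


class TestReport:
    def test_round_trip(self, small_run, tmp_path):
        summary, _ = small_run
        path = tmp_path / "report.csv"
        written = ss.write_report([summary], path)
        back = ss.read_report(path)
        assert list(back.columns) == list(written.columns)
        pd.testing.assert_frame_equal(back, written, check_dtype=False)

    def test_one_row_per_scenario_model(self, small_run, tmp_path):
        summary, _ = small_run
        table = ss.write_report([summary], tmp_path / "r.csv")
        assert len(table) == len(summary.config.models)
        assert set(table["model"]) == set(summary.config.models)

    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            ss.write_report([], tmp_path / "r.csv")
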