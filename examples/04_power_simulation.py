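"""A small Monte-Carlo run of the design-then-analyse loop.

Each replicate simulates a 1000-person observational study, estimates the
variance components, sizes a 5-year trial for 80% power against -0.05/yr,
simulates that trial with a proportional effect, and analyses it with the
random-slopes and free-trajectories models.  150 replicates keep this quick;
rejection rates carry a Monte-Carlo SE of ~3 percentage points at that size.
"""

import slopesim as ss

cfg = ss.ScenarioConfig(
    shape="steady", effect_kind="proportional_time", gamma=-0.05, d=-0.05,
    sigma2_e=0.15, trial_years=5.0, n_reps=150, base_seed=1,
    models=("rs", "ftfc"),
)
summary = ss.run_scenario(cfg)

print(f"scenario: {cfg.label()}, {summary.n_reps_used} usable replicates")
print(f"trial sizes: mean {summary.n_trial_mean:.0f}, "
      f"IQR [{summary.n_trial_q1:.0f}, {summary.n_trial_q3:.0f}]\n")
print(f"{'model':<6}{'power %':>9}{'MC SE':>7}{'mean effect':>13}"
      f"{'emp SE':>9}{'model SE':>10}{'SE bias %':>11}")
for m, perf in summary.models.items():
    print(f"{m:<6}{perf.reject_pct:9.1f}{perf.reject_mc_se:7.1f}"
          f"{perf.mean_effect:13.4f}{perf.empirical_se:9.4f}"
          f"{perf.mean_model_se:10.4f}{perf.se_bias_pct:11.1f}")

print("\nThe random-slopes power sits near the nominal 80% (the design is")
print("correctly specified here), while the free-trajectories model pays an")
print("efficiency price for estimating an unrestricted effect at every visit.")
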