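"""Two-stage sample-size calculation for a slope-difference trial.

Stage 1: estimate the random-slopes variance components from existing
longitudinal data (here: a simulated 1000-person observational study).
Stage 2: build the implied covariance of a hypothetical two-person trial,
compute the variance of the treatment-slope estimate, and convert it into a
total sample size for 80% power against a slope difference of -0.05/year.
"""

import slopesim as ss

vc_true = ss.DEFAULT_VC
sched5 = ss.VisitSchedule.annual(5)

# direct-parameter mode: known variance components
v2 = ss.var_gamma_two_person(vc_true, sched5)
n5 = ss.sample_size(ss.SampleSizeInputs(d=-0.05, alpha=0.05, power=0.8,
                                        vc=vc_true, schedule=sched5))
print("known components ({:.2f}, {:.2f}, {:.5f}, {:.2f}):".format(*vc_true.astuple()))
print(f"  V(gamma-hat) for a 2-person 5-year trial: {v2:.5f}")
print(f"  total N for a 5-year trial:  {n5}")

# pilot-data mode: fit the observational model first
pilot = ss.simulate_observational("steady", vc_true, sched5, 1000, seed=12)
obs_fit = ss.fit_random_slopes(pilot, design="observational")
vc_hat = obs_fit.vc_hat
n_hat = ss.sample_size(ss.SampleSizeInputs(d=-0.05, alpha=0.05, power=0.8,
                                           vc=vc_hat, schedule=sched5))
print(f"\npilot study of {pilot.n_subjects} people:")
print(f"  estimated components: ({vc_hat.sigma2_u0:.4f}, {vc_hat.sigma2_u1:.5f}, "
      f"{vc_hat.sigma_u01:.5f}, {vc_hat.sigma2_e:.4f})")
print(f"  total N for a 5-year trial:  {n_hat}")

# shorter trials need more people: the size-versus-length curve
print("\nsample size versus trial length (annual visits, true components):")
for length, n in ss.sample_size_curve(vc_true, -0.05, 0.05, 0.8, [2, 3, 4, 5, 6, 7]):
    print(f"  {length:3.0f} years  ->  N = {n:5d}")
print("Longer trials watch the slopes diverge for longer, so they need fewer")
print("participants; the curve is the design trade-off between N and duration.")
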