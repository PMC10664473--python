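"""Mean trajectories and treatment-effect shapes.

Evaluates the four control-group mean trajectories (all calibrated to run
from 6.00 at baseline to 7.00 at five years) and shows how the three
treatment-effect shapes modify the treated-group mean.  The final column is
the treated-minus-control difference at five years, which every effect shape
is calibrated to hold at -0.25.
"""

import numpy as np

import slopesim as ss

times = np.arange(6.0)

print("Control-group mean trajectories, 6 + 0.2 f(t):")
print("  t      " + "  ".join(f"{t:6.0f}" for t in times))
for shape in ss.SHAPE_NAMES:
    mu = ss.control_mean(shape, times)
    print(f"  {shape:<13}" + "  ".join(f"{m:6.3f}" for m in mu))

print("\nTreated-group means and the 5-year effect (gamma = -0.05, delay = 1.25 y):")
specs = [
    ("steady", ss.TreatmentEffectSpec("proportional_time", gamma=-0.05)),
    ("early", ss.TreatmentEffectSpec("proportional_control_change", gamma=-0.05)),
    ("steady", ss.TreatmentEffectSpec("delayed_decline", delay=1.25)),
]
for shape, spec in specs:
    mu_t = ss.treated_mean(shape, spec, times)
    diff5 = float(mu_t[-1] - ss.control_mean(shape, 5.0))
    print(f"  {shape:<13}{spec.kind:<28}"
          + "  ".join(f"{m:6.3f}" for m in mu_t)
          + f"   effect at 5y: {diff5:+.2f}")

print("\nEach effect shape reaches the same -0.25 difference at five years, but")
print("distributes it differently over follow-up; only the proportional-to-time")
print("shape matches the random-slopes analysis model's assumption.")
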