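import numpy as np
import pytest

import slopesim as ss


@pytest.fixture(scope="session")
def vc_default() -> ss.VarianceComponents:
    """Reference variance components: (0.5, 0.01, 0.5*sqrt(0.005), 0.15)."""
    return ss.DEFAULT_VC


@pytest.fixture(scope="session")
def sched5() -> ss.VisitSchedule:
    return ss.VisitSchedule.annual(5)


@pytest.fixture(scope="session")
def sched3() -> ss.VisitSchedule:
    return ss.VisitSchedule.annual(3)


@pytest.fixture(scope="session")
def tiny_trial(vc_default) -> ss.LongitudinalDataset:
    """8 subjects, 3 visits: small enough for brute-force likelihood oracles."""
    spec = ss.TreatmentEffectSpec("proportional_time", gamma=-0.3)
    return ss.simulate_trial("steady", spec, vc_default, ss.VisitSchedule([0, 1, 2]), 8, 3)


@pytest.fixture(scope="session")
def small_trial(vc_default, sched5) -> ss.LongitudinalDataset:
    """40-subject steady-decline 5-year trial used for cross-library checks."""
    spec = ss.TreatmentEffectSpec("proportional_time", gamma=-0.05)
    return ss.simulate_trial("steady", spec, vc_default, sched5, 40, 0)


@pytest.fixture(scope="session")
def medium_trial(vc_default, sched5) -> ss.LongitudinalDataset:
    """200-subject steady-decline trial for model-equivalence checks."""
    spec = ss.TreatmentEffectSpec("proportional_time", gamma=-0.05)
    return ss.simulate_trial("steady", spec, vc_default, sched5, 200, 11)


def random_valid_vc(rng: np.random.Generator) -> ss.VarianceComponents:
    """A random draw from the valid variance-component region."""
    s2u0 = rng.uniform(0.05, 2.0)
    s2u1 = rng.uniform(0.001, 0.3)
    rho = rng.uniform(-0.95, 0.95)
    s2e = rng.uniform(0.05, 3.0)
    return ss.VarianceComponents(s2u0, s2u1, rho * np.sqrt(s2u0 * s2u1), s2e)
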