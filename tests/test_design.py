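"""Sample-size machinery: two-person variance, the size formula, pseudo-true effects."""

import numpy as np
import pytest
from scipy import stats as sps

import slopesim as ss
from conftest import random_valid_vc


def stacked_gls_var_gamma(vc, schedule):
    """Independent oracle: stack the 2-person design and invert numerically."""
    t = schedule.asarray()
    n = len(t)
    ones = np.ones_like(t)
    X = np.vstack(
        [np.column_stack([ones, t, 0 * t]), np.column_stack([ones, t, t])]
    )
    block = vc.marginal_covariance(t)
    Sigma = np.block(
        [[block, np.zeros((n, n))], [np.zeros((n, n)), block]]
    )
    cov = np.linalg.inv(X.T @ np.linalg.inv(Sigma) @ X)
    return cov[2, 2]


class TestSigmaPerson:
    def test_pure_residual_is_scaled_identity(self):
        vc = ss.VarianceComponents(0, 0, 0, 0.7)
        S = ss.sigma_person(vc, [0, 1, 2, 4])
        assert np.allclose(S, 0.7 * np.eye(4))

    def test_reference_entries(self, vc_default, sched5):
        S = ss.sigma_person(vc_default, sched5)
        assert S[0, 0] == pytest.approx(0.65, abs=1e-12)
        assert S[0, 5] == pytest.approx(0.5 + 5 * 0.5 * np.sqrt(0.005), abs=1e-12)

    def test_positive_definite_over_random_valid_inputs(self, sched5):
        rng = np.random.default_rng(0)
        for _ in range(25):
            vc = random_valid_vc(rng)
            np.linalg.cholesky(ss.sigma_person(vc, sched5))  # raises if not PD


class TestVarGammaTwoPerson:
    def test_hand_computed_two_visit_value(self):
        """iid errors over {0,1}: the 3x3 information inverts to V(gamma) = 2."""
        vc = ss.VarianceComponents(0, 0, 0, 1.0)
        v = ss.var_gamma_two_person(vc, ss.VisitSchedule([0, 1]))
        assert v == pytest.approx(2.0, abs=1e-12)

    def test_homogeneous_in_residual_variance(self):
        s = ss.VisitSchedule([0, 1, 2])
        v1 = ss.var_gamma_two_person(ss.VarianceComponents(0, 0, 0, 1.0), s)
        v2 = ss.var_gamma_two_person(ss.VarianceComponents(0, 0, 0, 2.0), s)
        assert v2 == pytest.approx(2 * v1, abs=1e-12)

    def test_matches_stacked_gls_oracle_randomised(self, sched5, sched3):
        rng = np.random.default_rng(123)
        for sched in (sched5, sched3, ss.VisitSchedule([0, 0.5, 1.5, 2, 4.5])):
            for _ in range(10):
                vc = random_valid_vc(rng)
                ours = ss.var_gamma_two_person(vc, sched)
                oracle = stacked_gls_var_gamma(vc, sched)
                assert ours == pytest.approx(oracle, abs=1e-10, rel=1e-10)


class TestSampleSize:
    def test_two_visit_reference_case(self):
        """V = 2, d = 1, alpha 0.05, power 0.8 gives N = 2 x ceil(7.849 x 2) = 32."""
        inputs = ss.SampleSizeInputs(
            d=1.0, alpha=0.05, power=0.8,
            vc=ss.VarianceComponents(0, 0, 0, 1.0), schedule=ss.VisitSchedule([0, 1]),
        )
        assert ss.sample_size(inputs) == 32

    def test_halving_d_quadruples_bracket(self, vc_default, sched5):
        z2 = (sps.norm.ppf(0.975) + sps.norm.ppf(0.8)) ** 2
        v2 = ss.var_gamma_two_person(vc_default, sched5)
        b1 = z2 * v2 / 0.05**2
        b2 = z2 * v2 / 0.025**2
        assert b2 == pytest.approx(4 * b1, rel=1e-12)
        n1 = ss.sample_size(ss.SampleSizeInputs(-0.05, 0.05, 0.8, vc_default, sched5))
        n2 = ss.sample_size(ss.SampleSizeInputs(-0.025, 0.05, 0.8, vc_default, sched5))
        assert n1 % 2 == 0 and n2 % 2 == 0
        assert n2 == 2 * int(np.ceil(b2))

    def test_analytic_power_attained_at_returned_n(self, sched5, sched3):
        """Power >= target at N; below target at N-2 unless the ceiling was exact."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            vc = random_valid_vc(rng)
            for sched in (sched5, sched3):
                n = ss.sample_size(ss.SampleSizeInputs(-0.05, 0.05, 0.8, vc, sched))
                assert ss.analytic_power(vc, sched, -0.05, 0.05, n) >= 0.8 - 1e-9
                if n > 2:
                    v2 = ss.var_gamma_two_person(vc, sched)
                    z2 = (sps.norm.ppf(0.975) + sps.norm.ppf(0.8)) ** 2
                    bracket = z2 * v2 / 0.05**2
                    if abs(bracket - round(bracket)) > 1e-9:  # ceiling not exact
                        assert ss.analytic_power(vc, sched, -0.05, 0.05, n - 2) < 0.8

    def test_invalid_inputs_rejected(self, vc_default, sched5):
        with pytest.raises(ValueError):
            ss.SampleSizeInputs(0.0, 0.05, 0.8, vc_default, sched5)
        with pytest.raises(ValueError):
            ss.SampleSizeInputs(-0.05, 1.2, 0.8, vc_default, sched5)
        with pytest.raises(ValueError):
            ss.scale_variance(2.0, 7)


class TestScaleVariance:
    def test_arithmetic(self):
        assert ss.scale_variance(2.0, 2) == 2.0
        assert ss.scale_variance(2.0, 100) == pytest.approx(0.04)


class TestExpectedRsEffect:
    def test_proportional_means_recovered_exactly(self, vc_default, sched5):
        """Means inside the model space return gamma exactly, for any covariance."""
        t = sched5.asarray()
        mu_c = 6 + 0.2 * t
        rng = np.random.default_rng(5)
        for gamma in (-0.05, 0.12):
            mu_t = mu_c + gamma * t
            for vc in (vc_default, random_valid_vc(rng)):
                got = ss.expected_rs_effect(mu_c, mu_t, vc, sched5)
                assert got == pytest.approx(gamma, abs=1e-12)

    def test_equal_means_give_zero(self, vc_default, sched3):
        mu = ss.control_mean("late", sched3.asarray())
        assert ss.expected_rs_effect(mu, mu, vc_default, sched3) == pytest.approx(0, abs=1e-12)

    def test_constant_shift_invariance(self, vc_default, sched5):
        t = sched5.asarray()
        mu_c = ss.control_mean("early", t)
        mu_t = ss.treated_mean(
            "early", ss.TreatmentEffectSpec("proportional_control_change", gamma=-0.05), t
        )
        a = ss.expected_rs_effect(mu_c, mu_t, vc_default, sched5)
        b = ss.expected_rs_effect(mu_c + 3.3, mu_t + 3.3, vc_default, sched5)
        assert a == pytest.approx(b, abs=1e-12)

    def test_nonproportional_effect_is_distorted(self, vc_default, sched3):
        """A non-proportional effect maps to a slope away from the naive -0.05/yr."""
        t = sched3.asarray()
        mu_c = ss.control_mean("early", t)
        mu_t = ss.treated_mean(
            "early", ss.TreatmentEffectSpec("proportional_control_change", gamma=-0.05), t
        )
        got = ss.expected_rs_effect(mu_c, mu_t, vc_default, sched3)
        assert got < -0.05  # more extreme than the proportional target


class TestSampleSizeCurve:
    def test_monotone_nonincreasing_in_length(self, vc_default):
        for s2e in (0.15, 2.0):
            vc = ss.VarianceComponents(0.5, 0.01, 0.5 * np.sqrt(0.005), s2e)
            curve = ss.sample_size_curve(vc, -0.05, 0.05, 0.8, lengths=[2, 3, 4, 5, 6, 7])
            ns = [n for _, n in curve]
            assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_single_length_reduces_to_sample_size(self, vc_default, sched5):
        [(_, n)] = ss.sample_size_curve(vc_default, -0.05, 0.05, 0.8, lengths=[5])
        assert n == ss.sample_size(ss.SampleSizeInputs(-0.05, 0.05, 0.8, vc_default, sched5))

    def test_early_and_late_fitted_curves_coincide(self, vc_default, sched5):
        """Averaged fitted covariances from early- and late-decline cohorts
        give nearly identical size-versus-length curves."""
        curves = {}
        for shape in ("early", "late"):
            fits = []
            for rep in range(10):
                ds = ss.simulate_observational(
                    shape, vc_default, sched5, 1000,
                    np.random.SeedSequence([77, rep]),
                )
                fits.append(ss.fit_random_slopes(ds, design="observational").vc_hat.astuple())
            vc_mean = ss.VarianceComponents.from_sequence(np.mean(fits, axis=0))
            curves[shape] = ss.sample_size_curve(vc_mean, -0.05, 0.05, 0.8, [2, 3, 4, 5, 6, 7])
        for (l1, n1), (l2, n2) in zip(curves["early"], curves["late"]):
            assert l1 == l2
            assert abs(n1 - n2) / max(n1, n2) < 0.10
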