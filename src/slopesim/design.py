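"""Sample-size machinery for trials analysed with a random-slopes model.

The treatment-slope variance is computed for a hypothetical two-person trial
(one control, one treated subject observed over the full schedule): with X
the 2 n_v x 3 stacked design (intercept, time, treated-by-time) and Sigma the
block-diagonal marginal covariance implied by the variance components,

    V(gamma-hat) = [(X' Sigma^-1 X)^-1]_{33}

Because arms are exactly balanced, an N-person trial has variance
``V / (N / 2)``, and the total sample size for a two-sided level-alpha test
with power 1 - beta against a slope difference d is

    N = 2 * ceil( (z_{1-alpha/2} + z_{1-beta})^2 * V(gamma-hat) / d^2 )

(normal quantiles; the ceiling keeps N even).  The same two-person GLS
device also yields the large-sample ("pseudo-true") value of the treatment
slope when the true group means do not follow the linear model: the GLS
projection of the stacked mean vectors onto the design, a covariance-
weighted linear combination of the per-visit group-mean differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import stats as sps

from .params import VarianceComponents, VisitSchedule

__all__ = [
    "TwoPersonDesign",
    "SampleSizeInputs",
    "sigma_person",
    "var_gamma_two_person",
    "scale_variance",
    "sample_size",
    "analytic_power",
    "expected_rs_effect",
    "projection_vc",
    "sample_size_curve",
]


def sigma_person(vc: VarianceComponents, times: Union[VisitSchedule, Iterable[float]]) -> np.ndarray:
    """Marginal covariance of one subject's visit vector under `vc`.

    Entry (j, k) is ``sigma2_u0 + t_j t_k sigma2_u1 + (t_j + t_k) sigma_u01``
    plus ``sigma2_e`` on the diagonal.  Positive definite for every valid
    `vc` (Gram structure plus a positive ridge from the residual variance).
    """
    t = times.asarray() if isinstance(times, VisitSchedule) else np.asarray(list(times), float)
    return vc.marginal_covariance(t)


@dataclass(frozen=True)
class TwoPersonDesign:
    """Stacked design and covariance for the hypothetical 2-person trial.

    ``X`` stacks one control person over the schedule (treated-by-time
    column zero) on top of one treated person (treated-by-time column equal
    to the visit times); ``Sigma`` is block-diagonal with two identical
    per-person blocks.
    """

    X: np.ndarray
    Sigma: np.ndarray
    schedule: VisitSchedule

    @classmethod
    def build(cls, vc: VarianceComponents, schedule: VisitSchedule) -> "TwoPersonDesign":
        t = schedule.asarray()
        ones = np.ones_like(t)
        Xc = np.column_stack([ones, t, 0.0 * t])
        Xt = np.column_stack([ones, t, t])
        X = np.vstack([Xc, Xt])
        block = sigma_person(vc, schedule)
        n = len(t)
        Sigma = np.zeros((2 * n, 2 * n))
        Sigma[:n, :n] = block
        Sigma[n:, n:] = block
        return cls(X=X, Sigma=Sigma, schedule=schedule)

    def information(self) -> np.ndarray:
        """X' Sigma^-1 X (3 x 3)."""
        SinvX = np.linalg.solve(self.Sigma, self.X)
        return self.X.T @ SinvX


def var_gamma_two_person(
    vc: VarianceComponents, schedule: VisitSchedule
) -> float:
    """Variance of the treatment-slope estimate in a 2-person trial.

    Element (3, 3) of ``(X' Sigma^-1 X)^-1`` for the two-person design.
    Raises a :class:`numpy.linalg.LinAlgError` when the information matrix
    is singular (e.g. fewer than two distinct visit times).
    """
    design = TwoPersonDesign.build(vc, schedule)
    info = design.information()
    cov = np.linalg.inv(info)
    return float(cov[2, 2])


def scale_variance(v2: float, n_total: int) -> float:
    """Treatment-slope variance for an N-person 1:1 trial: ``v2 / (N/2)``."""
    if n_total < 2 or n_total % 2:
        raise ValueError("n_total must be even and >= 2")
    return v2 / (n_total / 2)


@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs to the sample-size formula.

    `d` is the target treatment effect parameterised as a difference in
    slopes (outcome/year); `alpha` the two-sided type-I error; `power` the
    desired power.
    """

    d: float
    alpha: float
    power: float
    vc: VarianceComponents
    schedule: VisitSchedule

    def __post_init__(self):
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.d == 0:
            raise ValueError("target effect d must be non-zero")


def sample_size(inputs: SampleSizeInputs) -> int:
    """Total (even) sample size for a 1:1 trial powered on the slope difference."""
    v2 = var_gamma_two_person(inputs.vc, inputs.schedule)
    z_a = sps.norm.ppf(1 - inputs.alpha / 2)
    z_b = sps.norm.ppf(inputs.power)
    bracket = (z_a + z_b) ** 2 * v2 / inputs.d**2
    return 2 * math.ceil(bracket - 1e-12)


def analytic_power(
    vc: VarianceComponents,
    schedule: VisitSchedule,
    d: float,
    alpha: float,
    n_total: int,
) -> float:
    """Normal-approximation power of the slope test at sample size `n_total`."""
    v2 = var_gamma_two_person(vc, schedule)
    se = math.sqrt(scale_variance(v2, n_total))
    z_a = sps.norm.ppf(1 - alpha / 2)
    return float(sps.norm.cdf(abs(d) / se - z_a))


def expected_rs_effect(
    mu_control: Sequence[float],
    mu_treated: Sequence[float],
    vc_pseudo: VarianceComponents,
    schedule: VisitSchedule,
) -> float:
    """Large-sample expectation of the random-slopes treatment slope.

    When the true group means do not follow the linear model, the
    random-slopes estimate converges to the GLS projection of the true means
    onto the model space: element 3 of ``(X' Sigma^-1 X)^-1 X' Sigma^-1 mu``
    with ``mu`` the stacked (control, treated) mean vectors and ``Sigma``
    built from `vc_pseudo` — a linear combination of the per-visit
    group-mean differences whose weights depend on the covariance.

    `vc_pseudo` should be the covariance the fitted model converges to; for
    a misspecified mean a natural choice is the random-slopes fit to a large
    simulated cohort under the target generator (see
    :func:`projection_vc`).
    """
    mu_c = np.asarray(mu_control, dtype=float)
    mu_t = np.asarray(mu_treated, dtype=float)
    n = schedule.n_visits
    if mu_c.shape != (n,) or mu_t.shape != (n,):
        raise ValueError("mean vectors must conform to the schedule")
    design = TwoPersonDesign.build(vc_pseudo, schedule)
    mu = np.concatenate([mu_c, mu_t])
    SinvX = np.linalg.solve(design.Sigma, design.X)
    beta = np.linalg.solve(design.X.T @ SinvX, SinvX.T @ mu)
    return float(beta[2])


def projection_vc(
    shape,
    vc: VarianceComponents,
    schedule: VisitSchedule,
    n_subjects: int = 50_000,
    seed: int = 0,
) -> VarianceComponents:
    """Pseudo-true variance components of the random-slopes model.

    Fits the observational random-slopes model to one large simulated
    untreated cohort under (`shape`, `vc`) on `schedule`; at this size the
    fit approximates the KL projection of the true distribution onto the
    random-slopes family, which is the covariance entering the pseudo-true
    treatment slope.
    """
    from .reml import fit_random_slopes
    from .simulate import simulate_observational

    ds = simulate_observational(shape, vc, schedule, n_subjects, seed)
    fit = fit_random_slopes(ds, design="observational")
    return fit.vc_hat


def sample_size_curve(
    vc: VarianceComponents,
    d: float,
    alpha: float,
    power: float,
    lengths: Sequence[float],
    visit_interval: float = 1.0,
) -> list[tuple[float, int]]:
    """Sample size versus trial length, at a fixed visit interval.

    Each length gets a baseline-plus-regular-visits schedule
    (``0, interval, ..., length``) and the standard calculation; returns
    ``[(length, N), ...]``.  N is non-increasing in length for fixed inputs:
    longer trials see more of the slope.
    """
    out = []
    for length in lengths:
        if length <= 0:
            raise ValueError("trial lengths must be positive")
        sched = VisitSchedule.regular(float(length), visit_interval)
        n = sample_size(SampleSizeInputs(d=d, alpha=alpha, power=power, vc=vc, schedule=sched))
        out.append((float(length), n))
    return out
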