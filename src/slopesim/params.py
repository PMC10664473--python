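"""Shared parameter containers: visit schedules and random-slopes variance components.

These two objects are passed between every layer of the package: the data
generator uses them to simulate cohorts, the fitting engines estimate them,
and the sample-size machinery turns them into the marginal covariance of a
hypothetical two-person trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["VisitSchedule", "VarianceComponents", "DEFAULT_VC"]


@dataclass(frozen=True)
class VisitSchedule:
    """An ordered set of measurement times in years, baseline coded 0.

    Parameters
    ----------
    times
        Strictly increasing visit times; the first must be 0 (baseline).
        Annual schedules such as ``0, 1, ..., 5`` are typical, but any
        strictly increasing real-valued grid is accepted (e.g. six-monthly
        visits).
    """

    times: tuple[float, ...]

    def __init__(self, times: Iterable[float]):
        t = tuple(float(x) for x in times)
        if len(t) < 2:
            raise ValueError("a schedule needs at least 2 visits")
        if t[0] != 0.0:
            raise ValueError("baseline visit must be at time 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("visit times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @classmethod
    def annual(cls, years: int) -> "VisitSchedule":
        """Baseline plus annual visits out to `years`."""
        if years < 1:
            raise ValueError("years must be >= 1")
        return cls(range(years + 1))

    @classmethod
    def regular(cls, length: float, interval: float) -> "VisitSchedule":
        """Baseline plus visits every `interval` years up to `length`."""
        if interval <= 0 or length < interval:
            raise ValueError("need 0 < interval <= length")
        n = int(round(length / interval))
        return cls(np.linspace(0.0, n * interval, n + 1))

    @property
    def n_visits(self) -> int:
        return len(self.times)

    @property
    def t_final(self) -> float:
        return self.times[-1]

    def asarray(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def __iter__(self):
        return iter(self.times)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class VarianceComponents:
    """Covariance parameters of a random-intercept/random-slope model.

    The implied marginal covariance between visits ``j`` and ``k`` of the
    same subject is::

        sigma2_u0 + t_j * t_k * sigma2_u1 + (t_j + t_k) * sigma_u01
            + (sigma2_e if j == k else 0)

    Attributes
    ----------
    sigma2_u0 : float
        Random-intercept variance (outcome^2).
    sigma2_u1 : float
        Random-slope variance (outcome^2 / year^2).
    sigma_u01 : float
        Intercept-slope covariance (outcome^2 / year).
    sigma2_e : float
        Residual error variance (outcome^2).
    """

    sigma2_u0: float
    sigma2_u1: float
    sigma_u01: float
    sigma2_e: float

    def __post_init__(self):
        if self.sigma2_u0 < 0 or self.sigma2_u1 < 0:
            raise ValueError("random-effect variances must be non-negative")
        # sigma2_e = 0 is permitted for noise-free generator fixtures; the
        # fitting engines require data with positive residual variance.
        if self.sigma2_e < 0:
            raise ValueError("residual variance must be non-negative")
        # Allow a whisker of slack for round-tripped estimates on the boundary.
        if self.sigma_u01**2 > self.sigma2_u0 * self.sigma2_u1 * (1 + 1e-12) + 1e-300:
            raise ValueError("sigma_u01^2 must not exceed sigma2_u0 * sigma2_u1")

    @property
    def correlation(self) -> float:
        """Intercept-slope correlation; 0 when either variance is 0."""
        denom = np.sqrt(self.sigma2_u0 * self.sigma2_u1)
        if denom == 0:
            return 0.0
        return float(np.clip(self.sigma_u01 / denom, -1.0, 1.0))

    @property
    def G(self) -> np.ndarray:
        """2x2 random-effects covariance matrix."""
        return np.array(
            [
                [self.sigma2_u0, self.sigma_u01],
                [self.sigma_u01, self.sigma2_u1],
            ]
        )

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.sigma2_u0, self.sigma2_u1, self.sigma_u01, self.sigma2_e)

    def marginal_covariance(self, times) -> np.ndarray:
        """Implied per-subject marginal covariance over the given visit times.

        Entry (j, k) is ``sigma2_u0 + t_j t_k sigma2_u1 + (t_j + t_k) sigma_u01``
        plus ``sigma2_e`` on the diagonal (R + Z G Z' with Z = [1, t]).
        """
        t = np.asarray(times, dtype=float)
        Z = np.column_stack([np.ones_like(t), t])
        return Z @ self.G @ Z.T + self.sigma2_e * np.eye(len(t))

    @classmethod
    def from_sequence(cls, vals: Sequence[float]) -> "VarianceComponents":
        u0, u1, u01, e = (float(v) for v in vals)
        return cls(u0, u1, u01, e)


#: Default variance components used throughout the worked examples:
#: intercept variance 0.5, slope variance 0.01, intercept-slope correlation
#: 0.5 (covariance 0.5 * sqrt(0.5 * 0.01)), residual variance 0.15.
DEFAULT_VC = VarianceComponents(
    sigma2_u0=0.5,
    sigma2_u1=0.01,
    sigma_u01=0.5 * np.sqrt(0.5 * 0.01),
    sigma2_e=0.15,
)
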