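"""Synthetic longitudinal cohorts: observational studies and two-arm trials.

The data-generating mechanism is

    y_ij = mean_arm(t_j) + u0_i + u1_i * t_j + e_ij

with ``(u0_i, u1_i)`` bivariate Gaussian (zero mean, covariance from
:class:`~slopesim.params.VarianceComponents`) and ``e_ij`` i.i.d. Gaussian
residual error.  The fixed part follows one of the four trajectory shapes;
non-linearity enters only through the fixed part, the subject-level time
component ``u1_i * t_j`` stays linear, so all shapes share one covariance
structure.  Datasets are complete and balanced: every subject is observed at
every scheduled visit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .params import VarianceComponents, VisitSchedule
from .trajectories import (
    TrajectoryShape,
    TreatmentEffectSpec,
    control_mean,
    get_shape,
    treated_mean,
)

__all__ = [
    "LongitudinalDataset",
    "draw_subject_effects",
    "simulate_observational",
    "simulate_trial",
]

COLUMNS = ["subject_id", "arm", "time", "y"]


@dataclass(frozen=True)
class LongitudinalDataset:
    """Long-format longitudinal outcomes plus their visit schedule.

    `data` has one row per subject-visit with columns ``subject_id`` (int),
    ``arm`` (0 control / 1 treated), ``time`` (years) and ``y`` (outcome).
    The dataset must be balanced and complete against `schedule`, and arm
    must be constant within subject.
    """

    data: pd.DataFrame
    schedule: VisitSchedule

    def __post_init__(self):
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        times = self.schedule.asarray()
        per_subject = df.groupby("subject_id")["time"]
        counts = per_subject.count()
        if not (counts == len(times)).all():
            raise ValueError("every subject must have exactly one record per visit")
        observed = np.sort(df["time"].unique())
        if len(observed) != len(times) or not np.allclose(observed, times):
            raise ValueError("observed times do not match the schedule")
        arms = df.groupby("subject_id")["arm"].nunique()
        if (arms != 1).any():
            raise ValueError("arm must be constant within subject")

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def arms(self) -> np.ndarray:
        return np.sort(self.data["arm"].unique())

    def arm_outcome_matrix(self, arm: int) -> np.ndarray:
        """Outcomes for one arm as an (n_subjects, n_visits) array.

        Rows are subjects (ascending id), columns are visits in schedule
        order.  This wide layout is what the balanced-data fitting engines
        consume.
        """
        sub = self.data[self.data["arm"] == arm]
        wide = sub.pivot(index="subject_id", columns="time", values="y")
        wide = wide.reindex(columns=self.schedule.times)
        if wide.isna().any().any():  # pragma: no cover - guarded by validation
            raise ValueError("incomplete data for arm %d" % arm)
        return wide.to_numpy(dtype=float)

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the long-format records as CSV (header row included)."""
        self.data[COLUMNS].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "LongitudinalDataset":
        """Read a CSV written by :meth:`to_csv`; schedule inferred from times."""
        df = pd.read_csv(path)
        times = np.sort(df["time"].unique())
        return cls(df, VisitSchedule(times))


def draw_subject_effects(
    vc: VarianceComponents, n: int, seed: Union[int, np.random.Generator]
) -> np.ndarray:
    """Draw `n` i.i.d. (u0, u1) random intercept/slope pairs.

    Returns an (n, 2) array of zero-mean bivariate Gaussian draws with
    covariance ``vc.G``.  Reproducible given `seed` (an int or Generator).
    Zero-variance components are honoured exactly (degenerate Gaussian).
    """
    rng = np.random.default_rng(seed)
    G = vc.G
    # Use the matrix square root via eigen-decomposition so singular G
    # (zero variances, boundary correlation) is handled without jitter.
    w, V = np.linalg.eigh(G)
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    z = rng.standard_normal((n, 2))
    return z @ L.T


def _simulate_arm(
    mean_curve: np.ndarray,
    vc: VarianceComponents,
    times: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    u = draw_subject_effects(vc, n, rng)
    e = rng.standard_normal((n, len(times))) * np.sqrt(vc.sigma2_e)
    return mean_curve[None, :] + u[:, [0]] + u[:, [1]] * times[None, :] + e


def _to_long(y_by_arm: dict[int, np.ndarray], times: np.ndarray,
             subject_ids_by_arm: dict[int, np.ndarray]) -> pd.DataFrame:
    frames = []
    for arm, y in y_by_arm.items():
        ids = subject_ids_by_arm[arm]
        n = y.shape[0]
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(ids, len(times)),
                    "arm": arm,
                    "time": np.tile(times, n),
                    "y": y.ravel(),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["subject_id", "time"], ignore_index=True)


def simulate_observational(
    shape: Union[str, TrajectoryShape],
    vc: VarianceComponents,
    schedule: VisitSchedule,
    n_subjects: int,
    seed: Union[int, np.random.Generator],
) -> LongitudinalDataset:
    """Simulate an untreated (single-arm) observational study.

    Every subject follows the control-group mean trajectory of `shape` plus
    subject-level random intercept/slope and residual error; ``arm`` is 0
    throughout.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    shape = get_shape(shape)
    rng = np.random.default_rng(seed)
    times = schedule.asarray()
    mu = np.asarray(control_mean(shape, times), dtype=float)
    y = _simulate_arm(mu, vc, times, n_subjects, rng)
    df = _to_long({0: y}, times, {0: np.arange(n_subjects)})
    return LongitudinalDataset(df, schedule)


def simulate_trial(
    shape: Union[str, TrajectoryShape],
    spec: TreatmentEffectSpec,
    vc: VarianceComponents,
    schedule: VisitSchedule,
    n_total: int,
    seed: Union[int, np.random.Generator],
) -> LongitudinalDataset:
    """Simulate a 1:1 randomised two-arm trial of `n_total` subjects.

    Exactly ``n_total/2`` subjects per arm (exact balance, as the sample-size
    formula assumes).  The control arm follows the observational generator;
    the treated arm mean follows :func:`~slopesim.trajectories.treated_mean`.
    Random-effect and residual structure is identical across arms.  Subject
    ids are a seed-determined permutation so id carries no arm information.
    """
    if n_total < 2 or n_total % 2:
        raise ValueError("n_total must be even and >= 2")
    shape = get_shape(shape)
    rng = np.random.default_rng(seed)
    times = schedule.asarray()
    mu_c = np.asarray(control_mean(shape, times), dtype=float)
    mu_t = np.asarray(treated_mean(shape, spec, times), dtype=float)
    n_arm = n_total // 2
    y_c = _simulate_arm(mu_c, vc, times, n_arm, rng)
    y_t = _simulate_arm(mu_t, vc, times, n_arm, rng)
    ids = rng.permutation(n_total)
    df = _to_long({0: y_c, 1: y_t}, times, {0: ids[:n_arm], 1: ids[n_arm:]})
    return LongitudinalDataset(df, schedule)
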