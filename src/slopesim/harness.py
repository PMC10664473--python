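"""Monte-Carlo harness: the six-step design-then-analyse simulation loop.

Each replicate of a scenario
(1) simulates an untreated observational study,
(2) fits the observational random-slopes model to estimate variance
    components,
(3) turns those estimates into a trial sample size,
(4) simulates a 1:1 trial of that size under the scenario's trajectory and
    treatment-effect shape,
(5) analyses the trial with each requested model and extracts the
    final-visit treatment-effect estimand,
and the scenario summary (6) aggregates rejection rates, mean effects and
SE diagnostics over replicates.

Seeding: every replicate draws from child seeds derived deterministically
from the scenario base seed, so replicates are independent, individually
reproducible, and independent of execution order.  Observational-stage seeds
are keyed only on (trajectory, residual variance, replicate) — not on the
treatment-effect kind — so all effect options within a scenario family see
the identical sequence of observational studies and hence of sample sizes,
mirroring the computational shortcut of reusing one set of design datasets
across effect options.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .design import SampleSizeInputs, sample_size
from .estimand import TreatmentEffectEstimate, final_time_effect
from .mmrm import MARGINAL_KINDS, fit_marginal
from .params import VarianceComponents, VisitSchedule
from .reml import fit_with_ladder
from .simulate import simulate_observational, simulate_trial
from .trajectories import EFFECT_KINDS, SHAPE_NAMES, TreatmentEffectSpec

__all__ = [
    "ScenarioConfig",
    "RepResult",
    "ModelPerformance",
    "PerformanceSummary",
    "run_replicate",
    "run_scenario",
    "mc_se",
    "mc_ci_bounds",
    "se_pct_bias",
    "build_grid",
    "write_report",
    "read_report",
]

ALL_MODELS = ("rs",) + MARGINAL_KINDS

#: Scenario calibration by residual variance: (gamma, target d, delay years).
EFFECT_CALIBRATION = {0.15: (-0.05, -0.05, 1.25), 2.0: (-0.1, -0.1, 2.5)}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation scenario."""

    shape: str = "steady"
    effect_kind: str = "proportional_time"
    gamma: float = -0.05
    delay: float = 0.0
    sigma2_e: float = 0.15
    sigma2_u0: float = 0.5
    sigma2_u1: float = 0.01
    sigma_u01: float = 0.5 * float(np.sqrt(0.5 * 0.01))
    obs_years: float = 5.0
    trial_years: float = 5.0
    visit_interval: float = 1.0
    n_obs: int = 1000
    d: float = -0.05
    alpha: float = 0.05
    power_target: float = 0.8
    n_reps: int = 500
    base_seed: int = 1
    models: tuple[str, ...] = ("rs", "ltfc", "ftfc")
    boundary_filter: str = "none"

    def __post_init__(self):
        if self.shape not in SHAPE_NAMES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.effect_kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.effect_kind!r}")
        if self.effect_kind in ("proportional_time", "proportional_control_change"):
            if self.d * self.gamma <= 0:
                raise ValueError("d must have the same sign as gamma")
        if self.effect_kind == "delayed_decline" and self.shape != "steady":
            raise ValueError("delayed_decline is defined only for the steady shape")
        bad = [m for m in self.models if m not in ALL_MODELS]
        if bad:
            raise ValueError(f"unknown analysis models {bad}")
        if self.boundary_filter not in ("none", "exclude_obs_boundary"):
            raise ValueError("boundary_filter must be 'none' or 'exclude_obs_boundary'")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")

    # -- derived objects ----------------------------------------------------
    @property
    def vc(self) -> VarianceComponents:
        return VarianceComponents(self.sigma2_u0, self.sigma2_u1, self.sigma_u01, self.sigma2_e)

    @property
    def obs_schedule(self) -> VisitSchedule:
        return VisitSchedule.regular(self.obs_years, self.visit_interval)

    @property
    def trial_schedule(self) -> VisitSchedule:
        return VisitSchedule.regular(self.trial_years, self.visit_interval)

    @property
    def effect_spec(self) -> TreatmentEffectSpec:
        return TreatmentEffectSpec(self.effect_kind, gamma=self.gamma, delay=self.delay)

    def label(self) -> str:
        return (
            f"{self.shape}/{self.effect_kind}/s2e={self.sigma2_e:g}/"
            f"trial={self.trial_years:g}y"
        )

    # -- seed derivation ----------------------------------------------------
    def _obs_seed(self, rep: int) -> np.random.SeedSequence:
        # Keyed on (trajectory, residual variance, replicate) only: sample
        # sizes are shared across treatment-effect kinds.
        return np.random.SeedSequence(
            [self.base_seed, 101, SHAPE_NAMES.index(self.shape),
             int(round(self.sigma2_e * 1e6)), rep]
        )

    def _trial_seed(self, rep: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            [self.base_seed, 202, SHAPE_NAMES.index(self.shape),
             int(round(self.sigma2_e * 1e6)),
             int(round(self.trial_years * 1000)),
             EFFECT_KINDS.index(self.effect_kind), rep]
        )

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RepResult:
    """Outcome of one replicate of the six-step loop."""

    rep_index: int
    usable: bool
    n_trial: int = 0
    obs_vc_hat: Optional[tuple[float, float, float, float]] = None
    obs_converged: bool = False
    obs_boundary: bool = False
    trial_boundary: Optional[bool] = None
    converged: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict)  # model -> TreatmentEffectEstimate


def run_replicate(config: ScenarioConfig, rep_index: int) -> RepResult:
    """Run steps 1-5 of the loop for one replicate (deterministic in inputs)."""
    rng_obs = np.random.default_rng(config._obs_seed(rep_index))
    obs = simulate_observational(
        config.shape, config.vc, config.obs_schedule, config.n_obs, rng_obs
    )
    obs_fit = fit_with_ladder(obs, design="observational")
    if not obs_fit.converged:
        return RepResult(rep_index=rep_index, usable=False, obs_converged=False)
    n_trial = sample_size(
        SampleSizeInputs(
            d=config.d, alpha=config.alpha, power=config.power_target,
            vc=obs_fit.vc_hat, schedule=config.trial_schedule,
        )
    )
    n_trial = max(n_trial, 4)
    rng_trial = np.random.default_rng(config._trial_seed(rep_index))
    trial = simulate_trial(
        config.shape, config.effect_spec, config.vc, config.trial_schedule,
        n_trial, rng_trial,
    )
    out = RepResult(
        rep_index=rep_index, usable=True, n_trial=n_trial,
        obs_vc_hat=obs_fit.vc_hat.astuple(), obs_converged=True,
        obs_boundary=obs_fit.boundary,
    )
    for model in config.models:
        if model == "rs":
            fit = fit_with_ladder(trial, design="trial")
            out.trial_boundary = fit.boundary if fit.converged else None
        else:
            fit = fit_marginal(trial, model)
        out.converged[model] = fit.converged
        if fit.converged:
            out.estimates[model] = final_time_effect(
                fit, config.trial_schedule, config.alpha
            )
    return out


def mc_se(p: float, n_reps: int) -> float:
    """Monte-Carlo standard error of a proportion, in percentage points."""
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    return 100.0 * float(np.sqrt(p * (1 - p) / n_reps))


def mc_ci_bounds(p_nominal: float, n_reps: int, reported_dp: int = 1) -> tuple[float, float]:
    """95% Monte-Carlo interval around a nominal rate, at reporting precision.

    The MC SE is rounded to `reported_dp` decimals first, then the bounds
    ``100 p +/- 1.96 se`` are rounded the same way — the convention used when
    quoting, e.g., 4.4-5.6% around a nominal 5% at 5000 replicates.
    """
    se = round(mc_se(p_nominal, n_reps), reported_dp)
    centre = 100.0 * p_nominal
    return (round(centre - 1.96 * se, reported_dp), round(centre + 1.96 * se, reported_dp))


def se_pct_bias(mean_model_se: float, empirical_se: float) -> float:
    """Percentage bias of the mean model-based SE against the empirical SE."""
    if empirical_se <= 0:
        raise ValueError("empirical SE must be positive")
    return 100.0 * (mean_model_se - empirical_se) / empirical_se


@dataclass
class ModelPerformance:
    """Per-model Monte-Carlo metrics within one scenario."""

    model: str
    converged_pct: float
    boundary_pct: Optional[float]
    reject_pct: float
    reject_mc_se: float
    mean_effect: float
    mean_slope: Optional[float]
    empirical_se: float
    mean_model_se: float
    se_bias_pct: float


@dataclass
class PerformanceSummary:
    """Aggregated results of one scenario."""

    config: ScenarioConfig
    n_reps: int
    n_unusable: int
    n_boundary_excluded: int
    n_nonconverged_excluded: int
    n_reps_used: int
    obs_boundary_pct: float
    n_trial_mean: float
    n_trial_median: float
    n_trial_q1: float
    n_trial_q3: float
    models: dict[str, ModelPerformance]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        cfg = self.config
        for m in cfg.models:
            perf = self.models[m]
            rows.append(
                {
                    "shape": cfg.shape,
                    "effect_kind": cfg.effect_kind,
                    "sigma2_e": cfg.sigma2_e,
                    "trial_years": cfg.trial_years,
                    "n_reps": self.n_reps,
                    "n_reps_used": self.n_reps_used,
                    "n_unusable": self.n_unusable,
                    "n_boundary_excluded": self.n_boundary_excluded,
                    "n_nonconverged_excluded": self.n_nonconverged_excluded,
                    "obs_boundary_pct": self.obs_boundary_pct,
                    "n_trial_mean": self.n_trial_mean,
                    "n_trial_median": self.n_trial_median,
                    "n_trial_q1": self.n_trial_q1,
                    "n_trial_q3": self.n_trial_q3,
                    "model": perf.model,
                    "converged_pct": perf.converged_pct,
                    "boundary_pct": perf.boundary_pct,
                    "reject_pct": perf.reject_pct,
                    "reject_mc_se": perf.reject_mc_se,
                    "mean_effect": perf.mean_effect,
                    "mean_slope": perf.mean_slope,
                    "empirical_se": perf.empirical_se,
                    "mean_model_se": perf.mean_model_se,
                    "se_bias_pct": perf.se_bias_pct,
                }
            )
        return pd.DataFrame(rows)


def run_scenario(
    config: ScenarioConfig,
    n_reps: Optional[int] = None,
    keep_reps: bool = False,
):
    """Run the full loop for one scenario and aggregate performance measures.

    Metrics other than convergence itself are computed only over replicates
    in which the observational fit and every requested analysis model
    converged (and, under ``boundary_filter="exclude_obs_boundary"``, whose
    observational correlation estimate stayed inside magnitude 0.99).

    Returns the :class:`PerformanceSummary`, or ``(summary, reps)`` when
    `keep_reps` is set.
    """
    n_reps = config.n_reps if n_reps is None else int(n_reps)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    reps = [run_replicate(config, r) for r in range(n_reps)]
    usable = [r for r in reps if r.usable]
    if not usable:
        raise RuntimeError(f"no usable replicates in scenario {config.label()}")
    n_unusable = n_reps - len(usable)
    obs_boundary_pct = 100.0 * np.mean([r.obs_boundary for r in usable])
    if config.boundary_filter == "exclude_obs_boundary":
        kept = [r for r in usable if not r.obs_boundary]
        n_boundary_excluded = len(usable) - len(kept)
    else:
        kept, n_boundary_excluded = usable, 0
    if not kept:
        raise RuntimeError("boundary filter removed every replicate")
    complete = [r for r in kept if all(r.converged.get(m, False) for m in config.models)]
    n_nonconv = len(kept) - len(complete)
    if not complete:
        raise RuntimeError("no replicate with all models converged")
    n_used = len(complete)
    n_trials = np.array([r.n_trial for r in complete], dtype=float)
    t_final = config.trial_schedule.t_final

    models: dict[str, ModelPerformance] = {}
    for m in config.models:
        conv_pct = 100.0 * np.mean([r.converged.get(m, False) for r in kept])
        if m == "rs":
            flags = [r.trial_boundary for r in complete if r.trial_boundary is not None]
            boundary_pct = 100.0 * float(np.mean(flags)) if flags else 0.0
        else:
            boundary_pct = None
        ests: list[TreatmentEffectEstimate] = [r.estimates[m] for r in complete]
        effects = np.array([e.effect_final for e in ests])
        ses = np.array([e.se for e in ests])
        p_rej = float(np.mean([e.reject for e in ests]))
        emp_se = float(np.std(effects, ddof=1))
        mean_model_se = float(np.sqrt(np.mean(ses**2)))
        models[m] = ModelPerformance(
            model=m,
            converged_pct=conv_pct,
            boundary_pct=boundary_pct,
            reject_pct=100.0 * p_rej,
            reject_mc_se=mc_se(p_rej, n_used),
            mean_effect=float(np.mean(effects)),
            mean_slope=float(np.mean(effects)) / t_final if m != "ftfc" else None,
            empirical_se=emp_se,
            mean_model_se=mean_model_se,
            se_bias_pct=se_pct_bias(mean_model_se, emp_se) if emp_se > 0 else float("nan"),
        )
    summary = PerformanceSummary(
        config=config,
        n_reps=n_reps,
        n_unusable=n_unusable,
        n_boundary_excluded=n_boundary_excluded,
        n_nonconverged_excluded=n_nonconv,
        n_reps_used=n_used,
        obs_boundary_pct=float(obs_boundary_pct),
        n_trial_mean=float(np.mean(n_trials)),
        n_trial_median=float(np.median(n_trials)),
        n_trial_q1=float(np.percentile(n_trials, 25)),
        n_trial_q3=float(np.percentile(n_trials, 75)),
        models=models,
    )
    if keep_reps:
        return summary, reps
    return summary


def build_grid(
    shapes: Sequence[str] = SHAPE_NAMES,
    effects: Sequence[str] = ("none", "proportional", "nonproportional"),
    trial_lengths: Sequence[float] = (5.0, 3.0),
    sigma2_es: Sequence[float] = (0.15, 2.0),
    n_reps: int = 500,
    base_seed: int = 1,
    boundary_filter: str = "none",
) -> list[ScenarioConfig]:
    """Factorial scenario grid.

    `effects` entries are scenario families: ``"none"``,
    ``"proportional"`` (effect proportional to time) and
    ``"nonproportional"`` (delayed decline for the steady shape, effect
    proportional to control-arm change otherwise).  Effect sizes and delays
    are calibrated per residual variance so every family shares the same
    final-visit effect at five years: gamma = d = -0.05/yr and delay 1.25 y
    when ``sigma2_e = 0.15``; gamma = d = -0.1/yr and delay 2.5 y when
    ``sigma2_e = 2``.  The FCTFC model is carried only in the scenario used
    to establish its equivalence with LTFC (steady/proportional/5-year/low
    residual variance).
    """
    grid = []
    for s2e in sigma2_es:
        if s2e not in EFFECT_CALIBRATION:
            raise ValueError(
                f"no effect calibration for sigma2_e={s2e}; known: {sorted(EFFECT_CALIBRATION)}"
            )
        gamma, d, delay = EFFECT_CALIBRATION[s2e]
        for shape in shapes:
            for years in trial_lengths:
                for fam in effects:
                    if fam == "none":
                        kind, g, dl = "none", 0.0, 0.0
                    elif fam == "proportional":
                        kind, g, dl = "proportional_time", gamma, 0.0
                    elif fam == "nonproportional":
                        if shape == "steady":
                            kind, g, dl = "delayed_decline", 0.0, delay
                        else:
                            kind, g, dl = "proportional_control_change", gamma, 0.0
                    else:
                        raise ValueError(f"unknown effect family {fam!r}")
                    models = ("rs", "ltfc", "ftfc")
                    if (
                        fam == "proportional" and shape == "steady"
                        and years == 5.0 and s2e == 0.15
                    ):
                        models = ("rs", "ltfc", "fctfc", "ftfc")
                    grid.append(
                        ScenarioConfig(
                            shape=shape, effect_kind=kind, gamma=g, delay=dl,
                            sigma2_e=s2e, trial_years=float(years), d=d,
                            n_reps=n_reps, base_seed=base_seed, models=models,
                            boundary_filter=boundary_filter,
                        )
                    )
    return grid


REPORT_COLUMNS = [
    "shape", "effect_kind", "sigma2_e", "trial_years", "n_reps", "n_reps_used",
    "n_unusable", "n_boundary_excluded", "n_nonconverged_excluded",
    "obs_boundary_pct", "n_trial_mean", "n_trial_median", "n_trial_q1",
    "n_trial_q3", "model", "converged_pct", "boundary_pct", "reject_pct",
    "reject_mc_se", "mean_effect", "mean_slope", "empirical_se",
    "mean_model_se", "se_bias_pct",
]


def write_report(summaries: Sequence[PerformanceSummary], path: Union[str, Path]) -> pd.DataFrame:
    """Write one CSV row per scenario x model; returns the table written."""
    if not summaries:
        raise ValueError("need at least one summary")
    table = pd.concat([s.to_frame() for s in summaries], ignore_index=True)
    table = table[REPORT_COLUMNS]
    table.to_csv(path, index=False)
    return table


def read_report(path: Union[str, Path]) -> pd.DataFrame:
    """Read a report CSV back into the documented column schema."""
    return pd.read_csv(path)
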