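"""The common trial estimand: treated-minus-control mean at the final visit.

Slope-parameterised models (random slopes, LTFC, FCTFC) constrain the two
arms to share a baseline mean, so the group-mean difference at the final
visit is the treatment slope times follow-up time; the free-trajectories
model estimates the final-visit difference directly.  Expressing every model
on this scale makes their estimates, standard errors and tests comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from scipy import stats as sps

from .mmrm import MarginalFit
from .params import VisitSchedule
from .reml import RandomSlopesFit

__all__ = ["TreatmentEffectEstimate", "final_time_effect"]


@dataclass(frozen=True)
class TreatmentEffectEstimate:
    """Final-visit difference in group means with its Wald test.

    ``statistic = effect_final / se`` referenced against a t distribution
    with ``df`` degrees of freedom; ``reject`` is the two-sided decision at
    level ``alpha``.
    """

    effect_final: float
    se: float
    df: float
    statistic: float
    p_value: float
    reject: bool
    alpha: float
    model_kind: str

    def to_dict(self) -> dict:
        return {
            "model": self.model_kind,
            "effect_final": self.effect_final,
            "se": self.se,
            "df": self.df,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "reject": self.reject,
            "alpha": self.alpha,
        }


def final_time_effect(
    fit: Union[RandomSlopesFit, MarginalFit],
    schedule: VisitSchedule,
    alpha: float = 0.05,
) -> TreatmentEffectEstimate:
    """Convert a converged fit into the final-visit treatment-effect estimand.

    For slope-parameterised models the effect and its SE are the treatment
    slope and SE scaled by the follow-up time (which leaves the Wald
    statistic unchanged); for the free-trajectories model they are the
    final-visit effect and SE directly.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if not fit.converged:
        raise ValueError("cannot extract an estimand from a non-converged fit")
    t_final = schedule.t_final
    if isinstance(fit, RandomSlopesFit):
        if fit.gamma is None:
            raise ValueError("observational fits carry no treatment effect")
        effect = fit.gamma * t_final
        se = fit.se_gamma * t_final
        df = fit.df_gamma if fit.df_gamma is not None else float(fit.n_subjects - 2)
        kind = "rs"
    else:
        kind = fit.model_kind
        if kind == "ftfc":
            effect = fit.gamma
            se = fit.se_gamma
        else:
            effect = fit.gamma * t_final
            se = fit.se_gamma * t_final
        df = fit.df_resid
    if se > 0:
        stat = effect / se
        p = 2.0 * float(sps.t.sf(abs(stat), df))
    else:  # degenerate (noise-free fixtures)
        stat = 0.0 if effect == 0 else float("inf")
        p = 1.0 if effect == 0 else 0.0
    return TreatmentEffectEstimate(
        effect_final=float(effect),
        se=float(se),
        df=float(df),
        statistic=float(stat),
        p_value=p,
        reject=bool(p < alpha),
        alpha=float(alpha),
        model_kind=kind,
    )
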