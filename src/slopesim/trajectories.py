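"""Mean trajectories and treatment-effect shapes for progressive-disease outcomes.

The simulator models a continuous outcome (higher = worse) that declines over
five years.  The control-group mean at time ``t`` is ``6 + 0.2 * f(t)`` where
``f`` is one of four monotone time transforms, calibrated so that every shape
starts at 6.00 and reaches 7.00 at five years (2 dp):

* ``steady``        : f(t) = t                        (linear)
* ``early``         : f(t) = -5 exp(-2 t) + 5         (fast change early on)
* ``late``          : f(t) = exp(2 t) / 4400          (change arrives late)
* ``intermediate``  : f(t) = -5 / (1 + exp(-3 (2.5 - t))) + 5   (sigmoid)

Treatment can act on the mean in three ways (plus a null):

* ``proportional_time``            : treated mean = control + gamma * t
* ``proportional_control_change``  : treated mean = control + gamma * f(t)
* ``delayed_decline``              : treated group is flat for `delay` years
  and then mirrors the control trajectory (steady shape only)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

__all__ = [
    "TrajectoryShape",
    "TreatmentEffectSpec",
    "SHAPES",
    "SHAPE_NAMES",
    "get_shape",
    "f_shape",
    "control_mean",
    "treated_mean",
]

ArrayLike = Union[float, np.ndarray]

#: Baseline mean level shared by every trajectory.
BASELINE_MEAN = 6.0
#: Scale applied to the time transform in the control-group mean.
TREND_SCALE = 0.2


@dataclass(frozen=True)
class TrajectoryShape:
    """A named time transform ``t -> f(t)`` defining the mean trajectory."""

    name: str
    f: Callable[[ArrayLike], ArrayLike] = field(repr=False)

    def __call__(self, t: ArrayLike) -> ArrayLike:
        return self.f(t)


def _f_steady(t: ArrayLike) -> ArrayLike:
    return np.asarray(t, dtype=float) + 0.0


def _f_early(t: ArrayLike) -> ArrayLike:
    t = np.asarray(t, dtype=float)
    return -5.0 * np.exp(-2.0 * t) + 5.0


def _f_late(t: ArrayLike) -> ArrayLike:
    t = np.asarray(t, dtype=float)
    return np.exp(2.0 * t) / 4400.0


def _f_intermediate(t: ArrayLike) -> ArrayLike:
    t = np.asarray(t, dtype=float)
    return -5.0 / (1.0 + np.exp(-3.0 * (2.5 - t))) + 5.0


SHAPES: dict[str, TrajectoryShape] = {
    "steady": TrajectoryShape("steady", _f_steady),
    "early": TrajectoryShape("early", _f_early),
    "late": TrajectoryShape("late", _f_late),
    "intermediate": TrajectoryShape("intermediate", _f_intermediate),
}

#: Canonical ordering of the four shapes (also fixes seed-derivation indices).
SHAPE_NAMES: tuple[str, ...] = ("steady", "early", "late", "intermediate")


def get_shape(shape: Union[str, TrajectoryShape]) -> TrajectoryShape:
    """Resolve a shape name to its :class:`TrajectoryShape`."""
    if isinstance(shape, TrajectoryShape):
        return shape
    try:
        return SHAPES[shape]
    except KeyError:
        raise ValueError(
            f"unknown trajectory shape {shape!r}; expected one of {sorted(SHAPES)}"
        ) from None


EFFECT_KINDS = ("none", "proportional_time", "proportional_control_change", "delayed_decline")


@dataclass(frozen=True)
class TreatmentEffectSpec:
    """How treatment modifies the mean trajectory.

    Parameters
    ----------
    kind
        One of ``none``, ``proportional_time``, ``proportional_control_change``
        or ``delayed_decline``.
    gamma
        Effect rate: outcome/year for ``proportional_time``; multiplier of the
        time transform for ``proportional_control_change``.  Ignored otherwise.
    delay
        Years of flat treated-group trajectory before decline starts
        (``delayed_decline`` only, and only valid with the steady shape).
    """

    kind: str
    gamma: float = 0.0
    delay: float = 0.0

    def __post_init__(self):
        if self.kind not in EFFECT_KINDS:
            raise ValueError(
                f"unknown effect kind {self.kind!r}; expected one of {EFFECT_KINDS}"
            )
        if self.kind == "delayed_decline" and self.delay < 0:
            raise ValueError("delay must be non-negative")

    @classmethod
    def none(cls) -> "TreatmentEffectSpec":
        return cls("none")


def f_shape(shape: Union[str, TrajectoryShape], t: ArrayLike) -> ArrayLike:
    """Evaluate the time transform ``f`` of `shape` at time(s) `t` (years)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = get_shape(shape)(t_arr)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def control_mean(shape: Union[str, TrajectoryShape], t: ArrayLike) -> ArrayLike:
    """Control-group mean outcome at time(s) `t`: ``6 + 0.2 f(t)``."""
    return BASELINE_MEAN + TREND_SCALE * f_shape(shape, t)


def treated_mean(
    shape: Union[str, TrajectoryShape],
    spec: TreatmentEffectSpec,
    t: ArrayLike,
) -> ArrayLike:
    """Treated-group mean outcome at time(s) `t` under effect `spec`."""
    shape = get_shape(shape)
    if spec.kind == "none":
        return control_mean(shape, t)
    if spec.kind == "proportional_time":
        t_arr = np.asarray(t, dtype=float)
        out = control_mean(shape, t_arr) + spec.gamma * t_arr
    elif spec.kind == "proportional_control_change":
        out = control_mean(shape, t) + spec.gamma * f_shape(shape, t)
    elif spec.kind == "delayed_decline":
        if shape.name != "steady":
            raise ValueError("delayed_decline is defined only for the steady shape")
        t_arr = np.asarray(t, dtype=float)
        shifted = np.clip(t_arr - spec.delay, 0.0, None)
        out = BASELINE_MEAN + TREND_SCALE * shifted
    else:  # pragma: no cover - guarded by __post_init__
        raise ValueError(spec.kind)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out
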