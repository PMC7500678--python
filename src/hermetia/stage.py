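"""Development-stage regulation and the combined rate regulators.

The development sum ``T_sum`` (apparent age, hours of suitable conditions)
drives two stage switches: assimilation feeds at full potential until the
milestone ``k_TS1``, ramps down linearly to zero at ``k_TS2`` (mouth-part
degeneration before the non-feeding prepupal instar), while the combined
maturity-and-maintenance flux runs until larval development completes at
``k_TS3``.  Size further throttles ingestion through the von-Bertalanffy
potential ``1 - B_dry / k_B_asy``.

Every switch also has a logistically smoothed variant (slope ``4/width`` at
the ramp midpoint) so the ODE right-hand side stays smooth for the solver;
the piecewise forms are kept for unit-level verification.

The three combined regulators multiply the stage factor with the relevant
environmental factors, each normalized by its own maximum so the product
always lies in [0, 1] regardless of whether the underlying parameter set
is normalized or carries absolute units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .env_rates import _exp, _maybe_scalar
from .exceptions import DomainError, ParameterError
from .state import EnvironmentState

if TYPE_CHECKING:  # pragma: no cover
    from .profiles import ParameterProfile

__all__ = [
    "StageParams",
    "SmoothStep",
    "smooth_step",
    "ingestion_potential",
    "assim_stage_factor",
    "maturity_stage_factor",
    "combined_assim_regulator",
    "combined_mat_regulator",
    "combined_dev_regulator",
]


@dataclass(frozen=True)
class StageParams:
    """Development milestones and size limit.

    Attributes
    ----------
    k_TS1, k_TS2, k_TS3 : float
        Development-sum milestones [h]: feeding starts to cease, feeding
        ends, larval development ends (prepupa -> pupa).
    k_B_asy : float
        Asymptotic dry mass under unlimited feeding [g].
    w_mat : float
        Width of the smoothed maturity switch at ``k_TS3`` [h].  The
        underlying switch is instantaneous; a finite width is needed only
        for the smooth ODE right-hand side.
    """

    k_TS1: float
    k_TS2: float
    k_TS3: float
    k_B_asy: float
    w_mat: float = 10.0

    def __post_init__(self):
        if not (0 < self.k_TS1 < self.k_TS2 < self.k_TS3):
            raise ParameterError(
                "StageParams requires 0 < k_TS1 < k_TS2 < k_TS3, got "
                f"{self.k_TS1} / {self.k_TS2} / {self.k_TS3}"
            )
        if not self.k_B_asy > 0:
            raise ParameterError("StageParams.k_B_asy must be > 0 g")
        if not self.w_mat > 0:
            raise ParameterError("StageParams.w_mat must be > 0 h")

    @property
    def k_TS_inf(self) -> float:
        """Midpoint of the feeding shut-down ramp [h]."""
        return self.k_TS1 + 0.5 * (self.k_TS2 - self.k_TS1)


@dataclass(frozen=True)
class SmoothStep:
    """A logistic 0-1 transition: midpoint ``x0``, slope ``k``, direction."""

    x0: float
    k: float
    direction: str = "ascending"

    def __post_init__(self):
        if not self.k > 0:
            raise ParameterError("SmoothStep.k must be > 0")
        if self.direction not in ("ascending", "descending"):
            raise ParameterError("SmoothStep.direction must be ascending|descending")


def smooth_step(x, s: SmoothStep):
    """Evaluate a logistic step ``1 / (1 + exp(-k (x - x0)))`` (or its mirror)."""
    up = 1.0 / (1.0 + _exp(-s.k * (np.asarray(x, dtype=float) - s.x0)))
    out = up if s.direction == "ascending" else 1.0 - up
    return _maybe_scalar(out, x)


def ingestion_potential(B_dry, p: StageParams):
    """Size-dependent feeding potential ``1 - B_dry / k_B_asy``, floored at 0.

    The floor covers masses beyond the asymptote (possible transiently in a
    fitted or perturbed model) where negative assimilation would be
    biologically meaningless.
    """
    B = np.asarray(B_dry, dtype=float)
    if np.any(B < 0):
        raise DomainError("B_dry must be >= 0 g")
    return _maybe_scalar(np.maximum(0.0, 1.0 - B / p.k_B_asy), B_dry)


def assim_stage_factor(T_sum, B_dry, p: StageParams, smooth: bool = False):
    """Stage- and size-dependent assimilation factor in [0, 1].

    Piecewise: full ingestion potential before ``k_TS1``, linear ramp to
    zero on [k_TS1, k_TS2], zero afterwards.  Smoothed: the potential times
    a descending logistic with midpoint ``k_TS_inf`` and slope
    ``4 / (k_TS2 - k_TS1)``.
    """
    T = np.asarray(T_sum, dtype=float)
    if np.any(T < 0):
        raise DomainError("T_sum must be >= 0 h")
    pot = np.asarray(ingestion_potential(B_dry, p), dtype=float)
    if smooth:
        step = smooth_step(
            T,
            SmoothStep(
                x0=p.k_TS_inf, k=4.0 / (p.k_TS2 - p.k_TS1), direction="descending"
            ),
        )
        out = pot * np.asarray(step)
    else:
        ramp = np.clip((T - p.k_TS2) / (p.k_TS1 - p.k_TS2), 0.0, 1.0)
        out = pot * ramp
    if np.ndim(T_sum) == 0 and np.ndim(B_dry) == 0:
        return float(out)
    return out


def maturity_stage_factor(T_sum, p: StageParams, smooth: bool = False):
    """Maturity-maintenance allocation: 1 before ``k_TS3``, 0 after.

    Pupal metamorphosis would keep consuming reserves at a nonzero rate;
    that stage is outside this model, so the factor simply drops to zero.
    """
    T = np.asarray(T_sum, dtype=float)
    if np.any(T < 0):
        raise DomainError("T_sum must be >= 0 h")
    if smooth:
        out = np.asarray(
            smooth_step(
                T,
                SmoothStep(x0=p.k_TS3, k=4.0 / p.w_mat, direction="descending"),
            )
        )
    else:
        out = np.where(T < p.k_TS3, 1.0, 0.0)
    return _maybe_scalar(out, T_sum)


def combined_assim_regulator(
    T_sum: float,
    B_dry: float,
    env: EnvironmentState,
    profile: "ParameterProfile",
    smooth: bool = True,
) -> float:
    """Assimilation regulator: stage factor times all four normalized
    environmental factors (temperature, feed-growth, moisture, airflow)."""
    return float(
        assim_stage_factor(T_sum, B_dry, profile.stage, smooth=smooth)
        * profile.normalized_temperature_factor(env.T_med)
        * profile.normalized_feed_growth_factor(env.B_feed)
        * profile.normalized_moisture_factor(env.W_med_pct, smooth=smooth)
        * profile.normalized_airflow_factor(env.A_air)
    )


def combined_mat_regulator(
    T_sum: float,
    env: EnvironmentState,
    profile: "ParameterProfile",
    smooth: bool = True,
) -> float:
    """Maturity-maintenance regulator.

    Moisture is deliberately absent: it limits ingestion and gas exchange
    in the substrate, not the internal maintenance metabolism.
    """
    return float(
        maturity_stage_factor(T_sum, profile.stage, smooth=smooth)
        * profile.normalized_temperature_factor(env.T_med)
        * profile.normalized_feed_growth_factor(env.B_feed)
        * profile.normalized_airflow_factor(env.A_air)
    )


def combined_dev_regulator(
    env: EnvironmentState,
    profile: "ParameterProfile",
    smooth: bool = True,
) -> float:
    """Development-rate regulator: all four environmental factors, no stage
    or size dependence (uses the development Monod instance for feed)."""
    return float(
        profile.normalized_temperature_factor(env.T_med)
        * profile.normalized_feed_dev_factor(env.B_feed)
        * profile.normalized_moisture_factor(env.W_med_pct, smooth=smooth)
        * profile.normalized_airflow_factor(env.A_air)
    )
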