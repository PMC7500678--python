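"""Environmental response functions for black soldier fly larval rates.

Each function maps one environmental driver — substrate temperature, feed
density, substrate moisture or airflow — to a development or growth rate.
The temperature responses are an Arrhenius law with low/high boundary
corrections and a modified Logan-10 thermal performance curve whose
high-temperature branch decays to zero instead of going negative.  Feed
and airflow limitation follow Monod (type-II) saturation kinetics; the
moisture response is a product of a piecewise-linear assimilation ramp
and a piecewise-linear respiration shut-off.  All switching shapes also
exist in a logistically smoothed variant so they can sit inside an ODE
right-hand side without kinks.

Rates carry the units of their maximum-rate parameter: several shipped
parameter sets are normalized (dimensionless maxima near 1) because the
fitting workflow operates on rates scaled by their observed maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ParameterError

__all__ = [
    "ArrheniusParams",
    "Logan10Params",
    "MonodParams",
    "MoistureParams",
    "AirflowLogisticParams",
    "arrhenius_rate",
    "logan10_rate",
    "monod_rate",
    "moisture_assim_factor",
    "moisture_resp_factor",
    "moisture_growth_rate",
    "airflow_logistic_rate",
    "smooth_ramp_up",
    "smooth_ramp_down",
]

#: Exponent cap applied before every ``exp`` call; keeps all responses
#: finite for any physically plausible input instead of overflowing.
EXP_CLAMP = 700.0

_ABS_ZERO_C = -273.15


def _exp(x):
    """Exponential with the argument clamped to +-EXP_CLAMP."""
    return np.exp(np.clip(x, -EXP_CLAMP, EXP_CLAMP))


def _maybe_scalar(x, template):
    """Return a python float when the caller passed a scalar."""
    if np.ndim(template) == 0:
        return float(x)
    return x


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius temperature response with boundary corrections.

    Attributes
    ----------
    k_r_ref_T : float
        Rate observed at the reference temperature (normalized or s^-1).
    k_T_A, k_T_AL, k_T_AH : float
        Arrhenius temperatures [K] for the reference response and the
        lower/upper boundary corrections.
    k_T_ref, k_T_L, k_T_H : float
        Reference, lower-boundary and upper-boundary temperatures [K].
    """

    k_r_ref_T: float
    k_T_A: float
    k_T_AL: float
    k_T_AH: float
    k_T_ref: float
    k_T_L: float
    k_T_H: float

    def __post_init__(self):
        for name in ("k_T_A", "k_T_AL", "k_T_AH", "k_T_ref", "k_T_L", "k_T_H"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"ArrheniusParams.{name} must be > 0 K")
        if not (self.k_T_L < self.k_T_ref < self.k_T_H):
            raise ParameterError(
                "ArrheniusParams requires k_T_L < k_T_ref < k_T_H, got "
                f"{self.k_T_L} / {self.k_T_ref} / {self.k_T_H}"
            )
        if self.k_r_ref_T < 0:
            raise ParameterError("ArrheniusParams.k_r_ref_T must be >= 0")


@dataclass(frozen=True)
class Logan10Params:
    """Modified Logan-10 thermal performance curve.

    The classic Logan-10 curve goes negative above the lethal maximum;
    this modified form instead decays smoothly to zero there.  The shape
    parameter ``k_gamma = (k_r_max_T - k_r_base_T) / k_r_base_T`` is
    derived, not stored.
    """

    k_r_max_T: float
    k_r_base_T: float
    k_rho_T: float
    k_T_base: float
    k_T_max: float
    k_dT: float

    def __post_init__(self):
        if self.k_r_base_T <= 0:
            raise ParameterError(
                "Logan10Params.k_r_base_T must be > 0 (k_gamma undefined at 0)"
            )
        if not self.k_r_base_T <= self.k_r_max_T:
            raise ParameterError("Logan10Params requires k_r_base_T <= k_r_max_T")
        if not self.k_T_base < self.k_T_max:
            raise ParameterError("Logan10Params requires k_T_base < k_T_max")
        if not self.k_dT > 0:
            raise ParameterError("Logan10Params.k_dT must be > 0")
        if not self.k_rho_T > 0:
            raise ParameterError("Logan10Params.k_rho_T must be > 0")

    @property
    def k_gamma(self) -> float:
        return (self.k_r_max_T - self.k_r_base_T) / self.k_r_base_T


@dataclass(frozen=True)
class MonodParams:
    """Monod / type-II saturation: ``r_max * x / (x + k_half)``."""

    r_max: float
    k_half: float

    def __post_init__(self):
        if self.r_max < 0:
            raise ParameterError("MonodParams.r_max must be >= 0")
        if not self.k_half > 0:
            raise ParameterError("MonodParams.k_half must be > 0")


@dataclass(frozen=True)
class MoistureParams:
    """Thresholds of the substrate-moisture response [kg water / kg wet feed].

    Growth is zero below ``k_W_med_C1`` (feed too dry to ingest), ramps to
    its maximum at ``k_W_med_C2``, is flat on the optimum plateau up to
    ``k_W_med_C3``, and declines to zero at ``k_W_med_crit`` where oxygen
    diffusion into the substrate ceases.
    """

    k_r_max_W: float
    k_W_med_C1: float
    k_W_med_C2: float
    k_W_med_C3: float
    k_W_med_crit: float

    def __post_init__(self):
        c1, c2, c3, crit = (
            self.k_W_med_C1,
            self.k_W_med_C2,
            self.k_W_med_C3,
            self.k_W_med_crit,
        )
        if not (0 <= c1 < c2 <= c3 < crit <= 1):
            raise ParameterError(
                "MoistureParams requires 0 <= C1 < C2 <= C3 < crit <= 1, got "
                f"{c1} / {c2} / {c3} / {crit}"
            )
        if self.k_r_max_W < 0:
            raise ParameterError("MoistureParams.k_r_max_W must be >= 0")


@dataclass(frozen=True)
class AirflowLogisticParams:
    """Logistic airflow response (alternative to the Monod form).

    The curve is implemented exactly as printed,
    ``r_max / (1 + exp((A - k_A_inf) / k_A_trans))``, which *decreases*
    with airflow when ``k_A_trans > 0``.  Callers wanting the saturating
    (increasing) response reported for closed rearing containers must pass
    a negative ``k_A_trans``; the sign convention is deliberately not
    flipped internally.
    """

    k_r_max_A: float
    k_A_inf: float
    k_A_trans: float

    def __post_init__(self):
        if self.k_A_trans == 0:
            raise ParameterError("AirflowLogisticParams.k_A_trans must be nonzero")
        if self.k_r_max_A < 0:
            raise ParameterError("AirflowLogisticParams.k_r_max_A must be >= 0")


def arrhenius_rate(T_med, p: ArrheniusParams):
    """Arrhenius temperature response with boundary corrections.

    Parameters
    ----------
    T_med : float or array
        Substrate temperature [degC].
    p : ArrheniusParams
        Parameter set (stores its temperatures in K).

    Returns
    -------
    Rate in the units of ``p.k_r_ref_T``; always finite and >= 0.
    """
    T = np.asarray(T_med, dtype=float)
    if np.any(T <= _ABS_ZERO_C):
        raise DomainError("temperature at or below absolute zero")
    T_K = T + 273.15
    num = _exp(p.k_T_A / p.k_T_ref - p.k_T_A / T_K)
    den = (
        1.0
        + _exp(p.k_T_AL / T_K - p.k_T_AL / p.k_T_L)
        + _exp(p.k_T_AH / p.k_T_H - p.k_T_AH / T_K)
    )
    return _maybe_scalar(p.k_r_ref_T * num / den, T_med)


def logan10_rate(T_med, p: Logan10Params):
    """Modified Logan-10 thermal performance curve.

    Non-negative everywhere and decays to zero both below the developmental
    threshold ``k_T_base`` and above the lethal maximum ``k_T_max``.
    """
    T = np.asarray(T_med, dtype=float)
    den = (
        1.0
        + p.k_gamma * _exp(-p.k_rho_T * (T - p.k_T_base))
        + _exp(-(p.k_T_max - T) / p.k_dT)
    )
    return _maybe_scalar(p.k_r_max_T / den, T_med)


def monod_rate(x, p: MonodParams):
    """Monod saturation ``r_max * x / (x + k_half)`` for a resource level x >= 0.

    Evaluated as ``r_max / (1 + k_half/x)`` so the half-saturation identity
    ``monod_rate(k_half) == r_max/2`` holds exactly in floating point.
    """
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise DomainError("Monod driving factor must be >= 0")
    with np.errstate(divide="ignore"):
        out = np.where(xv > 0, p.r_max / (1.0 + p.k_half / np.where(xv > 0, xv, 1.0)), 0.0)
    return _maybe_scalar(out, x)


def smooth_ramp_up(x, lo: float, hi: float):
    """Logistic stand-in for a 0->1 linear ramp on [lo, hi].

    Slope 4/(hi - lo) at the midpoint, matching the ramp's own slope there,
    so the two forms agree at the midpoint exactly and differ by at most
    1/(1+e^2) ~ 0.12 at the ramp endpoints.
    """
    k = 4.0 / (hi - lo)
    x0 = 0.5 * (lo + hi)
    return 1.0 / (1.0 + _exp(-k * (np.asarray(x, dtype=float) - x0)))


def smooth_ramp_down(x, lo: float, hi: float):
    """Logistic stand-in for a 1->0 linear ramp on [lo, hi]."""
    return 1.0 - smooth_ramp_up(x, lo, hi)


def _check_moisture_domain(W):
    Wv = np.asarray(W, dtype=float)
    if np.any((Wv < 0) | (Wv > 1)):
        raise DomainError("moisture must lie in [0, 1] kg/kg wet basis")
    return Wv


def moisture_assim_factor(W, p: MoistureParams, smooth: bool = False):
    """Assimilation factor vs moisture: 0 below C1, ramp to 1 at C2."""
    Wv = _check_moisture_domain(W)
    if smooth:
        out = smooth_ramp_up(Wv, p.k_W_med_C1, p.k_W_med_C2)
    else:
        out = np.clip(
            (Wv - p.k_W_med_C1) / (p.k_W_med_C2 - p.k_W_med_C1), 0.0, 1.0
        )
    return _maybe_scalar(out, W)


def moisture_resp_factor(W, p: MoistureParams, smooth: bool = False):
    """Respiration factor vs moisture: 1 below C3, declining to 0 at crit."""
    Wv = _check_moisture_domain(W)
    if smooth:
        out = smooth_ramp_down(Wv, p.k_W_med_C3, p.k_W_med_crit)
    else:
        out = np.clip(
            (Wv - p.k_W_med_crit) / (p.k_W_med_C3 - p.k_W_med_crit), 0.0, 1.0
        )
    return _maybe_scalar(out, W)


def moisture_growth_rate(W, p: MoistureParams, smooth: bool = False):
    """Moisture-limited growth rate: ``k_r_max_W`` times both factors."""
    out = (
        p.k_r_max_W
        * np.asarray(moisture_assim_factor(W, p, smooth=smooth))
        * np.asarray(moisture_resp_factor(W, p, smooth=smooth))
    )
    return _maybe_scalar(out, W)


def airflow_logistic_rate(A, p: AirflowLogisticParams):
    """Logistic airflow response, exactly as parameterized (see params doc)."""
    Av = np.asarray(A, dtype=float)
    if np.any(Av < 0):
        raise DomainError("airflow must be >= 0")
    out = p.k_r_max_A / (1.0 + _exp((Av - p.k_A_inf) / p.k_A_trans))
    return _maybe_scalar(out, A)
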