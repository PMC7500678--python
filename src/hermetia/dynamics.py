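"""Two-state growth/development ODE, flux partitioning, and simulation.

The larva is described by its dry mass ``B_dry`` [g] and the development
sum ``T_sum`` [h] (apparent age: hours of optimal growing conditions
accumulated).  Their dynamics are

    dB_dry/dt = eps_inges * r_assim * k_inges * B_dry
                - r_mat * k_maint * B_dry                     [g / s]
    dT_sum/dt = r_dev * k_dev_ts                              [h / s]

with the regulators ``r_assim``, ``r_mat`` and ``r_dev`` in [0, 1]
combining the development-stage switches and the normalized environmental
factors.  Internally everything runs in seconds (the specific rates carry
s^-1 units); the public API uses hours.

Mass bookkeeping follows a mass-balance partition of the ingested feed
flux into excreted, digestion-cost, and effective fractions; the effective
flux feeds growth while a combined maturity-and-maintenance flux drains
structure.  Substrate depletion is not simulated — feed availability is an
exogenous driver, and the flux series lets callers do their own substrate
bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .exceptions import IntegrationError, ParameterError
from .stage import (
    StageParams,
    combined_assim_regulator,
    combined_dev_regulator,
    combined_mat_regulator,
)
from .state import EnvironmentSchedule, EnvironmentState, LarvaState

__all__ = [
    "GrowthParams",
    "FluxBreakdown",
    "Trajectory",
    "growth_rhs",
    "flux_partition",
    "simulate",
    "detect_stage_events",
]

SECONDS_PER_HOUR = 3600.0

FLUX_NAMES = (
    "phi_B_ing",
    "phi_B_excr",
    "phi_B_assim",
    "phi_B_eff",
    "phi_B_mat_maint",
    "phi_B_metab",
)


@dataclass(frozen=True)
class GrowthParams:
    """Specific rates and partition fractions of the mass balance.

    Attributes
    ----------
    k_inges : float
        Specific maximum ingestion rate [g feed / g larva / s].
    k_maint : float
        Specific maximum combined maturity-and-maintenance rate [g/g/s].
    eps_inges : float
        Digestion efficiency of the ingested feed [-].  Stored as an
        independent parameter; set ``eps_mode='derived'`` to force the
        strict mass-balance identity ``1 - k_alpha_excr - k_alpha_assim``
        instead (the two disagree in the shipped estimates: 0.79 vs 0.2103,
        an inconsistency inherited from the source estimates).
    k_alpha_excr, k_alpha_assim : float
        Fractions of the ingested flux excreted undigested and spent on
        digestion itself [-].
    k_dev_ts : float
        Maximum apparent-age rate [h of development sum per s of real
        time].  The default 1/3600 advances apparent age one hour per real
        hour under optimal conditions.
    """

    k_inges: float
    k_maint: float
    eps_inges: float = 0.79
    k_alpha_excr: float = 0.5762
    k_alpha_assim: float = 0.2135
    k_dev_ts: float = 1.0 / SECONDS_PER_HOUR
    eps_mode: str = "independent"

    def __post_init__(self):
        if not (self.k_inges > 0 and self.k_maint > 0):
            raise ParameterError("GrowthParams.k_inges and k_maint must be > 0")
        if not (0 < self.eps_inges <= 1):
            raise ParameterError("GrowthParams.eps_inges must be in (0, 1]")
        if self.k_alpha_excr < 0 or self.k_alpha_assim < 0:
            raise ParameterError("GrowthParams partition fractions must be >= 0")
        if self.k_alpha_excr + self.k_alpha_assim > 1:
            raise ParameterError(
                "GrowthParams requires k_alpha_excr + k_alpha_assim <= 1"
            )
        if not self.k_dev_ts > 0:
            raise ParameterError("GrowthParams.k_dev_ts must be > 0")
        if self.eps_mode not in ("independent", "derived"):
            raise ParameterError("GrowthParams.eps_mode must be independent|derived")

    @property
    def effective_eps(self) -> float:
        """Digestion efficiency actually used in the growth equation."""
        if self.eps_mode == "derived":
            return 1.0 - self.k_alpha_excr - self.k_alpha_assim
        return self.eps_inges


@dataclass(frozen=True)
class FluxBreakdown:
    """Instantaneous mass fluxes [g/s] of the feed partition."""

    phi_B_ing: float
    phi_B_excr: float
    phi_B_assim: float
    phi_B_eff: float
    phi_B_mat_maint: float
    phi_B_metab: float

    def as_tuple(self):
        return tuple(getattr(self, n) for n in FLUX_NAMES)


@dataclass
class Trajectory:
    """A simulated time course with regulators, fluxes, and stage events."""

    time_h: np.ndarray
    B_dry_g: np.ndarray
    T_sum_h: np.ndarray
    r_assim: Optional[np.ndarray] = None
    r_mat: Optional[np.ndarray] = None
    r_dev: Optional[np.ndarray] = None
    fluxes: Optional[dict] = None
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time_h)
        if len(self.B_dry_g) != n or len(self.T_sum_h) != n:
            raise ParameterError("Trajectory series must share one time grid")

    def state_at_index(self, i: int) -> LarvaState:
        return LarvaState(B_dry=float(self.B_dry_g[i]), T_sum=float(self.T_sum_h[i]))

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: time_h, B_dry_g, T_sum_h, regulators, fluxes."""
        data = {
            "time_h": self.time_h,
            "B_dry_g": self.B_dry_g,
            "T_sum_h": self.T_sum_h,
        }
        for name in ("r_assim", "r_mat", "r_dev"):
            series = getattr(self, name)
            if series is not None:
                data[name] = series
        if self.fluxes is not None:
            for name in FLUX_NAMES:
                data[name] = self.fluxes[name]
        return pd.DataFrame(data)

    def events_frame(self) -> pd.DataFrame:
        rows = [
            {"event": k, "value": v}
            for k, v in self.events.items()
            if v is not None
        ]
        return pd.DataFrame(rows, columns=["event", "value"])


def growth_rhs(
    state: LarvaState,
    env: EnvironmentState,
    profile,
    smooth: bool = True,
) -> tuple[float, float]:
    """Right-hand side of the ODE: (dB_dry/dt [g/s], dT_sum/dt [h/s])."""
    g: GrowthParams = profile.growth
    r_assim = combined_assim_regulator(state.T_sum, state.B_dry, env, profile, smooth)
    r_mat = combined_mat_regulator(state.T_sum, env, profile, smooth)
    r_dev = combined_dev_regulator(env, profile, smooth)
    dB = (
        g.effective_eps * r_assim * g.k_inges * state.B_dry
        - r_mat * g.k_maint * state.B_dry
    )
    dT = r_dev * g.k_dev_ts
    return float(dB), float(dT)


def flux_partition(
    state: LarvaState,
    env: EnvironmentState,
    profile,
    smooth: bool = True,
) -> FluxBreakdown:
    """Partition of the ingested feed flux at the given state/environment.

    The effective fraction always uses the mass-balance identity
    ``1 - k_alpha_excr - k_alpha_assim`` so ingestion is conserved exactly:
    ``phi_ing = phi_excr + phi_assim + phi_eff``.
    """
    g: GrowthParams = profile.growth
    r_assim = combined_assim_regulator(state.T_sum, state.B_dry, env, profile, smooth)
    r_mat = combined_mat_regulator(state.T_sum, env, profile, smooth)
    phi_ing = r_assim * g.k_inges * state.B_dry
    phi_excr = g.k_alpha_excr * phi_ing
    phi_assim = g.k_alpha_assim * phi_ing
    phi_eff = (1.0 - g.k_alpha_excr - g.k_alpha_assim) * phi_ing
    phi_mat_maint = r_mat * g.k_maint * state.B_dry
    return FluxBreakdown(
        phi_B_ing=phi_ing,
        phi_B_excr=phi_excr,
        phi_B_assim=phi_assim,
        phi_B_eff=phi_eff,
        phi_B_mat_maint=phi_mat_maint,
        phi_B_metab=phi_assim + phi_mat_maint,
    )


def _segment_env_products(profile, env: EnvironmentState, smooth: bool):
    """Constant environmental products for one hold segment.

    Returns (E_assim, E_mat, E_dev): the products of normalized
    environmental factors entering each regulator, excluding the
    stage-dependent factors which vary within a segment.
    """
    f_T = profile.normalized_temperature_factor(env.T_med)
    f_grw = profile.normalized_feed_growth_factor(env.B_feed)
    f_dev = profile.normalized_feed_dev_factor(env.B_feed)
    f_W = profile.normalized_moisture_factor(env.W_med_pct, smooth=smooth)
    f_A = profile.normalized_airflow_factor(env.A_air)
    return f_T * f_grw * f_W * f_A, f_T * f_grw * f_A, f_T * f_dev * f_W * f_A


def _make_segment_rhs(
    profile,
    env_products: tuple[float, float, float],
    override: Optional[tuple[float, float, float]],
) -> Callable:
    """Fast scalar RHS for one constant-environment segment (time in s)."""
    g: GrowthParams = profile.growth
    sp: StageParams = profile.stage
    a = g.effective_eps * g.k_inges
    m = g.k_maint
    kdev = g.k_dev_ts
    exp = math.exp

    if override is not None:
        r_a, r_m, r_d = override

        def rhs(t, y):
            B = y[0]
            return (a * r_a * B - m * r_m * B, kdev * r_d)

        return rhs

    E_assim, E_mat, E_dev = env_products
    inv_basy = 1.0 / sp.k_B_asy
    k_sa = 4.0 / (sp.k_TS2 - sp.k_TS1)
    x_sa = sp.k_TS_inf
    k_sm = 4.0 / sp.w_mat
    x_sm = sp.k_TS3

    def rhs(t, y):
        B, T = y
        pot = 1.0 - B * inv_basy
        if pot < 0.0:
            pot = 0.0
        za = k_sa * (T - x_sa)
        sa = 1.0 / (1.0 + exp(za if za < 700.0 else 700.0))
        zm = k_sm * (T - x_sm)
        sm = 1.0 / (1.0 + exp(zm if zm < 700.0 else 700.0))
        dB = a * E_assim * pot * sa * B - m * E_mat * sm * B
        return (dB, kdev * E_dev)

    return rhs


def simulate(
    initial: LarvaState,
    schedule: EnvironmentSchedule,
    profile,
    t_end_h: float,
    *,
    t_eval_h: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "RK45",
    grid_step_h: float = 0.5,
    regulator_override: Optional[tuple[float, float, float]] = None,
    record: str = "full",
) -> Trajectory:
    """Integrate the growth/development ODE over a time-varying environment.

    Parameters
    ----------
    initial : LarvaState
        State at t = 0 (dry mass [g], development sum [h]).
    schedule : EnvironmentSchedule
        Environmental drivers over time; held constant outside its span.
    profile : ParameterProfile
        Full parameter set (rate models, stage milestones, growth rates).
    t_end_h : float
        End of the simulation [h].
    t_eval_h : sequence of float, optional
        Output grid [h]; defaults to a uniform grid of ``grid_step_h``.
    rtol, atol : float
        Solver tolerances.  The defaults (1e-8, 1e-12 g) resolve the
        regulator products, which span orders of magnitude near switches.
    method : str
        Any adaptive ``scipy.integrate.solve_ivp`` method; default RK45.
    regulator_override : (r_assim, r_mat, r_dev), optional
        Constant regulators replacing the full model — used for analytic
        verification against the closed-form exponential solution.
    record : {'full', 'states'}
        'full' also evaluates regulator and flux series on the output grid;
        'states' records only (B_dry, T_sum), which is what fitting needs.

    Returns
    -------
    Trajectory
        Time courses plus milestone-crossing and peak-mass events.

    Notes
    -----
    Integration runs segment-by-segment between schedule breakpoints (the
    environment is piecewise constant under hold interpolation), always
    with the smoothed regulators.  Milestone crossings of the development
    sum are located by the solver's root finder on its dense output.
    """
    if not t_end_h > 0:
        raise ParameterError("t_end_h must be > 0")
    if record not in ("full", "states"):
        raise ParameterError("record must be 'full' or 'states'")

    if t_eval_h is None:
        n = max(2, int(round(t_end_h / grid_step_h)) + 1)
        grid_h = np.linspace(0.0, t_end_h, n)
    else:
        grid_h = np.asarray(t_eval_h, dtype=float)
        if grid_h.ndim != 1 or grid_h.size < 1:
            raise ParameterError("t_eval_h must be a 1-D, non-empty sequence")
        if np.any(np.diff(grid_h) <= 0):
            raise ParameterError("t_eval_h must be strictly increasing")
        if grid_h[0] < 0 or grid_h[-1] > t_end_h:
            raise ParameterError("t_eval_h must lie within [0, t_end_h]")

    sp: StageParams = profile.stage
    milestones = {"k_TS1": sp.k_TS1, "k_TS2": sp.k_TS2, "k_TS3": sp.k_TS3}

    # Segment boundaries: schedule switch points inside (0, t_end).
    if schedule.interpolation == "hold":
        inner = schedule.breakpoints_within(0.0, t_end_h)
    else:
        inner = np.array([])
    seg_edges_h = np.concatenate(([0.0], inner, [t_end_h]))

    t_out: list[np.ndarray] = []
    y_out: list[np.ndarray] = []
    crossings: dict[str, Optional[float]] = {k: None for k in milestones}

    y0 = np.array([initial.B_dry, initial.T_sum], dtype=float)
    use_linear = schedule.interpolation == "linear"

    for t0_h, t1_h in zip(seg_edges_h[:-1], seg_edges_h[1:]):
        if use_linear:
            # Environment varies within the segment: evaluate it per call.
            def rhs(t, y, _s=schedule, _p=profile, _ov=regulator_override):
                env = _s.at(t / SECONDS_PER_HOUR)
                st = LarvaState(B_dry=max(y[0], 0.0), T_sum=max(y[1], 0.0))
                if _ov is not None:
                    g = _p.growth
                    return (
                        g.effective_eps * _ov[0] * g.k_inges * y[0]
                        - _ov[1] * g.k_maint * y[0],
                        _ov[2] * g.k_dev_ts,
                    )
                return growth_rhs(st, env, _p, smooth=True)
        else:
            env = schedule.at(0.5 * (t0_h + t1_h))
            products = (
                None
                if regulator_override is not None
                else _segment_env_products(profile, env, smooth=True)
            )
            rhs = _make_segment_rhs(profile, products, regulator_override)

        events = []
        for key, thresh in milestones.items():
            def ev(t, y, _th=thresh):
                return y[1] - _th

            ev.direction = 1.0
            ev.terminal = False
            events.append((key, ev))

        mask = (grid_h >= t0_h) & (grid_h <= t1_h)
        seg_eval = np.unique(np.concatenate((grid_h[mask], [t0_h, t1_h])))
        sol = solve_ivp(
            rhs,
            (t0_h * SECONDS_PER_HOUR, t1_h * SECONDS_PER_HOUR),
            y0,
            method=method,
            t_eval=seg_eval * SECONDS_PER_HOUR,
            events=[e for _, e in events],
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE solver failed in [{t0_h}, {t1_h}] h: {sol.message}; "
                f"last state B_dry={y0[0]:.6g} g, T_sum={y0[1]:.6g} h"
            )
        if not np.all(np.isfinite(sol.y)):
            raise IntegrationError("non-finite state encountered during integration")
        for (key, _), t_ev in zip(events, sol.t_events):
            if t_ev.size and crossings[key] is None:
                crossings[key] = float(t_ev[0]) / SECONDS_PER_HOUR
        keep = np.isin(sol.t, grid_h[mask] * SECONDS_PER_HOUR)
        t_out.append(sol.t[keep] / SECONDS_PER_HOUR)
        y_out.append(sol.y[:, keep])
        y0 = sol.y[:, -1].copy()

    t_all = np.concatenate(t_out)
    y_all = np.concatenate(y_out, axis=1)
    # Deduplicate segment-boundary points shared by adjacent segments.
    t_all, idx = np.unique(t_all, return_index=True)
    y_all = y_all[:, idx]

    B = np.maximum(y_all[0], 0.0)
    T_sum = np.maximum.accumulate(np.maximum(y_all[1], 0.0))

    events_dict: dict = {f"{k}_crossing_h": v for k, v in crossings.items()}
    i_peak = int(np.argmax(B))
    events_dict["peak_time_h"] = float(t_all[i_peak])
    events_dict["peak_B_dry_g"] = float(B[i_peak])

    traj = Trajectory(
        time_h=t_all, B_dry_g=B, T_sum_h=T_sum, events=events_dict
    )
    if record == "full":
        _attach_diagnostics(traj, schedule, profile, regulator_override)
    return traj


def _attach_diagnostics(
    traj: Trajectory,
    schedule: EnvironmentSchedule,
    profile,
    override: Optional[tuple[float, float, float]],
) -> None:
    """Evaluate regulator and flux series on the trajectory grid."""
    n = len(traj.time_h)
    r_a = np.empty(n)
    r_m = np.empty(n)
    r_d = np.empty(n)
    flux = {name: np.empty(n) for name in FLUX_NAMES}
    for i in range(n):
        st = traj.state_at_index(i)
        env = schedule.at(traj.time_h[i])
        if override is not None:
            r_a[i], r_m[i], r_d[i] = override
        else:
            r_a[i] = combined_assim_regulator(st.T_sum, st.B_dry, env, profile, True)
            r_m[i] = combined_mat_regulator(st.T_sum, env, profile, True)
            r_d[i] = combined_dev_regulator(env, profile, True)
        g = profile.growth
        phi_ing = r_a[i] * g.k_inges * st.B_dry
        flux["phi_B_ing"][i] = phi_ing
        flux["phi_B_excr"][i] = g.k_alpha_excr * phi_ing
        flux["phi_B_assim"][i] = g.k_alpha_assim * phi_ing
        flux["phi_B_eff"][i] = (1.0 - g.k_alpha_excr - g.k_alpha_assim) * phi_ing
        flux["phi_B_mat_maint"][i] = r_m[i] * g.k_maint * st.B_dry
        flux["phi_B_metab"][i] = flux["phi_B_assim"][i] + flux["phi_B_mat_maint"][i]
    traj.r_assim, traj.r_mat, traj.r_dev = r_a, r_m, r_d
    traj.fluxes = flux


def detect_stage_events(traj: Trajectory, p: StageParams) -> pd.DataFrame:
    """Locate milestone crossings and the dry-mass peak on a trajectory.

    Crossing times of ``T_sum`` through each milestone are found by root
    bracketing on a monotone (PCHIP) interpolant of the recorded series,
    well below 0.01 h resolution on any reasonable output grid.  Absent
    crossings (milestone not reached) are omitted from the table.
    """
    t, T = traj.time_h, traj.T_sum_h
    rows = []
    interp = PchipInterpolator(t, T) if len(t) >= 2 else None
    for name, thresh in (
        ("k_TS1", p.k_TS1),
        ("k_TS2", p.k_TS2),
        ("k_TS3", p.k_TS3),
    ):
        if interp is None or T[0] > thresh or T[-1] < thresh:
            continue
        if T[0] == thresh:
            t_cross = float(t[0])
        else:
            t_cross = float(brentq(lambda x: interp(x) - thresh, t[0], t[-1]))
        rows.append({"event": f"{name}_crossing_h", "value": t_cross})
    i_peak = int(np.argmax(traj.B_dry_g))
    rows.append({"event": "peak_time_h", "value": float(t[i_peak])})
    rows.append({"event": "peak_B_dry_g", "value": float(traj.B_dry_g[i_peak])})
    return pd.DataFrame(rows, columns=["event", "value"])
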