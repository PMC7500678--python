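"""Core state containers: larva state, environment state, environment schedule."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DomainError, ParameterError

__all__ = ["LarvaState", "EnvironmentState", "EnvironmentSchedule"]


@dataclass(frozen=True)
class LarvaState:
    """Instantaneous state of one larva.

    Attributes
    ----------
    B_dry : float
        Dry mass per larva [g].
    T_sum : float
        Development sum ("apparent age"): hours of optimal growing
        conditions accumulated since hatching [h].
    """

    B_dry: float
    T_sum: float = 0.0

    def __post_init__(self):
        if self.B_dry < 0:
            raise DomainError("LarvaState.B_dry must be >= 0 g")
        if self.T_sum < 0:
            raise DomainError("LarvaState.T_sum must be >= 0 h")


@dataclass(frozen=True)
class EnvironmentState:
    """The four environmental drivers of larval growth and development.

    Attributes
    ----------
    T_med : float
        Substrate temperature [degC].
    B_feed : float
        Feed availability [g dry feed per larva per day].
    W_med_pct : float
        Substrate moisture [kg water per kg wet substrate], in [0, 1].
    A_air : float
        Airflow rate into the rearing unit [l / min].
    """

    T_med: float
    B_feed: float
    W_med_pct: float
    A_air: float

    def __post_init__(self):
        if not 0.0 <= self.W_med_pct <= 1.0:
            raise DomainError("EnvironmentState.W_med_pct must lie in [0, 1]")
        if self.B_feed < 0:
            raise DomainError("EnvironmentState.B_feed must be >= 0")
        if self.A_air < 0:
            raise DomainError("EnvironmentState.A_air must be >= 0")


class EnvironmentSchedule:
    """Time-stamped sequence of environment states, held constant between samples.

    Times are in hours and must be strictly increasing.  Evaluation uses
    zero-order hold by default (rearing experiments hold conditions constant
    between interventions); linear interpolation of the numeric drivers is
    available via ``interpolation='linear'``.
    """

    def __init__(
        self,
        times_h: Sequence[float],
        states: Sequence[EnvironmentState],
        interpolation: str = "hold",
    ):
        times = np.asarray(times_h, dtype=float)
        if times.size == 0:
            raise ParameterError("EnvironmentSchedule must be non-empty")
        if len(states) != times.size:
            raise ParameterError("times and states must have equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ParameterError("schedule times must be strictly increasing")
        if interpolation not in ("hold", "linear"):
            raise ParameterError("interpolation must be 'hold' or 'linear'")
        self.times_h = times
        self.states = list(states)
        self.interpolation = interpolation

    @classmethod
    def constant(cls, env: EnvironmentState) -> "EnvironmentSchedule":
        """A schedule holding a single environment forever."""
        return cls([0.0], [env])

    def __len__(self) -> int:
        return len(self.states)

    def at(self, t_h: float) -> EnvironmentState:
        """Environment at time ``t_h`` [h], extrapolated by hold at both ends."""
        times = self.times_h
        if t_h <= times[0]:
            return self.states[0]
        if t_h >= times[-1]:
            return self.states[-1]
        idx = int(np.searchsorted(times, t_h, side="right") - 1)
        if self.interpolation == "hold":
            return self.states[idx]
        t0, t1 = times[idx], times[idx + 1]
        w = (t_h - t0) / (t1 - t0)
        a, b = self.states[idx], self.states[idx + 1]
        return EnvironmentState(
            T_med=a.T_med + w * (b.T_med - a.T_med),
            B_feed=a.B_feed + w * (b.B_feed - a.B_feed),
            W_med_pct=a.W_med_pct + w * (b.W_med_pct - a.W_med_pct),
            A_air=a.A_air + w * (b.A_air - a.A_air),
        )

    def breakpoints_within(self, t0_h: float, t1_h: float) -> np.ndarray:
        """Schedule switch times strictly inside (t0_h, t1_h); used by the solver."""
        t = self.times_h
        return t[(t > t0_h) & (t < t1_h)]
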