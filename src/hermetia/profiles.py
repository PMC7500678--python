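"""Parameter profiles: bundles of every rate-model, stage, and growth constant.

Two profiles ship with the package.  ``table3_original`` carries the
published estimates obtained from the aggregated literature datasets;
``table3_recalibrated_D1D5`` differs only in the two feed half-saturation
constants, which were re-estimated on a subset of the dry-mass trajectory
data after a feed-type change (the re-estimation procedure itself is
implemented in :mod:`hermetia.estimation`).

Several rate maxima in the shipped profiles are normalized (dimensionless,
near 1) because fitting operated on rates scaled by their observed maximum.
The combined regulators always divide each factor by its own maximum, so
normalized and absolute parameter sets behave identically in the dynamics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .dynamics import GrowthParams
from .env_rates import (
    AirflowLogisticParams,
    ArrheniusParams,
    Logan10Params,
    MonodParams,
    MoistureParams,
    airflow_logistic_rate,
    arrhenius_rate,
    logan10_rate,
    moisture_growth_rate,
    monod_rate,
)
from .exceptions import ParameterError
from .stage import StageParams

__all__ = [
    "ParameterProfile",
    "builtin_profile",
    "BUILTIN_PROFILE_NAMES",
    "SYMBOL_MAP",
]

# Canonical symbol -> (component attribute, field name).  This is the
# single place where the flat parameter vocabulary used in profile files,
# fitting masks and the CLI is tied to the nested dataclasses.
SYMBOL_MAP: dict[str, tuple[str, str]] = {
    "k_r_ref_T": ("arrhenius", "k_r_ref_T"),
    "k_T_A": ("arrhenius", "k_T_A"),
    "k_T_AL": ("arrhenius", "k_T_AL"),
    "k_T_AH": ("arrhenius", "k_T_AH"),
    "k_T_ref": ("arrhenius", "k_T_ref"),
    "k_T_L": ("arrhenius", "k_T_L"),
    "k_T_H": ("arrhenius", "k_T_H"),
    "k_r_max_T": ("logan10", "k_r_max_T"),
    "k_r_base_T": ("logan10", "k_r_base_T"),
    "k_rho_T": ("logan10", "k_rho_T"),
    "k_T_base": ("logan10", "k_T_base"),
    "k_T_max": ("logan10", "k_T_max"),
    "k_dT": ("logan10", "k_dT"),
    "k_r_max_dm": ("monod_dev", "r_max"),
    "k_B_half_dm": ("monod_dev", "k_half"),
    "k_r_max_gm": ("monod_grw", "r_max"),
    "k_B_half_gm": ("monod_grw", "k_half"),
    "k_r_max_W": ("moisture", "k_r_max_W"),
    "k_W_med_C1": ("moisture", "k_W_med_C1"),
    "k_W_med_C2": ("moisture", "k_W_med_C2"),
    "k_W_med_C3": ("moisture", "k_W_med_C3"),
    "k_W_med_crit": ("moisture", "k_W_med_crit"),
    "k_r_max_A": ("airflow_monod", "r_max"),
    "k_A_half": ("airflow_monod", "k_half"),
    "k_A_inf": ("airflow_logistic", "k_A_inf"),
    "k_A_trans": ("airflow_logistic", "k_A_trans"),
    "k_TS1": ("stage", "k_TS1"),
    "k_TS2": ("stage", "k_TS2"),
    "k_TS3": ("stage", "k_TS3"),
    "k_B_asy": ("stage", "k_B_asy"),
    "w_mat": ("stage", "w_mat"),
    "k_inges": ("growth", "k_inges"),
    "k_maint": ("growth", "k_maint"),
    "eps_inges": ("growth", "eps_inges"),
    "k_alpha_excr": ("growth", "k_alpha_excr"),
    "k_alpha_assim": ("growth", "k_alpha_assim"),
    "k_dev_ts": ("growth", "k_dev_ts"),
}


@dataclass
class ParameterProfile:
    """Named bundle of all model parameters.

    ``temperature_model`` selects which thermal response drives the
    regulators ('logan10' or 'arrhenius'); ``airflow_model`` selects
    'monod' (default: the form with published estimates) or 'logistic'.
    ``normalized_flags`` records, per rate instance, whether its maximum
    is a normalized (dimensionless) value; it is informational only,
    because regulators divide by the maximum either way.
    """

    name: str
    arrhenius: ArrheniusParams
    logan10: Logan10Params
    monod_dev: MonodParams
    monod_grw: MonodParams
    moisture: MoistureParams
    airflow_monod: MonodParams
    stage: StageParams
    growth: GrowthParams
    airflow_logistic: Optional[AirflowLogisticParams] = None
    temperature_model: str = "logan10"
    airflow_model: str = "monod"
    normalized_flags: dict = field(
        default_factory=lambda: {
            "temperature": True,
            "monod_dev": True,
            "monod_grw": True,
            "moisture": True,
            "airflow": True,
        }
    )
    notes: str = ""

    def __post_init__(self):
        if self.temperature_model not in ("logan10", "arrhenius"):
            raise ParameterError("temperature_model must be logan10|arrhenius")
        if self.airflow_model not in ("monod", "logistic"):
            raise ParameterError("airflow_model must be monod|logistic")
        if self.airflow_model == "logistic" and self.airflow_logistic is None:
            raise ParameterError(
                "airflow_model='logistic' requires airflow_logistic parameters"
            )
        self._arrhenius_max_cache: Optional[float] = None

    # -- normalized environmental factors (each in [0, 1]) ----------------

    def _arrhenius_max(self) -> float:
        """Numeric maximum of the Arrhenius response over [-20, 80] degC.

        The boundary-corrected Arrhenius curve peaks above its reference
        value, so normalization by ``k_r_ref_T`` alone would exceed 1;
        the true curve maximum (cached) is used instead.
        """
        if self._arrhenius_max_cache is None:
            res = minimize_scalar(
                lambda T: -arrhenius_rate(T, self.arrhenius),
                bounds=(-20.0, 80.0),
                method="bounded",
                options={"xatol": 1e-8},
            )
            self._arrhenius_max_cache = float(-res.fun)
        return self._arrhenius_max_cache

    def normalized_temperature_factor(self, T_med):
        if self.temperature_model == "logan10":
            r_max = self.logan10.k_r_max_T
            if r_max == 0:
                raise ParameterError("logan10 k_r_max_T must be > 0 in regulators")
            return logan10_rate(T_med, self.logan10) / r_max
        r_max = self._arrhenius_max()
        if r_max == 0:
            raise ParameterError("arrhenius response is identically zero")
        return np.minimum(1.0, arrhenius_rate(T_med, self.arrhenius) / r_max)

    def normalized_feed_dev_factor(self, B_feed):
        if self.monod_dev.r_max == 0:
            raise ParameterError("monod_dev r_max must be > 0 in regulators")
        return monod_rate(B_feed, self.monod_dev) / self.monod_dev.r_max

    def normalized_feed_growth_factor(self, B_feed):
        if self.monod_grw.r_max == 0:
            raise ParameterError("monod_grw r_max must be > 0 in regulators")
        return monod_rate(B_feed, self.monod_grw) / self.monod_grw.r_max

    def normalized_moisture_factor(self, W, smooth: bool = True):
        if self.moisture.k_r_max_W == 0:
            raise ParameterError("moisture k_r_max_W must be > 0 in regulators")
        return (
            moisture_growth_rate(W, self.moisture, smooth=smooth)
            / self.moisture.k_r_max_W
        )

    def normalized_airflow_factor(self, A):
        if self.airflow_model == "monod":
            if self.airflow_monod.r_max == 0:
                raise ParameterError("airflow_monod r_max must be > 0 in regulators")
            return monod_rate(A, self.airflow_monod) / self.airflow_monod.r_max
        p = self.airflow_logistic
        if p.k_r_max_A == 0:
            raise ParameterError("airflow_logistic k_r_max_A must be > 0")
        return airflow_logistic_rate(A, p) / p.k_r_max_A

    # -- flat symbol access ------------------------------------------------

    def get(self, symbol: str) -> float:
        """Value of a parameter by its canonical symbol (e.g. 'k_B_half_gm')."""
        try:
            comp, fld = SYMBOL_MAP[symbol]
        except KeyError:
            raise ParameterError(f"unknown parameter symbol: {symbol!r}") from None
        obj = getattr(self, comp)
        if obj is None:
            raise ParameterError(f"profile {self.name!r} has no {comp} component")
        return getattr(obj, fld)

    def with_updates(self, updates: dict[str, float], name: Optional[str] = None):
        """A new profile with the given symbol -> value changes applied.

        All component invariants are re-validated; untouched parameters are
        carried over bit-identically.
        """
        by_comp: dict[str, dict[str, float]] = {}
        for symbol, value in updates.items():
            if symbol not in SYMBOL_MAP:
                raise ParameterError(f"unknown parameter symbol: {symbol!r}")
            comp, fld = SYMBOL_MAP[symbol]
            by_comp.setdefault(comp, {})[fld] = float(value)
        kwargs = {}
        for comp, changes in by_comp.items():
            obj = getattr(self, comp)
            if obj is None:
                raise ParameterError(f"profile {self.name!r} has no {comp} component")
            kwargs[comp] = dataclasses.replace(obj, **changes)
        out = dataclasses.replace(self, **kwargs)
        out.name = name if name is not None else self.name
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def comp_dict(obj):
            return None if obj is None else dataclasses.asdict(obj)

        return {
            "name": self.name,
            "notes": self.notes,
            "temperature_model": self.temperature_model,
            "airflow_model": self.airflow_model,
            "normalized_flags": dict(self.normalized_flags),
            "arrhenius": comp_dict(self.arrhenius),
            "logan10": comp_dict(self.logan10),
            "monod_dev": comp_dict(self.monod_dev),
            "monod_grw": comp_dict(self.monod_grw),
            "moisture": comp_dict(self.moisture),
            "airflow_monod": comp_dict(self.airflow_monod),
            "airflow_logistic": comp_dict(self.airflow_logistic),
            "stage": comp_dict(self.stage),
            "growth": comp_dict(self.growth),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterProfile":
        def build(key, klass):
            raw = d.get(key)
            if raw is None:
                return None
            try:
                return klass(**raw)
            except TypeError as e:
                raise ParameterError(f"invalid {key} block: {e}") from None

        required = [
            ("arrhenius", ArrheniusParams),
            ("logan10", Logan10Params),
            ("monod_dev", MonodParams),
            ("monod_grw", MonodParams),
            ("moisture", MoistureParams),
            ("airflow_monod", MonodParams),
            ("stage", StageParams),
            ("growth", GrowthParams),
        ]
        comps = {}
        for key, klass in required:
            obj = build(key, klass)
            if obj is None:
                raise ParameterError(f"profile is missing the {key!r} block")
            comps[key] = obj
        return cls(
            name=str(d.get("name", "unnamed")),
            notes=str(d.get("notes", "")),
            temperature_model=d.get("temperature_model", "logan10"),
            airflow_model=d.get("airflow_model", "monod"),
            normalized_flags=dict(
                d.get(
                    "normalized_flags",
                    {
                        "temperature": True,
                        "monod_dev": True,
                        "monod_grw": True,
                        "moisture": True,
                        "airflow": True,
                    },
                )
            ),
            airflow_logistic=build("airflow_logistic", AirflowLogisticParams),
            **comps,
        )


def _base_components():
    return dict(
        arrhenius=ArrheniusParams(
            k_r_ref_T=0.7195,
            k_T_A=8450.0,
            k_T_AL=60000.0,
            k_T_AH=40667.275,
            k_T_ref=298.92,
            k_T_L=285.0,
            k_T_H=308.96,
        ),
        logan10=Logan10Params(
            k_r_max_T=1.0,
            k_r_base_T=0.215,
            k_rho_T=0.2487,
            k_T_base=15.95,
            k_T_max=39.769,
            k_dT=3.0,
        ),
        moisture=MoistureParams(
            k_r_max_W=1.0,
            k_W_med_C1=0.329,
            k_W_med_C2=0.69,
            k_W_med_C3=0.76,
            k_W_med_crit=0.833,
        ),
        airflow_monod=MonodParams(r_max=1.128, k_half=0.1877),
        stage=StageParams(
            k_TS1=234.35, k_TS2=265.5, k_TS3=297.5, k_B_asy=0.115, w_mat=10.0
        ),
        growth=GrowthParams(
            k_inges=1.61e-4,
            k_maint=5.6779e-6,
            eps_inges=0.79,
            k_alpha_excr=0.5762,
            k_alpha_assim=0.2135,
        ),
    )


def builtin_profile(name: str) -> ParameterProfile:
    """One of the shipped parameter profiles.

    ``table3_original``: the estimates from the aggregated literature
    datasets (feed half-saturations 0.0049 / 0.00532 g d^-1).
    ``table3_recalibrated_D1D5``: identical except the feed
    half-saturations re-estimated on the D1/D5 trajectory subset
    (0.0137 / 0.0717 g d^-1, maxima renormalized to 1).
    """
    base = _base_components()
    if name == "table3_original":
        return ParameterProfile(
            name=name,
            monod_dev=MonodParams(r_max=0.9758, k_half=0.0049),
            monod_grw=MonodParams(r_max=2.0, k_half=0.00532),
            notes="published estimates from aggregated literature datasets",
            **base,
        )
    if name == "table3_recalibrated_D1D5":
        return ParameterProfile(
            name=name,
            monod_dev=MonodParams(r_max=1.0, k_half=0.0137),
            monod_grw=MonodParams(r_max=1.0, k_half=0.0717),
            notes=(
                "feed half-saturations re-estimated on the D1/D5 dry-mass "
                "trajectory subset after a feed-type change"
            ),
            **base,
        )
    raise ParameterError(
        f"unknown builtin profile {name!r}; available: {BUILTIN_PROFILE_NAMES}"
    )


BUILTIN_PROFILE_NAMES = ("table3_original", "table3_recalibrated_D1D5")
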