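"""Parameter estimation: dataset preparation and multi-start least squares.

The estimation workflow mirrors how the shipped parameter values were
obtained from heterogeneous literature datasets:

1. collect observations of one rate (or development time, converted to a
   rate by reciprocals) against one varied factor;
2. normalize each dataset by its own observed maximum, removing the
   dependence on feed type and assay conditions that differ between
   sources;
3. pool the normalized datasets that probe the same factor (or average
   them pointwise);
4. fit the static rate model by bounded nonlinear least squares from many
   stratified starting points;
5. rescale the fitted maximum-rate parameters by the observed maximum to
   return to absolute units.

Dynamic fitting compares simulated against observed dry-mass trajectories
(the development sum is latent) and supports re-estimating a masked subset
of profile parameters on a subset of trajectories — the recalibration step
used when the feed type changes between experimental campaigns.

The static fitter is an sklearn-style estimator (``StaticRateModel``) so it
composes with sklearn model-selection tooling; :func:`fit_static` is a thin
wrapper returning a :class:`FitResult`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from . import env_rates as er
from .dynamics import simulate
from .exceptions import DataError, FitError, ParameterError
from .state import EnvironmentSchedule, LarvaState

logger = logging.getLogger(__name__)

__all__ = [
    "RateDataset",
    "FitResult",
    "StaticRateModel",
    "development_time_to_rate",
    "normalize_dataset",
    "group_datasets",
    "fit_static",
    "rescale_to_observed",
    "fit_dynamic",
    "calibrate_subset",
    "r_squared",
    "STATIC_MODELS",
]

FACTOR_KINDS = ("temperature", "feed_density", "moisture", "airflow", "time")


@dataclass
class RateDataset:
    """Observations of one response against one varied factor.

    For static rate data the factor is an environmental driver and the
    response a (possibly normalized) rate; for trajectory data the factor
    is time [h] and the response dry mass [g].
    """

    id: str
    factor_kind: str
    factor: np.ndarray
    response: np.ndarray
    factor_unit: str = ""
    response_unit: str = ""
    normalized: bool = False
    source_ids: Optional[np.ndarray] = None
    true_params: Optional[dict] = None

    def __post_init__(self):
        self.factor = np.asarray(self.factor, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.factor_kind not in FACTOR_KINDS:
            raise DataError(
                f"factor_kind must be one of {FACTOR_KINDS}, got {self.factor_kind!r}"
            )
        if self.factor.shape != self.response.shape or self.factor.ndim != 1:
            raise DataError("factor and response must be equal-length 1-D arrays")
        if self.factor.size == 0:
            raise DataError("dataset is empty")
        if np.any(self.response < 0):
            raise DataError("responses must be >= 0")
        if self.source_ids is None:
            self.source_ids = np.full(self.factor.size, self.id, dtype=object)
        else:
            self.source_ids = np.asarray(self.source_ids, dtype=object)
            if self.source_ids.shape != self.factor.shape:
                raise DataError("source_ids must match factor length")

    def __len__(self) -> int:
        return int(self.factor.size)


@dataclass
class FitResult:
    """Outcome of a multi-start least-squares fit."""

    model_id: str
    params: dict
    bounds: dict
    rss: float
    r_squared: float
    n_starts: int
    best_start: int
    converged: list = field(default_factory=list)
    n_obs: int = 0
    start_rss: list = field(default_factory=list)
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rss < 0:
            raise ParameterError("FitResult.rss must be >= 0")
        if self.r_squared > 1 + 1e-12:
            raise ParameterError("FitResult.r_squared must be <= 1")

    def report(self) -> str:
        """One key per line, human-diffable."""
        lines = [f"model: {self.model_id}"]
        for k, v in self.params.items():
            lines.append(f"param {k}: {v!r}")
        for k, v in self.fixed.items():
            lines.append(f"fixed {k}: {v!r}")
        lines += [
            f"rss: {self.rss!r}",
            f"r_squared: {self.r_squared!r}",
            f"n_obs: {self.n_obs}",
            f"n_starts: {self.n_starts}",
            f"best_start: {self.best_start}",
            f"n_converged: {sum(bool(c) for c in self.converged)}",
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# dataset preparation

def development_time_to_rate(times):
    """Convert development times [d] to development rates [d^-1] elementwise."""
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise DataError("development times must be > 0 before rate conversion")
    return 1.0 / t


def normalize_dataset(ds: RateDataset) -> RateDataset:
    """Divide responses by their observed maximum (new dataset, max = 1)."""
    m = float(np.max(ds.response))
    if m <= 0:
        raise DataError(f"dataset {ds.id!r} has no positive response to normalize by")
    return dataclasses.replace(
        ds,
        response=ds.response / m,
        normalized=True,
        response_unit="normalized",
    )


def group_datasets(
    datasets: Sequence[RateDataset], method: str = "pool"
) -> RateDataset:
    """Combine normalized datasets that probe the same factor.

    ``method='pool'`` concatenates all observations (each point keeps its
    source id); ``method='average'`` averages responses of points sharing
    the same factor value across sources.  Pooling is the default — with
    per-source normalization the two differ only in the implied weighting.
    """
    if not datasets:
        raise DataError("cannot group an empty list of datasets")
    kinds = {ds.factor_kind for ds in datasets}
    units = {ds.factor_unit for ds in datasets}
    if len(kinds) > 1 or len(units) > 1:
        raise DataError(f"cannot group datasets of mixed factor kind/unit: {kinds}")
    if method not in ("pool", "average"):
        raise DataError("method must be 'pool' or 'average'")
    factor = np.concatenate([ds.factor for ds in datasets])
    response = np.concatenate([ds.response for ds in datasets])
    sources = np.concatenate([ds.source_ids for ds in datasets])
    if method == "average":
        uniq, inv = np.unique(factor, return_inverse=True)
        avg = np.zeros_like(uniq)
        counts = np.bincount(inv)
        np.add.at(avg, inv, response)
        avg = avg / counts
        factor, response = uniq, avg
        sources = np.full(uniq.size, "avg", dtype=object)
    return RateDataset(
        id="+".join(ds.id for ds in datasets),
        factor_kind=datasets[0].factor_kind,
        factor=factor,
        response=response,
        factor_unit=datasets[0].factor_unit,
        response_unit=datasets[0].response_unit,
        normalized=all(ds.normalized for ds in datasets),
        source_ids=sources,
    )


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (negative for bad fits)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise DataError("observed/predicted must be equal-length 1-D, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("observed values have zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# --------------------------------------------------------------------------
# static model registry

@dataclass(frozen=True)
class _ModelSpec:
    param_names: tuple
    predict: Callable  # (x, theta_dict, fixed_dict) -> response array
    default_bounds: dict
    scale_params: tuple  # parameters in response units (rescaled by max rate)
    factor_kind: str
    fixed_defaults: dict = field(default_factory=dict)


def _predict_monod(x, th, fx):
    return er.monod_rate(x, er.MonodParams(r_max=th["r_max"], k_half=th["k_half"]))


def _predict_arrhenius(x, th, fx):
    p = er.ArrheniusParams(
        k_r_ref_T=th["k_r_ref_T"],
        k_T_A=th["k_T_A"],
        k_T_AL=th["k_T_AL"],
        k_T_AH=th["k_T_AH"],
        k_T_ref=fx["k_T_ref"],
        k_T_L=th["k_T_L"],
        k_T_H=th["k_T_H"],
    )
    return er.arrhenius_rate(x, p)


def _predict_logan10(x, th, fx):
    p = er.Logan10Params(
        k_r_max_T=th["k_r_max_T"],
        k_r_base_T=th["k_r_base_T"],
        k_rho_T=th["k_rho_T"],
        k_T_base=fx["k_T_base"],
        k_T_max=th["k_T_max"],
        k_dT=th["k_dT"],
    )
    return er.logan10_rate(x, p)


def _predict_moisture(x, th, fx):
    p = er.MoistureParams(
        k_r_max_W=th["k_r_max_W"],
        k_W_med_C1=th["k_W_med_C1"],
        k_W_med_C2=th["k_W_med_C2"],
        k_W_med_C3=th["k_W_med_C3"],
        k_W_med_crit=th["k_W_med_crit"],
    )
    return er.moisture_growth_rate(x, p, smooth=False)


def _predict_airflow_logistic(x, th, fx):
    p = er.AirflowLogisticParams(
        k_r_max_A=th["k_r_max_A"],
        k_A_inf=th["k_A_inf"],
        k_A_trans=th["k_A_trans"],
    )
    return er.airflow_logistic_rate(x, p)


#: Registry of fittable static models.  Default bounds are deliberately
#: generous physical ranges (temperatures within rearing-relevant spans,
#: fractions in [0, 1]); the published estimation only states that bounds
#: were used, so these are package choices.
STATIC_MODELS: dict[str, _ModelSpec] = {
    "monod_dev": _ModelSpec(
        param_names=("r_max", "k_half"),
        predict=_predict_monod,
        default_bounds={"r_max": (1e-6, 10.0), "k_half": (1e-6, 1.0)},
        scale_params=("r_max",),
        factor_kind="feed_density",
    ),
    "monod_grw": _ModelSpec(
        param_names=("r_max", "k_half"),
        predict=_predict_monod,
        default_bounds={"r_max": (1e-6, 10.0), "k_half": (1e-6, 1.0)},
        scale_params=("r_max",),
        factor_kind="feed_density",
    ),
    "airflow_monod": _ModelSpec(
        param_names=("r_max", "k_half"),
        predict=_predict_monod,
        default_bounds={"r_max": (1e-6, 10.0), "k_half": (1e-3, 10.0)},
        scale_params=("r_max",),
        factor_kind="airflow",
    ),
    "arrhenius": _ModelSpec(
        param_names=("k_r_ref_T", "k_T_A", "k_T_AL", "k_T_AH", "k_T_L", "k_T_H"),
        predict=_predict_arrhenius,
        default_bounds={
            "k_r_ref_T": (1e-3, 5.0),
            "k_T_A": (2000.0, 20000.0),
            "k_T_AL": (20000.0, 150000.0),
            "k_T_AH": (20000.0, 150000.0),
            "k_T_L": (273.15, 295.0),
            "k_T_H": (295.0, 330.0),
        },
        scale_params=("k_r_ref_T",),
        factor_kind="temperature",
        # The reference temperature is a convention, not an estimable
        # quantity (it trades off exactly against k_r_ref_T), so it is
        # held fixed; override via ``fixed``.
        fixed_defaults={"k_T_ref": 298.92},
    ),
    "logan10": _ModelSpec(
        param_names=("k_r_max_T", "k_r_base_T", "k_rho_T", "k_T_max", "k_dT"),
        predict=_predict_logan10,
        default_bounds={
            "k_r_max_T": (1e-3, 5.0),
            "k_r_base_T": (1e-3, 2.0),
            "k_rho_T": (0.01, 2.0),
            "k_T_max": (30.0, 60.0),
            "k_dT": (0.1, 15.0),
        },
        scale_params=("k_r_max_T", "k_r_base_T"),
        factor_kind="temperature",
        # k_r_base_T and k_T_base enter the curve only through the
        # combination k_gamma * exp(k_rho_T * k_T_base): the pair is not
        # jointly identifiable, so the threshold temperature — directly
        # readable from data as where development ceases — is a fixed
        # convention, like the Arrhenius reference temperature.
        fixed_defaults={"k_T_base": 15.95},
    ),
    "moisture": _ModelSpec(
        param_names=("k_r_max_W", "k_W_med_C1", "k_W_med_C2", "k_W_med_C3", "k_W_med_crit"),
        predict=_predict_moisture,
        default_bounds={
            "k_r_max_W": (1e-3, 5.0),
            "k_W_med_C1": (0.05, 0.55),
            "k_W_med_C2": (0.56, 0.74),
            "k_W_med_C3": (0.741, 0.80),
            "k_W_med_crit": (0.801, 0.99),
        },
        scale_params=("k_r_max_W",),
        factor_kind="moisture",
    ),
    "airflow_logistic": _ModelSpec(
        param_names=("k_r_max_A", "k_A_inf", "k_A_trans"),
        predict=_predict_airflow_logistic,
        default_bounds={
            "k_r_max_A": (1e-3, 10.0),
            "k_A_inf": (1e-3, 10.0),
            "k_A_trans": (-10.0, -1e-3),
        },
        scale_params=("k_r_max_A",),
        factor_kind="airflow",
    ),
}


def _lhs_starts(lb: np.ndarray, ub: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Latin-hypercube stratified starting points within the bounds box."""
    sampler = qmc.LatinHypercube(d=lb.size, seed=int(seed))
    u = sampler.random(n)
    return lb + u * (ub - lb)


class StaticRateModel(BaseEstimator, RegressorMixin):
    """sklearn-style estimator for the static environmental rate models.

    Parameters
    ----------
    model : str
        One of ``STATIC_MODELS`` (monod_dev, monod_grw, airflow_monod,
        arrhenius, logan10, moisture, airflow_logistic).
    bounds : dict, optional
        Per-parameter (lower, upper) overrides of the default bounds.
    n_starts : int
        Number of Latin-hypercube starting points for the bounded
        least-squares search.
    seed : int
        Seed of the start sampler; fits are bit-reproducible given it.
    fixed : dict, optional
        Parameters held fixed (merged over the model's fixed defaults).

    Attributes (after ``fit``)
    --------------------------
    params_ : dict of fitted parameter values
    rss_ : residual sum of squares at the optimum
    r_squared_ : coefficient of determination
    converged_ : per-start convergence flags
    best_start_ : index of the winning start
    """

    def __init__(self, model="monod_dev", bounds=None, n_starts=32, seed=0, fixed=None):
        self.model = model
        self.bounds = bounds
        self.n_starts = n_starts
        self.seed = seed
        self.fixed = fixed

    def _resolve(self):
        if self.model not in STATIC_MODELS:
            raise ParameterError(
                f"unknown static model {self.model!r}; "
                f"available: {sorted(STATIC_MODELS)}"
            )
        spec = STATIC_MODELS[self.model]
        bounds = dict(spec.default_bounds)
        if self.bounds:
            for k, v in self.bounds.items():
                if k not in bounds:
                    raise ParameterError(f"unknown bound for {self.model}: {k!r}")
                bounds[k] = tuple(v)
        fixed = dict(spec.fixed_defaults)
        if self.fixed:
            fixed.update(self.fixed)
        return spec, bounds, fixed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise DataError("X must be a single factor column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape or X.size == 0:
            raise DataError("X and y must be equal-length and non-empty")
        if int(self.n_starts) < 1:
            raise ParameterError("n_starts must be >= 1")
        spec, bounds, fixed = self._resolve()
        names = spec.param_names
        if np.ptp(X) == 0 and len(names) > 1:
            raise DataError(
                "factor has zero variance: design is rank-deficient for "
                f"{len(names)}-parameter model {self.model!r}"
            )
        lb = np.array([bounds[n][0] for n in names])
        ub = np.array([bounds[n][1] for n in names])
        if not np.all(np.isfinite(lb) & np.isfinite(ub)):
            raise ParameterError("bounds must be finite")

        def residuals(theta):
            th = dict(zip(names, theta))
            try:
                pred = spec.predict(X, th, fixed)
            except (ParameterError, er.DomainError):
                return np.full(y.size, 1e6)
            pred = np.asarray(pred, dtype=float)
            if not np.all(np.isfinite(pred)):
                return np.full(y.size, 1e6)
            return pred - y

        starts = _lhs_starts(lb, ub, int(self.n_starts), int(self.seed))
        best = None
        self.converged_ = []
        self.start_rss_ = []
        for i, x0 in enumerate(starts):
            try:
                res = least_squares(
                    residuals,
                    x0,
                    bounds=(lb, ub),
                    method="trf",
                    xtol=1e-13,
                    ftol=1e-13,
                    gtol=1e-13,
                    max_nfev=2000 * len(names),
                )
                ok = res.status > 0
            except Exception as e:  # defensive: a start may blow up
                logger.debug("start %d failed: %s", i, e)
                ok, res = False, None
            self.converged_.append(bool(ok))
            rss = float(2.0 * res.cost) if ok else np.inf
            self.start_rss_.append(rss)
            if ok and (best is None or rss < best[0]):
                best = (rss, i, res)
        if best is None:
            raise FitError(
                f"no start converged for model {self.model!r} "
                f"({self.n_starts} starts)"
            )
        rss, i_best, res = best
        logger.info(
            "fit %s: best start %d/%d, rss=%.6g", self.model, i_best, self.n_starts, rss
        )
        self.params_ = dict(zip(names, (float(v) for v in res.x)))
        self.fixed_ = fixed
        self.bounds_ = bounds
        self.rss_ = rss
        self.best_start_ = i_best
        pred = spec.predict(X, self.params_, fixed)
        self.r_squared_ = r_squared(y, np.asarray(pred, dtype=float))
        self.n_obs_ = int(y.size)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        spec, _, _ = self._resolve()
        return np.asarray(spec.predict(X, self.params_, self.fixed_), dtype=float)

    def to_fit_result(self) -> FitResult:
        return FitResult(
            model_id=self.model,
            params=dict(self.params_),
            bounds=dict(self.bounds_),
            rss=self.rss_,
            r_squared=self.r_squared_,
            n_starts=int(self.n_starts),
            best_start=self.best_start_,
            converged=list(self.converged_),
            n_obs=self.n_obs_,
            start_rss=list(self.start_rss_),
            fixed=dict(self.fixed_),
        )


def fit_static(
    ds: RateDataset,
    model_id: str,
    bounds: Optional[dict] = None,
    n_starts: int = 32,
    seed: int = 0,
    fixed: Optional[dict] = None,
) -> FitResult:
    """Multi-start bounded least-squares fit of one static rate model.

    Deterministic given ``seed``; returns the best converged start.
    """
    est = StaticRateModel(
        model=model_id, bounds=bounds, n_starts=n_starts, seed=seed, fixed=fixed
    )
    est.fit(ds.factor, ds.response)
    return est.to_fit_result()


def rescale_to_observed(result: FitResult, max_rate: float) -> FitResult:
    """Undo per-maximum normalization: multiply rate-scale parameters
    (maxima, base rates) by the observed maximum; shape parameters
    (half-saturations, thresholds, slopes) are untouched."""
    spec = STATIC_MODELS[result.model_id]
    params = dict(result.params)
    for name in spec.scale_params:
        if name in params:
            params[name] = params[name] * float(max_rate)
    return dataclasses.replace(result, params=params)


# --------------------------------------------------------------------------
# dynamic fitting

def _trajectory_residuals(
    theta: np.ndarray,
    mask: Sequence[str],
    base_profile,
    trajectories: Sequence[RateDataset],
    schedules: Sequence[EnvironmentSchedule],
    initial_states: Sequence[LarvaState],
    rtol: float,
    atol: float,
) -> np.ndarray:
    try:
        profile = base_profile.with_updates(dict(zip(mask, theta)))
    except ParameterError:
        return np.full(sum(len(t) for t in trajectories), 1e6)
    out = []
    for ds, sched, init in zip(trajectories, schedules, initial_states):
        times = ds.factor
        t_end = float(times[-1])
        uniq, inv = np.unique(times, return_inverse=True)
        t_eval = uniq[uniq > 0.0]
        try:
            traj = simulate(
                init,
                sched,
                profile,
                t_end,
                t_eval_h=t_eval,
                record="states",
                rtol=rtol,
                atol=atol,
            )
        except Exception:
            return np.full(sum(len(t) for t in trajectories), 1e6)
        lookup = dict(zip(np.round(t_eval, 9), traj.B_dry_g))
        lookup[0.0] = init.B_dry
        pred = np.array([lookup[np.round(u, 9)] for u in uniq])[inv]
        out.append(pred - ds.response)
    return np.concatenate(out)


def fit_dynamic(
    trajectories: Sequence[RateDataset],
    schedules: Sequence[EnvironmentSchedule],
    profile,
    mask: Sequence[str],
    bounds: Optional[dict] = None,
    n_starts: int = 8,
    seed: int = 0,
    initial_states: Optional[Sequence[LarvaState]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> FitResult:
    """Fit masked profile parameters to observed dry-mass trajectories.

    All trajectories enter one joint least-squares objective; each candidate
    parameter vector is evaluated by simulating every trajectory under its
    own environment schedule and comparing dry mass at the observation
    times.  A start whose initial point fails to integrate is marked
    non-converged; the remaining starts continue.

    Parameters
    ----------
    trajectories : list of RateDataset
        ``factor_kind='time'`` datasets (time [h] -> dry mass [g]), each
        with at least 4 points; time 0 must carry the initial mass unless
        ``initial_states`` is given.
    schedules : list of EnvironmentSchedule
        One environment per trajectory.
    mask : list of str
        Canonical parameter symbols to estimate (e.g. ``['k_inges',
        'k_maint']``); everything else stays at the profile value.
    bounds : dict, optional
        Per-symbol (lower, upper); defaults to a factor-of-20 box around
        the profile value (sign-preserving).
    """
    if len(mask) == 0:
        raise ParameterError("fit_dynamic requires a non-empty parameter mask")
    if len(trajectories) == 0:
        raise DataError("fit_dynamic requires at least one trajectory")
    if len(schedules) != len(trajectories):
        raise DataError("need one schedule per trajectory")
    for ds in trajectories:
        if ds.factor_kind != "time":
            raise DataError(f"dataset {ds.id!r} is not a time->mass trajectory")
        if len(ds) < 4:
            raise DataError(f"trajectory {ds.id!r} has fewer than 4 points")
        if np.any(np.diff(np.sort(ds.factor)) < 0):
            raise DataError("trajectory times must be sortable")
    # Order-invariance: sort each trajectory by time.
    trajectories = [
        dataclasses.replace(
            ds,
            factor=ds.factor[np.argsort(ds.factor, kind="stable")],
            response=ds.response[np.argsort(ds.factor, kind="stable")],
            source_ids=ds.source_ids[np.argsort(ds.factor, kind="stable")],
        )
        for ds in trajectories
    ]
    if initial_states is None:
        initial_states = [
            LarvaState(B_dry=float(ds.response[0]), T_sum=0.0) for ds in trajectories
        ]

    base_values = np.array([profile.get(s) for s in mask], dtype=float)
    lb = np.empty(len(mask))
    ub = np.empty(len(mask))
    for j, s in enumerate(mask):
        if bounds and s in bounds:
            lb[j], ub[j] = bounds[s]
        else:
            v = base_values[j]
            if v == 0:
                raise ParameterError(
                    f"no default bounds for zero-valued parameter {s!r}; pass bounds"
                )
            lo, hi = v / 20.0, v * 20.0
            lb[j], ub[j] = (lo, hi) if v > 0 else (hi, lo)

    def residuals(theta):
        return _trajectory_residuals(
            theta, mask, profile, trajectories, schedules, initial_states, rtol, atol
        )

    n_res = sum(len(t) for t in trajectories)
    starts = _lhs_starts(lb, ub, int(n_starts), int(seed))
    # The profile's own values are a natural extra start when inside bounds.
    if np.all((base_values >= lb) & (base_values <= ub)):
        starts = np.vstack([base_values, starts[:-1]]) if n_starts > 1 else starts

    best = None
    converged: list[bool] = []
    start_rss: list[float] = []
    for i, x0 in enumerate(starts):
        r0 = residuals(x0)
        if not np.all(np.isfinite(r0)) or np.all(r0 == 1e6):
            converged.append(False)
            start_rss.append(np.inf)
            continue
        res = least_squares(
            residuals,
            x0,
            bounds=(lb, ub),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            diff_step=1e-5,
            max_nfev=400,
        )
        ok = res.status > 0
        converged.append(bool(ok))
        rss = float(2.0 * res.cost) if ok else np.inf
        start_rss.append(rss)
        logger.info("dynamic fit start %d: rss=%.6g (status %s)", i, rss, res.status)
        if ok and (best is None or rss < best[0]):
            best = (rss, i, res)
    if best is None:
        raise FitError(
            f"no start converged in dynamic fit of {list(mask)} "
            f"({n_starts} starts)"
        )
    rss, i_best, res = best
    obs_all = np.concatenate([ds.response for ds in trajectories])
    pred_all = obs_all + residuals(res.x)
    return FitResult(
        model_id="dynamic:" + ",".join(mask),
        params=dict(zip(mask, (float(v) for v in res.x))),
        bounds={s: (float(lb[j]), float(ub[j])) for j, s in enumerate(mask)},
        rss=rss,
        r_squared=r_squared(obs_all, pred_all),
        n_starts=int(n_starts),
        best_start=i_best,
        converged=converged,
        n_obs=n_res,
        start_rss=start_rss,
    )


def calibrate_subset(
    profile,
    trajectories: Sequence[RateDataset],
    schedules: Sequence[EnvironmentSchedule],
    mask: Sequence[str],
    name: Optional[str] = None,
    **fit_kwargs,
):
    """Re-estimate a masked parameter subset on a subset of trajectories.

    This is the recalibration step used when growing conditions change
    between campaigns (e.g. a new feed type shifts the feed
    half-saturations): the masked parameters are refit on a few
    trajectories and the updated profile is then valid for the whole
    campaign.  Returns ``(new_profile, FitResult)``; untouched parameters
    are carried over identically.
    """
    result = fit_dynamic(trajectories, schedules, profile, mask, **fit_kwargs)
    new_name = name if name is not None else f"{profile.name}+recal"
    return profile.with_updates(result.params, name=new_name), result
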