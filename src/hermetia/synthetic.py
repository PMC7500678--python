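"""Seeded synthetic datasets mirroring the literature data classes.

The estimation workflow was developed against datasets digitized from
several publications: temperature sweeps of development rate (T1-T4),
feed-density sweeps of development and growth rate (F1-F4), moisture
sweeps (M1-M3), one airflow sweep (A1), and dry-mass-over-time
trajectories under different feeding rates (G1, D1-D5).  Those sources are
not redistributable, so this module generates datasets with the same
structure by sampling the model itself plus observation noise — which also
provides exact ground truth for parameter-recovery testing.

Default factor grids follow the ranges covered by the literature sources:
temperature 10-42 degC, feed density 0-0.2 g d^-1 per larva, moisture
0.1-0.95 kg/kg, airflow 0-3 l min^-1.  Noise defaults to gaussian with a
standard deviation of 5% of the response maximum, truncated at zero — a
fraction-of-maximum model matching the normalized fitting workflow.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import env_rates as er
from .dynamics import Trajectory, simulate
from .estimation import RateDataset
from .exceptions import DataError, ParameterError
from .profiles import ParameterProfile, builtin_profile
from .state import EnvironmentSchedule, EnvironmentState, LarvaState

__all__ = [
    "NoiseSpec",
    "ScenarioSpec",
    "generate_response_dataset",
    "generate_trajectory_dataset",
    "make_fixture_suite",
    "DEFAULT_GRIDS",
    "OPTIMAL_ENV",
]

#: A near-optimal constant environment: temperature at the thermal-response
#: peak, saturating feed, plateau moisture, high airflow.
OPTIMAL_ENV = EnvironmentState(T_med=31.0, B_feed=0.2, W_med_pct=0.72, A_air=3.0)

#: Per-model default factor designs, mirroring the literature experiments:
#: temperature and moisture sweeps used roughly equal increments (linear
#: grids); feeding-rate experiments used multiplicative dose series
#: concentrated at low rates (geometric grid over 0.002-0.2 g d^-1), which
#: is also what makes a small half-saturation measurable.
DEFAULT_GRIDS = {
    "arrhenius": ("temperature", lambda n: np.linspace(10.0, 42.0, n)),
    "logan10": ("temperature", lambda n: np.linspace(10.0, 42.0, n)),
    "monod_dev": ("feed_density", lambda n: np.geomspace(0.002, 0.2, n)),
    "monod_grw": ("feed_density", lambda n: np.geomspace(0.002, 0.2, n)),
    "moisture": ("moisture", lambda n: np.linspace(0.1, 0.95, n)),
    "airflow_monod": ("airflow", lambda n: np.linspace(0.0, 3.0, n)),
    "airflow_logistic": ("airflow", lambda n: np.linspace(0.0, 3.0, n)),
}

_UNITS = {
    "temperature": "degC",
    "feed_density": "g_per_d",
    "moisture": "kg_per_kg",
    "airflow": "l_per_min",
    "time": "h",
}


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model: kind, scale (fraction of response max), seed."""

    kind: str = "gaussian"
    scale: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian", "lognormal", "none"):
            raise ParameterError("NoiseSpec.kind must be gaussian|lognormal|none")
        if self.scale < 0:
            raise ParameterError("NoiseSpec.scale must be >= 0")

    def apply(self, clean: np.ndarray) -> np.ndarray:
        """Add noise to a clean response; results are truncated at 0."""
        clean = np.asarray(clean, dtype=float)
        if self.kind == "none" or self.scale == 0:
            return clean.copy()
        rng = np.random.default_rng(int(self.seed))
        if self.kind == "gaussian":
            sd = self.scale * float(np.max(clean)) if clean.size else 0.0
            noisy = clean + rng.normal(0.0, sd, size=clean.shape)
        else:  # lognormal: multiplicative, median-preserving
            noisy = clean * rng.lognormal(0.0, self.scale, size=clean.shape)
        return np.maximum(noisy, 0.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """What to generate: profile, grid (factor values or sample times [h]),
    environment schedule (trajectories only), replicates, noise."""

    profile: ParameterProfile
    grid: Optional[np.ndarray] = None
    schedule: Optional[EnvironmentSchedule] = None
    replicates: int = 1
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(kind="none"))
    initial_B_dry: float = 0.002  # experimental neonate starting weight [g]

    def __post_init__(self):
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if g.size == 0:
                raise ParameterError("ScenarioSpec.grid must be non-empty")
            object.__setattr__(self, "grid", g)
        if self.replicates < 1:
            raise ParameterError("ScenarioSpec.replicates must be >= 1")


def _model_curve(model_id: str, x: np.ndarray, profile: ParameterProfile):
    if model_id == "arrhenius":
        return er.arrhenius_rate(x, profile.arrhenius), dataclasses.asdict(
            profile.arrhenius
        )
    if model_id == "logan10":
        return er.logan10_rate(x, profile.logan10), dataclasses.asdict(profile.logan10)
    if model_id == "monod_dev":
        return er.monod_rate(x, profile.monod_dev), dataclasses.asdict(
            profile.monod_dev
        )
    if model_id == "monod_grw":
        return er.monod_rate(x, profile.monod_grw), dataclasses.asdict(
            profile.monod_grw
        )
    if model_id == "moisture":
        return (
            er.moisture_growth_rate(x, profile.moisture, smooth=False),
            dataclasses.asdict(profile.moisture),
        )
    if model_id == "airflow_monod":
        return er.monod_rate(x, profile.airflow_monod), dataclasses.asdict(
            profile.airflow_monod
        )
    if model_id == "airflow_logistic":
        if profile.airflow_logistic is None:
            raise ParameterError("profile has no airflow_logistic parameters")
        return (
            er.airflow_logistic_rate(x, profile.airflow_logistic),
            dataclasses.asdict(profile.airflow_logistic),
        )
    raise ParameterError(f"unknown model id {model_id!r}")


def generate_response_dataset(
    spec: ScenarioSpec, model_id: str, dataset_id: Optional[str] = None
) -> RateDataset:
    """Sample one static rate model on a factor grid, plus noise.

    The generating parameter values are recorded on the dataset
    (``true_params``) for recovery tests.  Deterministic per noise seed.
    """
    if model_id not in DEFAULT_GRIDS:
        raise ParameterError(f"unknown model id {model_id!r}")
    kind, make_grid = DEFAULT_GRIDS[model_id]
    grid = spec.grid if spec.grid is not None else make_grid(30)
    clean, true_params = _model_curve(model_id, grid, spec.profile)
    clean = np.asarray(clean, dtype=float)
    factor = np.tile(grid, spec.replicates)
    clean_rep = np.tile(clean, spec.replicates)
    noisy = spec.noise.apply(clean_rep)
    sources = np.concatenate(
        [np.full(grid.size, f"rep{r + 1}", dtype=object) for r in range(spec.replicates)]
    )
    return RateDataset(
        id=dataset_id or f"synthetic_{model_id}",
        factor_kind=kind,
        factor=factor,
        response=noisy,
        factor_unit=_UNITS[kind],
        response_unit="rate",
        normalized=False,
        source_ids=sources,
        true_params=true_params,
    )


def generate_trajectory_dataset(
    spec: ScenarioSpec, dataset_id: str = "synthetic_trajectory"
) -> tuple[RateDataset, Trajectory]:
    """Simulate a dry-mass trajectory, sample it at the grid times, add noise.

    Returns both the noisy observations (a ``factor_kind='time'`` dataset)
    and the clean simulated trajectory.
    """
    if spec.schedule is None:
        raise ParameterError("trajectory generation requires a schedule")
    times = spec.grid if spec.grid is not None else np.arange(0.0, 504.0, 12.0)
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0:
        raise DataError("trajectory sample times must start at 0 h")
    traj = simulate(
        LarvaState(B_dry=spec.initial_B_dry),
        spec.schedule,
        spec.profile,
        float(times[-1]),
        t_eval_h=times,
        record="full",
    )
    clean = np.interp(times, traj.time_h, traj.B_dry_g)
    obs = np.tile(clean, spec.replicates)
    factor = np.tile(times, spec.replicates)
    noisy = spec.noise.apply(obs)
    sources = np.concatenate(
        [
            np.full(times.size, f"rep{r + 1}", dtype=object)
            for r in range(spec.replicates)
        ]
    )
    ds = RateDataset(
        id=dataset_id,
        factor_kind="time",
        factor=factor,
        response=noisy,
        factor_unit="h",
        response_unit="g",
        source_ids=sources,
        true_params={
            "k_inges": spec.profile.growth.k_inges,
            "k_maint": spec.profile.growth.k_maint,
            "k_TS1": spec.profile.stage.k_TS1,
            "k_TS2": spec.profile.stage.k_TS2,
            "k_TS3": spec.profile.stage.k_TS3,
            "k_B_half_gm": spec.profile.monod_grw.k_half,
            "k_B_half_dm": spec.profile.monod_dev.k_half,
        },
    )
    return ds, traj


#: Feeding levels [g d^-1 per larva] for the five trajectory datasets,
#: spanning the growth half-saturation of the recalibrated profile.
TRAJECTORY_FEED_LEVELS = (0.02, 0.04, 0.07, 0.14, 0.28)


def make_fixture_suite(
    seed: int, outdir: Union[str, Path], profile: Optional[ParameterProfile] = None
) -> list[Path]:
    """Write one CSV fixture per literature dataset class; idempotent per seed.

    Produces temperature sweeps T1-T4 (thermal performance model),
    feed-density sweeps F1-F4 in development-rate and growth-rate variants,
    moisture sweeps M1-M3, the airflow sweep A1, and trajectories G1 and
    D1-D5 at five feeding levels.  Child seeds are spawned deterministically
    from ``seed``.
    """
    from .io import write_dataset  # local import to avoid a cycle

    profile = profile or builtin_profile("table3_recalibrated_D1D5")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(int(seed)).generate_state(64) % (2**31)
    written: list[Path] = []
    k = 0

    def next_noise(scale=0.05):
        nonlocal k
        s = NoiseSpec(kind="gaussian", scale=scale, seed=int(seeds[k]))
        k += 1
        return s

    def emit(ds: RateDataset, fname: str):
        path = outdir / fname
        write_dataset(ds, path)
        written.append(path)

    for i in range(4):
        spec = ScenarioSpec(profile=profile, noise=next_noise())
        emit(
            generate_response_dataset(spec, "logan10", dataset_id=f"T{i + 1}"),
            f"T{i + 1}_temperature_dev_rate.csv",
        )
    for i in range(4):
        spec = ScenarioSpec(profile=profile, noise=next_noise())
        emit(
            generate_response_dataset(spec, "monod_dev", dataset_id=f"F{i + 1}dev"),
            f"F{i + 1}_feed_dev_rate.csv",
        )
        spec = ScenarioSpec(profile=profile, noise=next_noise())
        emit(
            generate_response_dataset(spec, "monod_grw", dataset_id=f"F{i + 1}grw"),
            f"F{i + 1}_feed_growth_rate.csv",
        )
    for i in range(3):
        spec = ScenarioSpec(profile=profile, noise=next_noise())
        emit(
            generate_response_dataset(spec, "moisture", dataset_id=f"M{i + 1}"),
            f"M{i + 1}_moisture_growth_rate.csv",
        )
    spec = ScenarioSpec(profile=profile, noise=next_noise())
    emit(
        generate_response_dataset(spec, "airflow_monod", dataset_id="A1"),
        "A1_airflow_growth_rate.csv",
    )

    sched = EnvironmentSchedule.constant(OPTIMAL_ENV)
    spec = ScenarioSpec(profile=profile, schedule=sched, noise=next_noise())
    ds, _ = generate_trajectory_dataset(spec, dataset_id="G1")
    emit(ds, "G1_dry_mass_trajectory.csv")
    for i, feed in enumerate(TRAJECTORY_FEED_LEVELS):
        env = dataclasses.replace(OPTIMAL_ENV, B_feed=feed)
        spec = ScenarioSpec(
            profile=profile,
            schedule=EnvironmentSchedule.constant(env),
            noise=next_noise(),
        )
        ds, _ = generate_trajectory_dataset(spec, dataset_id=f"D{i + 1}")
        emit(ds, f"D{i + 1}_dry_mass_trajectory_feed_{feed}.csv")
    return written
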