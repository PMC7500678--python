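"""File formats: dataset/schedule/trajectory CSV and profile YAML.

All numeric values are written with 17 significant digits so write/read
round trips are lossless at float64 precision.  Parameter profiles are
stored as nested key/value text (YAML) because parameter tables are the
scientific interface of the model and must diff cleanly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .dynamics import Trajectory
from .estimation import FACTOR_KINDS, RateDataset
from .exceptions import DataError, ParameterError
from .profiles import BUILTIN_PROFILE_NAMES, ParameterProfile, builtin_profile
from .state import EnvironmentSchedule, EnvironmentState

__all__ = [
    "load_profile",
    "save_profile",
    "read_dataset",
    "write_dataset",
    "read_trajectory_dataset",
    "read_schedule",
    "write_schedule",
    "write_trajectory",
]

_FLOAT_FMT = "%.17g"

DATASET_COLUMNS = ["factor", "response", "source_id", "unit_factor", "unit_response"]
SCHEDULE_COLUMNS = ["time_h", "T_med_C", "B_feed_g_per_d", "W_med_pct", "A_air_l_per_min"]
TRAJECTORY_COLUMNS = ["time_h", "B_dry_g", "source_id"]


def load_profile(name_or_path: Union[str, Path]) -> ParameterProfile:
    """Load a parameter profile by builtin name or from a YAML file.

    Builtin names: ``table3_original`` (published estimates) and
    ``table3_recalibrated_D1D5`` (feed half-saturations re-estimated on the
    D1/D5 trajectory subset).
    """
    name = str(name_or_path)
    if name in BUILTIN_PROFILE_NAMES:
        return builtin_profile(name)
    path = Path(name_or_path)
    if not path.exists():
        raise ParameterError(
            f"{name!r} is neither a builtin profile {BUILTIN_PROFILE_NAMES} "
            "nor an existing file"
        )
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise ParameterError(f"cannot parse profile file {path}: {e}") from None
    if not isinstance(raw, dict):
        raise ParameterError(f"profile file {path} does not contain a mapping")
    return ParameterProfile.from_dict(raw)


def save_profile(profile: ParameterProfile, path: Union[str, Path]) -> None:
    """Write a profile as nested key/value YAML (lossless float round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(profile.to_dict(), fh, sort_keys=False, default_flow_style=False)


def _read_csv(path: Union[str, Path], required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except FileNotFoundError:
        raise DataError(f"file not found: {path}") from None
    except Exception as e:
        raise DataError(f"cannot parse {path}: {e}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        for c in required:
            if pd.isna(row[c]):
                raise DataError(f"{path}, line {i}: missing value in column {c!r}")
    return df


def write_dataset(ds: RateDataset, path: Union[str, Path]) -> None:
    """Write a rate dataset in the standard CSV dialect.

    Dataset metadata (id, factor kind, normalized flag) rides in a comment
    line so the numeric table stays a plain five-column CSV.
    """
    df = pd.DataFrame(
        {
            "factor": ds.factor,
            "response": ds.response,
            "source_id": ds.source_ids,
            "unit_factor": ds.factor_unit,
            "unit_response": ds.response_unit,
        }
    )
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# hermetia-dataset id={ds.id} kind={ds.factor_kind} "
            f"normalized={int(ds.normalized)}\n"
        )
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _dataset_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# hermetia-dataset"):
        for tok in first.split()[2:]:
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    return meta


def read_dataset(path: Union[str, Path]) -> RateDataset:
    """Read a rate dataset from the standard CSV dialect."""
    path = Path(path)
    df = _read_csv(path, DATASET_COLUMNS)
    meta = _dataset_meta(path)
    kind = meta.get("kind", "")
    if kind not in FACTOR_KINDS:
        # fall back on the unit column to infer the factor kind
        unit = str(df["unit_factor"].iloc[0]) if len(df) else ""
        kind = {
            "degC": "temperature",
            "g_per_d": "feed_density",
            "kg_per_kg": "moisture",
            "l_per_min": "airflow",
            "h": "time",
        }.get(unit, "")
    if kind not in FACTOR_KINDS:
        raise DataError(
            f"{path}: cannot determine factor kind (no metadata, unit "
            f"{df['unit_factor'].iloc[0]!r} not recognized)"
        )
    return RateDataset(
        id=meta.get("id", path.stem),
        factor_kind=kind,
        factor=df["factor"].to_numpy(dtype=float),
        response=df["response"].to_numpy(dtype=float),
        factor_unit=str(df["unit_factor"].iloc[0]),
        response_unit=str(df["unit_response"].iloc[0]),
        normalized=bool(int(meta.get("normalized", "0"))),
        source_ids=df["source_id"].to_numpy(dtype=object),
    )


def read_trajectory_dataset(path: Union[str, Path]) -> RateDataset:
    """Read a time -> dry-mass trajectory CSV (time_h, B_dry_g, source_id)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except FileNotFoundError:
        raise DataError(f"file not found: {path}") from None
    if set(TRAJECTORY_COLUMNS) <= set(df.columns):
        return RateDataset(
            id=path.stem,
            factor_kind="time",
            factor=df["time_h"].to_numpy(dtype=float),
            response=df["B_dry_g"].to_numpy(dtype=float),
            factor_unit="h",
            response_unit="g",
            source_ids=df["source_id"].to_numpy(dtype=object),
        )
    # the generic dataset dialect with kind=time also qualifies
    ds = read_dataset(path)
    if ds.factor_kind != "time":
        raise DataError(f"{path}: not a time->mass trajectory dataset")
    return ds


def write_schedule(schedule: EnvironmentSchedule, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "time_h": schedule.times_h,
            "T_med_C": [s.T_med for s in schedule.states],
            "B_feed_g_per_d": [s.B_feed for s in schedule.states],
            "W_med_pct": [s.W_med_pct for s in schedule.states],
            "A_air_l_per_min": [s.A_air for s in schedule.states],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_schedule(path: Union[str, Path]) -> EnvironmentSchedule:
    """Read an environment schedule CSV (hold interpolation between rows)."""
    path = Path(path)
    df = _read_csv(path, SCHEDULE_COLUMNS)
    times = df["time_h"].to_numpy(dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        bad = int(np.argmin(np.diff(times) > 0)) + 3  # +2 header/1-based, +1 next row
        raise DataError(f"{path}, line {bad}: time stamps must be strictly increasing")
    states = [
        EnvironmentState(
            T_med=float(r.T_med_C),
            B_feed=float(r.B_feed_g_per_d),
            W_med_pct=float(r.W_med_pct),
            A_air=float(r.A_air_l_per_min),
        )
        for r in df.itertuples()
    ]
    return EnvironmentSchedule(times, states)


def write_trajectory(traj: Trajectory, path_prefix: Union[str, Path]) -> tuple[Path, Path]:
    """Write a simulated trajectory and its events to ``<prefix>_trajectory.csv``
    and ``<prefix>_events.csv``."""
    prefix = Path(path_prefix)
    traj_path = prefix.parent / (prefix.name + "_trajectory.csv")
    ev_path = prefix.parent / (prefix.name + "_events.csv")
    traj.to_frame().to_csv(traj_path, index=False, float_format=_FLOAT_FMT)
    traj.events_frame().to_csv(ev_path, index=False, float_format=_FLOAT_FMT)
    return traj_path, ev_path
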