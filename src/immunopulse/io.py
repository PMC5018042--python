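"""Plain-text persistence: YAML configs, CSV time series, JSON summaries.

One flat schema per object.  Parameter configs carry a ``kind`` key
(``nondimensional`` / ``dimensional``); schedules are either an explicit
``boosts`` list of ``[time, dose]`` pairs or the periodic shorthand
``{V0, delta_t, n_boosts}``.  Everything written here round-trips through
the readers in this module.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .model import (
    STATE_NAMES_NONDIM,
    DimensionalParameters,
    NondimParameters,
    Trajectory,
)
from .simulate import SolverSettings, TreatmentSchedule

__all__ = [
    "load_parameters",
    "save_parameters",
    "load_schedule",
    "save_schedule",
    "load_state",
    "load_trajectory",
    "save_summary",
    "solver_settings_from_config",
]

PathLike = Union[str, Path]


def _read_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_parameters(path: PathLike):
    """Read a parameter config; returns the record matching its ``kind``."""
    data = _read_yaml(path)
    kind = data.pop("kind", "nondimensional")
    if kind in ("nondimensional", "nondim"):
        cls = NondimParameters
    elif kind == "dimensional":
        cls = DimensionalParameters
    else:
        raise ValueError(f"{path}: unknown parameter kind {kind!r}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return cls(**{k: float(v) for k, v in data.items()})


def save_parameters(params, path: PathLike) -> None:
    kind = "dimensional" if isinstance(params, DimensionalParameters) else "nondimensional"
    payload = {"kind": kind, **{k: float(v) for k, v in dataclasses.asdict(params).items()}}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def schedule_from_dict(data: dict) -> TreatmentSchedule:
    if "boosts" in data:
        pairs = data["boosts"]
        if not pairs:
            return TreatmentSchedule.empty()
        times, doses = zip(*[(float(t), float(d)) for t, d in pairs])
        return TreatmentSchedule(times, doses)
    if {"V0", "delta_t", "n_boosts"} <= set(data):
        return TreatmentSchedule.periodic(
            float(data["V0"]), float(data["delta_t"]), int(data["n_boosts"]),
            start=float(data.get("start", 0.0)),
        )
    raise ValueError("schedule config needs either 'boosts' or {V0, delta_t, n_boosts}")


def load_schedule(path: PathLike) -> TreatmentSchedule:
    return schedule_from_dict(_read_yaml(path))


def save_schedule(schedule: TreatmentSchedule, path: PathLike) -> None:
    payload = {"boosts": [[float(t), float(d)] for t, d in zip(schedule.boost_times, schedule.boost_doses)]}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def state_from_dict(data: dict) -> np.ndarray:
    missing = set(STATE_NAMES_NONDIM) - set(data)
    if missing:
        raise ValueError(f"initial state is missing components {sorted(missing)}")
    return np.array([float(data[name]) for name in STATE_NAMES_NONDIM])


def load_state(path: PathLike) -> np.ndarray:
    return state_from_dict(_read_yaml(path))


def load_trajectory(path: PathLike) -> pd.DataFrame:
    """Read a trajectory CSV back (column check included)."""
    frame = pd.read_csv(path)
    expected = ("t",) + STATE_NAMES_NONDIM
    if tuple(frame.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {tuple(frame.columns)}")
    return frame


def save_summary(summary, path: PathLike) -> None:
    """Write any summary object exposing ``to_dict`` (or a dict) as JSON."""
    payload = summary.to_dict() if hasattr(summary, "to_dict") else dict(summary)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def solver_settings_from_config(data: dict, **overrides) -> SolverSettings:
    """Build solver settings from the optional ``solver`` section of a
    config, applying explicit keyword overrides (CLI flags) last."""
    kwargs = dict(data.get("solver", {}))
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(SolverSettings)}
    unknown = set(kwargs) - known
    if unknown:
        raise ValueError(f"unknown solver settings {sorted(unknown)}")
    return SolverSettings(**kwargs)
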