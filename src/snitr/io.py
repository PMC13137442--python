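"""Readers and writers for parameter files, trajectories and series.

File dialects (deterministic byte output given identical inputs):

* Parameter file — flat JSON object with the ten rate keys.
* Trajectory file — CSV with header ``time,S,N,I,T,R``, fixed decimal
  notation ('.' separator, UTF-8, LF), configurable precision.
* Series file — CSV with header ``time,value`` plus a JSON sidecar
  (same stem, ``.json``) holding ``bin_width``, ``fit_window_end``,
  ``validation_end`` and ``population``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import ObservedSeries
from .model import Trajectory
from .params import PARAM_NAMES, ParameterError, SnitrParameters

__all__ = [
    "load_params",
    "save_params",
    "write_trajectory",
    "read_trajectory",
    "write_series",
    "read_series",
]

_TRAJ_COLUMNS = ["time", "S", "N", "I", "T", "R"]


def load_params(path, strict: bool = True) -> SnitrParameters:
    """Load and validate a parameter JSON file.

    Missing keys, values outside [0, 1] and (when ``strict``) violated
    sum constraints raise :class:`ParameterError` naming the offender;
    with ``strict=False`` sum-constraint violations only warn.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParameterError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a JSON object of rate parameters")
    params = SnitrParameters.from_dict(data)
    params.validate(strict=strict)
    return params


def save_params(params: SnitrParameters, path) -> None:
    Path(path).write_text(
        json.dumps(params.to_dict(), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
        newline="\n",
    )


def write_trajectory(traj: Trajectory, path, precision: int = 6) -> None:
    """Write a trajectory as fixed-decimal CSV (header time,S,N,I,T,R)."""
    frame = traj.to_frame()
    frame.to_csv(
        path,
        index=False,
        float_format=f"%.{precision}f",
        lineterminator="\n",
        encoding="utf-8",
    )


def _read_numeric_csv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            raise ValueError(f"{path}: column {col} contains non-numeric values")
    if np.any(np.diff(frame["time"].to_numpy()) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    return frame


def read_trajectory(path, params: SnitrParameters | None = None) -> Trajectory:
    """Read a trajectory CSV; ``params`` reattaches the generating rates.

    When no parameters are supplied a permissive placeholder is NOT
    invented — the caller gets a trajectory whose ``params`` is None and
    must not use parameter-dependent diagnostics on it.
    """
    frame = _read_numeric_csv(path, _TRAJ_COLUMNS)
    return Trajectory(
        times=frame["time"].to_numpy(dtype=float),
        states=frame[["S", "N", "I", "T", "R"]].to_numpy(dtype=float),
        params=params,
    )


def write_series(series: ObservedSeries, path, precision: int = 8) -> None:
    """Write an observed series CSV plus its JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time": series.times, "value": series.values}).to_csv(
        path,
        index=False,
        float_format=f"%.{precision}f",
        lineterminator="\n",
        encoding="utf-8",
    )
    sidecar = {
        "bin_width": series.bin_width,
        "fit_window_end": series.fit_window_end,
        "validation_end": series.validation_end,
        "population": series.population,
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
        newline="\n",
    )


def read_series(path) -> ObservedSeries:
    """Read a series CSV and its JSON sidecar back into an ObservedSeries."""
    path = Path(path)
    frame = _read_numeric_csv(path, ["time", "value"])
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("bin_width", "fit_window_end", "validation_end", "population"):
        if key not in meta:
            raise ValueError(f"{sidecar_path}: missing metadata key {key!r}")
    return ObservedSeries(
        times=frame["time"].to_numpy(dtype=float),
        values=frame["value"].to_numpy(dtype=float),
        bin_width=float(meta["bin_width"]),
        fit_window_end=float(meta["fit_window_end"]),
        validation_end=float(meta["validation_end"]),
        population=int(meta["population"]),
    )
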