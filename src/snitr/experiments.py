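"""Simulation studies: density evolution, parameter sweeps, reproduction-
number sensitivity grids, and intervention-timing runs.

The intervention experiment models delayed entry of truth-spreading
(transmitter) users: until the activation time every transmitter-
generating pathway (alpha2, beta2, epsilon) is switched off, so the
rumor spreads unopposed; at activation the pathways switch on and a
small fraction of susceptible users is converted directly into
transmitters.  Total density is conserved across the switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .model import Trajectory, integrate, rhs_reduced
from .params import DEFAULT_INIT, SnitrParameters, StateVector
from .stability import reproduction_numbers

__all__ = [
    "DensityResult",
    "SweepResult",
    "SensitivityGrid",
    "InterventionResult",
    "run_density_experiment",
    "sweep_parameter",
    "sensitivity_grid",
    "delayed_transmitter_run",
]

_COMPARTMENT_COLUMN = {"S": 0, "N": 1, "I": 2, "T": 3, "R": 4}


@dataclass(frozen=True)
class DensityResult:
    """A single density-evolution run with its steady-state diagnostic."""

    trajectory: Trajectory
    final_state: StateVector
    final_residual: float  # max-norm of the reduced field at the endpoint
    at_steady_state: bool


def run_density_experiment(
    params: SnitrParameters,
    init: StateVector = DEFAULT_INIT,
    t_end: float = 200.0,
    n_points: int = 2001,
    steady_tol: float = 1e-8,
) -> DensityResult:
    """Integrate the model and diagnose whether it reached steady state.

    Steady state is declared when the max-norm of the reduced vector
    field at the endpoint drops below ``steady_tol``; otherwise the run
    simply reports the endpoint and residual.
    """
    traj = integrate(params, init, t_end, n_points=n_points)
    endpoint = traj.endpoint()
    residual = float(np.max(np.abs(rhs_reduced(endpoint.to_array4(), params))))
    return DensityResult(
        trajectory=traj,
        final_state=endpoint,
        final_residual=residual,
        at_steady_state=residual < steady_tol,
    )


@dataclass(frozen=True)
class SweepResult:
    """Trajectories and per-value peak/final summaries for one swept rate."""

    swept_parameter: str
    compartment: str
    values: np.ndarray
    trajectories: list[Trajectory]
    summaries: pd.DataFrame = field(repr=False)


def sweep_parameter(
    base_params: SnitrParameters,
    name: str,
    values,
    init: StateVector = DEFAULT_INIT,
    t_end: float = 60.0,
    compartment: str = "I",
    n_points: int = 1201,
) -> SweepResult:
    """Re-run the model for each value of one rate, on a shared initial
    condition and grid, summarising the chosen compartment's peak
    density, time of peak and final density.

    Values whose resulting parameter set violates a sum constraint are
    still run but flagged (``constraint_ok=False``) in the summary.
    """
    if compartment not in _COMPARTMENT_COLUMN:
        raise ValueError(f"unknown compartment {compartment!r}")
    col = _COMPARTMENT_COLUMN[compartment]
    values = np.asarray(values, dtype=float)
    trajectories, rows = [], []
    for v in values:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = base_params.with_updates(**{name: float(v)})
        ok = not any(m.startswith("sum constraint") for m in p.soft_violations())
        traj = integrate(p, init, t_end, n_points=n_points)
        series = traj.states[:, col]
        k = int(np.argmax(series))
        trajectories.append(traj)
        rows.append(
            {
                "value": float(v),
                "constraint_ok": ok,
                "peak_density": float(series[k]),
                "time_of_peak": float(traj.times[k]),
                "final_density": float(series[-1]),
            }
        )
    return SweepResult(
        swept_parameter=name,
        compartment=compartment,
        values=values,
        trajectories=trajectories,
        summaries=pd.DataFrame(rows),
    )


@dataclass(frozen=True)
class SensitivityGrid:
    """A reproduction number evaluated on a 1- or 2-parameter grid."""

    target: str  # "r01" | "r02" | "r03"
    axes: dict[str, np.ndarray]
    values: np.ndarray


def sensitivity_grid(
    base_params: SnitrParameters,
    target: str,
    axes: dict[str, np.ndarray | list],
) -> SensitivityGrid:
    """Evaluate R01/R02/R03 on a grid over one or two rates.

    The grid shape is the product of the axis lengths (row-major in the
    order the axes are given).
    """
    if target not in ("r01", "r02", "r03"):
        raise ValueError(f"target must be r01, r02 or r03, got {target!r}")
    if not 1 <= len(axes) <= 2:
        raise ValueError("provide one or two axes")
    names = list(axes)
    grids = [np.asarray(axes[k], dtype=float) for k in names]
    shape = tuple(len(g) for g in grids)
    out = np.empty(shape)
    for idx in np.ndindex(shape):
        updates = {names[d]: float(grids[d][idx[d]]) for d in range(len(names))}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = base_params.with_updates(**updates)
        out[idx] = getattr(reproduction_numbers(p), target)
    return SensitivityGrid(target=target, axes=dict(zip(names, grids)), values=out)


@dataclass(frozen=True)
class InterventionResult:
    """Outcome of one delayed-transmitter run."""

    t_enter: float
    max_i: float
    max_t: float
    n_peaks: int  # local maxima of the neglected density
    trajectory: Trajectory


def delayed_transmitter_run(
    params: SnitrParameters,
    t_enter: float,
    seed_fraction: float = 0.01,
    init: StateVector = DEFAULT_INIT,
    t_end: float = 60.0,
    n_points: int = 1201,
    peak_prominence: float = 0.01,
) -> InterventionResult:
    """Run the model with transmitter entry delayed to ``t_enter``.

    On ``[0, t_enter)`` the transmitter-generating rates (alpha2, beta2,
    epsilon) are zeroed, so any initial transmitter density decays and
    the rumor spreads unopposed.  At ``t_enter`` the full rates are
    restored and ``seed_fraction`` of the current susceptible density is
    moved to the transmitter compartment (density-conserving).  Peak
    statistics are computed over the whole horizon; local maxima of the
    neglected density are counted with the given prominence threshold.

    ``t_enter = 0`` reproduces the unmodified model exactly.
    """
    if t_enter < 0:
        raise ValueError("t_enter must be non-negative")
    if t_enter >= t_end:
        raise ValueError(f"t_enter = {t_enter} must lie inside the horizon [0, {t_end})")
    if not 0.0 <= seed_fraction <= 0.1:
        raise ValueError("seed_fraction must lie in [0, 0.1]")
    if t_enter == 0.0:
        traj = integrate(params, init, t_end, n_points=n_points)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gated = params.with_updates(
                alpha2=1e-12, beta2=1e-12, epsilon=0.0
            )
        n1 = max(2, int(round(n_points * t_enter / t_end)))
        pre = integrate(gated, init, t_enter, n_points=n1)
        switch = pre.states[-1].copy()
        moved = seed_fraction * switch[0]
        switch[0] -= moved
        switch[3] += moved
        post = integrate(
            params,
            StateVector.from_array(switch, tol=1e-6),
            t_end - t_enter,
            n_points=n_points - n1 + 1,
        )
        times = np.concatenate([pre.times, t_enter + post.times[1:]])
        states = np.vstack([pre.states, post.states[1:]])
        traj = Trajectory(times=times, states=states, params=params)
    peaks, _ = find_peaks(traj.n, prominence=peak_prominence)
    return InterventionResult(
        t_enter=float(t_enter),
        max_i=float(traj.i.max()),
        max_t=float(traj.t_dens.max()),
        n_peaks=int(len(peaks)),
        trajectory=traj,
    )
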