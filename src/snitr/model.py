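"""SNITR vector field and deterministic trajectory integration.

The dynamics on densities ``(S, N, I, T, R)`` are

    dS/dt = mu - alpha1*I*S - alpha2*T*S - alpha3*S*N - mu*S
    dN/dt = alpha3*N*S - beta1*I*N - beta2*T*N - beta3*N - mu*N
    dI/dt = alpha1*S*I + beta1*N*I - epsilon*I - gamma1*I - mu*I
    dT/dt = alpha2*S*T + beta2*N*T + epsilon*I - gamma2*T - mu*T
    dR/dt = gamma1*I + gamma2*T + beta3*N - mu*R

The first four equations close on themselves, so analysis works on the
reduced system with ``R = 1 - (S+N+I+T)``.  Summing all five right-hand
sides gives ``mu * (1 - total density)``: the unit simplex is invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import SnitrParameters, StateError, StateVector

__all__ = ["IntegrationError", "Trajectory", "rhs", "rhs_reduced", "integrate"]

#: Allowed conservation drift |S+N+I+T+R - 1| along integrated trajectories.
CONSERVATION_TOL = 1e-6
#: Densities may undershoot/overshoot [0, 1] by this much before clipping.
POSITIVITY_TOL = 1e-9


class IntegrationError(RuntimeError):
    """The ODE solver failed before reaching the end of the horizon."""


def rhs(state, params: SnitrParameters) -> np.ndarray:
    """Time derivative of the full five-compartment system.

    Parameters
    ----------
    state : array-like of 5 floats or StateVector
        Densities ``(S, N, I, T, R)``.  Need not lie on the simplex —
        the identity ``sum(rhs) == mu * (1 - sum(state))`` holds for
        arbitrary finite states.
    params : SnitrParameters

    Returns
    -------
    ndarray of shape (5,) — ``(dS, dN, dI, dT, dR)``.
    """
    if isinstance(state, StateVector):
        state = state.to_array()
    s, n, i, t, r = np.asarray(state, dtype=float)
    if not np.all(np.isfinite([s, n, i, t, r])):
        raise StateError(f"non-finite state passed to rhs: {state}")
    p = params
    ds = p.mu - p.alpha1 * i * s - p.alpha2 * t * s - p.alpha3 * s * n - p.mu * s
    dn = p.alpha3 * n * s - p.beta1 * i * n - p.beta2 * t * n - p.beta3 * n - p.mu * n
    di = p.alpha1 * s * i + p.beta1 * n * i - (p.epsilon + p.gamma1 + p.mu) * i
    dt = p.alpha2 * s * t + p.beta2 * n * t + p.epsilon * i - (p.gamma2 + p.mu) * t
    dr = p.gamma1 * i + p.gamma2 * t + p.beta3 * n - p.mu * r
    return np.array([ds, dn, di, dt, dr])


def rhs_reduced(state4, params: SnitrParameters) -> np.ndarray:
    """Time derivative of the reduced system on ``(S, N, I, T)``.

    Identical to the first four components of :func:`rhs`; the recovered
    density is recoverable as ``1 - (S+N+I+T)`` and never feeds back.
    """
    s, n, i, t = np.asarray(state4, dtype=float)
    if not np.all(np.isfinite([s, n, i, t])):
        raise StateError(f"non-finite state passed to rhs_reduced: {state4}")
    p = params
    return np.array(
        [
            p.mu - p.alpha1 * i * s - p.alpha2 * t * s - p.alpha3 * s * n - p.mu * s,
            p.alpha3 * n * s - p.beta1 * i * n - p.beta2 * t * n - p.beta3 * n - p.mu * n,
            p.alpha1 * s * i + p.beta1 * n * i - (p.epsilon + p.gamma1 + p.mu) * i,
            p.alpha2 * s * t + p.beta2 * n * t + p.epsilon * i - (p.gamma2 + p.mu) * t,
        ]
    )


@dataclass(frozen=True)
class Trajectory:
    """A solution of the SNITR system sampled on a uniform time grid."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 5), columns S,N,I,T,R
    params: SnitrParameters

    def __post_init__(self) -> None:
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape != (len(self.times), 5):
            raise ValueError(
                f"states shape {self.states.shape} does not match grid of "
                f"{len(self.times)} points"
            )

    @property
    def s(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def n(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def i(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def t_dens(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def r(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def i_plus_t(self) -> np.ndarray:
        """Combined rumor-activity signal I(t) + T(t) (the observable
        used for fitting against repost data)."""
        return self.states[:, 2] + self.states[:, 3]

    @property
    def conservation_drift(self) -> float:
        """max over the grid of |S+N+I+T+R - 1|."""
        return float(np.max(np.abs(self.states.sum(axis=1) - 1.0)))

    def endpoint(self) -> StateVector:
        return StateVector.from_array(self.states[-1], tol=1e-6)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "S": self.s,
                "N": self.n,
                "I": self.i,
                "T": self.t_dens,
                "R": self.r,
            }
        )


def integrate(
    params: SnitrParameters,
    init: StateVector,
    t_end: float,
    n_points: int = 2001,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the SNITR system and sample it on a uniform grid.

    Adaptive-step integration (Runge–Kutta by default) with output on
    ``n_points`` equally spaced times in ``[0, t_end]``.  The solution is
    checked against the simplex invariant (conservation drift below
    ``CONSERVATION_TOL``, densities within ``POSITIVITY_TOL`` of
    ``[0, 1]``) and then clipped to ``[0, 1]``.

    Raises
    ------
    IntegrationError
        If the solver fails, reporting the time it reached, or if the
        solution drifts off the simplex beyond tolerance.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda _t, y: rhs(y, params),
        (0.0, t_end),
        init.to_array(),
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        reached = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(
            f"solver {method} failed at t = {reached:.6g}: {sol.message}"
        )
    states = sol.y.T
    drift = np.max(np.abs(states.sum(axis=1) - 1.0))
    if drift > CONSERVATION_TOL:
        raise IntegrationError(
            f"conservation drift {drift:.3g} exceeds {CONSERVATION_TOL:.1g}"
        )
    if states.min() < -POSITIVITY_TOL or states.max() > 1 + POSITIVITY_TOL:
        raise IntegrationError(
            "densities left [0, 1] beyond tolerance: "
            f"min {states.min():.3g}, max {states.max():.3g}"
        )
    return Trajectory(times=times, states=np.clip(states, 0.0, 1.0), params=params)
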