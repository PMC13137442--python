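"""Parameter and state containers for the SNITR rumor-propagation model.

The model tracks five user states on a social network — susceptible (S),
neglected (N), infected (I), transmitter (T) and recovered (R) — as
population densities that sum to one.  Ten rate parameters govern the
flows between compartments; all are proportions per unit time and live
in the unit interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ParameterError",
    "StateError",
    "SnitrParameters",
    "StateVector",
    "PARAM_NAMES",
]

#: Canonical ordering of the rate parameters.
PARAM_NAMES = (
    "mu",
    "alpha1",
    "alpha2",
    "alpha3",
    "beta1",
    "beta2",
    "beta3",
    "gamma1",
    "gamma2",
    "epsilon",
)


class ParameterError(ValueError):
    """A parameter value or combination violates the model constraints."""


class StateError(ValueError):
    """A compartment state violates the simplex constraints."""


@dataclass(frozen=True)
class SnitrParameters:
    """Rate parameters of the SNITR model.

    Parameters
    ----------
    mu : float
        User turnover rate: registration and log-out happen at the same
        constant rate, keeping the population density at one.
    alpha1, alpha2, alpha3 : float
        Proportions of susceptible users converting, on contact with the
        rumor, into infected (believe and spread), transmitter (publicly
        state the truth) and neglected (uncertain attitude) users.
    beta1, beta2, beta3 : float
        Proportions of neglected users converting into infected,
        transmitter and recovered users.
    gamma1 : float
        Proportion of infected users recovering (losing interest).
    gamma2 : float
        Proportion of transmitter users recovering.
    epsilon : float
        Proportion of infected users converting into transmitters after
        recognising the truth.  May be zero (no such conversions).

    Notes
    -----
    Hard constraints (raised at construction): every rate lies in
    ``[0, 1]``, ``mu > 0``, and only ``epsilon`` may be exactly zero.
    Soft constraints (warnings at construction, errors under
    ``validate(strict=True)``): ``alpha1+alpha2+alpha3 <= 1``,
    ``beta1+beta2+beta3 <= 1`` and ``gamma1+epsilon <= 1``.
    """

    mu: float
    alpha1: float
    alpha2: float
    alpha3: float
    beta1: float
    beta2: float
    beta3: float
    gamma1: float
    gamma2: float
    epsilon: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ParameterError(f"{name} must be finite, got {value!r}")
            if not 0.0 <= value <= 1.0:
                raise ParameterError(
                    f"{name} = {value} outside the admissible range [0, 1]"
                )
            if value == 0.0 and name != "epsilon":
                raise ParameterError(f"{name} must be strictly positive")
        for message in self.soft_violations():
            warnings.warn(message, stacklevel=3)

    def soft_violations(self) -> list[str]:
        """Return human-readable descriptions of violated sum constraints."""
        out = []
        if (s := self.alpha1 + self.alpha2 + self.alpha3) > 1.0 + 1e-12:
            out.append(f"sum constraint alpha1+alpha2+alpha3 <= 1 violated ({s:.4g})")
        if (s := self.beta1 + self.beta2 + self.beta3) > 1.0 + 1e-12:
            out.append(f"sum constraint beta1+beta2+beta3 <= 1 violated ({s:.4g})")
        if (s := self.gamma1 + self.epsilon) > 1.0 + 1e-12:
            out.append(f"sum constraint gamma1+epsilon <= 1 violated ({s:.4g})")
        if self.epsilon == 0.0:
            out.append("epsilon = 0: no infected-to-transmitter conversions")
        return out

    def validate(self, strict: bool = True) -> None:
        """Re-check the soft constraints, raising when ``strict``.

        The ``epsilon = 0`` note never raises; it only documents a
        degenerate but admissible configuration.
        """
        for message in self.soft_violations():
            if strict and message.startswith("sum constraint"):
                raise ParameterError(message)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "SnitrParameters":
        missing = [name for name in PARAM_NAMES if name not in data]
        if missing:
            raise ParameterError(f"missing parameter keys: {', '.join(missing)}")
        extra = sorted(set(data) - set(PARAM_NAMES))
        if extra:
            raise ParameterError(f"unknown parameter keys: {', '.join(extra)}")
        return cls(**{name: float(data[name]) for name in PARAM_NAMES})

    def with_updates(self, **updates: float) -> "SnitrParameters":
        """Return a copy with some rates replaced (re-validated)."""
        unknown = sorted(set(updates) - set(PARAM_NAMES))
        if unknown:
            raise ParameterError(f"unknown parameter names: {', '.join(unknown)}")
        return replace(self, **updates)


@dataclass(frozen=True)
class StateVector:
    """Compartment densities ``(S, N, I, T, R)`` at one time point.

    ``t_dens`` names the transmitter density to avoid clashing with time.
    Densities must lie in ``[0, 1]`` and sum to one within ``tol``.
    """

    s: float
    n: float
    i: float
    t_dens: float
    r: float
    tol: float = field(default=1e-9, repr=False, compare=False)

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise StateError(f"non-finite state components: {arr}")
        if np.any(arr < -self.tol) or np.any(arr > 1 + self.tol):
            raise StateError(f"state components outside [0, 1]: {arr}")
        total = float(arr.sum())
        if abs(total - 1.0) > max(self.tol, 1e-9):
            raise StateError(f"state densities sum to {total}, expected 1")

    def to_array(self) -> np.ndarray:
        return np.array([self.s, self.n, self.i, self.t_dens, self.r], dtype=float)

    def to_array4(self) -> np.ndarray:
        """The reduced state ``(S, N, I, T)``; R is the simplex remainder."""
        return np.array([self.s, self.n, self.i, self.t_dens], dtype=float)

    @classmethod
    def from_array(cls, arr, tol: float = 1e-9) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise StateError(f"expected 5 components, got shape {arr.shape}")
        return cls(*arr, tol=tol)

    @classmethod
    def from_array4(cls, arr, tol: float = 1e-9) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (4,):
            raise StateError(f"expected 4 components, got shape {arr.shape}")
        r = 1.0 - float(arr.sum())
        return cls(*arr, r, tol=tol)


#: Initial condition used throughout the simulation studies: most users
#: susceptible, small seeds of neglected/infected/transmitter users.
DEFAULT_INIT = StateVector(0.90, 0.04, 0.04, 0.02, 0.0)
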