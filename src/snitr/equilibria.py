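"""Steady states of the reduced SNITR system.

Two routes to an equilibrium are provided and deliberately kept apart:

* :func:`closed_form_equilibria` evaluates the published closed-form
  candidate points E0–E6, one per compartment-occupancy pattern (which
  of N, I, T are nonzero).  Several of the printed expressions for the
  higher points contain algebraic defects, so every candidate carries a
  residual diagnostic — the max-norm of the vector field at the point.
* :func:`find_equilibrium_numeric` finds genuine roots of the reduced
  vector field by damped Newton/hybrid iteration; these are the source
  of truth.

:func:`consistency_report` confronts the two: for each closed-form
candidate it reports whether it actually annihilates the vector field
and how far it sits from the nearest numerically confirmed root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import rhs_reduced
from .params import SnitrParameters

__all__ = [
    "EquilibriumPoint",
    "closed_form_equilibria",
    "find_equilibrium_numeric",
    "find_all_numeric",
    "consistency_report",
    "FEASIBILITY_TOL",
]

#: Components within this distance of [0, 1] still count as feasible.
FEASIBILITY_TOL = 1e-9
#: Residual below which a numeric root is accepted.
ROOT_TOL = 1e-10


@dataclass(frozen=True)
class EquilibriumPoint:
    """A candidate steady state of the reduced system.

    ``residual`` is the max-norm of the reduced vector field at the
    point; ``feasible`` means every component lies in ``[0, 1]`` (within
    :data:`FEASIBILITY_TOL`).  ``defined`` is False when a closed-form
    expression hits a zero denominator.  ``source`` records whether the
    point came from the printed formulas or the root-finder.
    """

    label: str
    s: float
    n: float
    i: float
    t_dens: float
    source: str  # "closed_form" | "numeric"
    residual: float = np.nan
    feasible: bool = False
    defined: bool = True
    converged: bool = True

    def to_array(self) -> np.ndarray:
        return np.array([self.s, self.n, self.i, self.t_dens], dtype=float)


def _make_point(
    label: str,
    coords,
    params: SnitrParameters,
    source: str,
    converged: bool = True,
) -> EquilibriumPoint:
    coords = np.asarray(coords, dtype=float)
    defined = bool(np.all(np.isfinite(coords)))
    if defined:
        residual = float(np.max(np.abs(rhs_reduced(coords, params))))
        feasible = bool(
            np.all(coords >= -FEASIBILITY_TOL) and np.all(coords <= 1 + FEASIBILITY_TOL)
        )
        coords = np.clip(coords, 0.0, 1.0) if feasible else coords
    else:
        residual, feasible = np.nan, False
    return EquilibriumPoint(
        label, *coords, source=source, residual=residual,
        feasible=feasible, defined=defined, converged=converged,
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0.0 else np.nan


def closed_form_equilibria(params: SnitrParameters) -> list[EquilibriumPoint]:
    """Evaluate the published closed-form candidates E0–E6.

    The expressions are transcribed as printed (including their known
    defects for the coexistence points); each returned point carries the
    residual of the reduced vector field, so a candidate that is not a
    genuine root is immediately visible.  Zero denominators give a point
    with ``defined=False`` rather than raising.
    """
    p = params
    pts = [_make_point("E0", (1.0, 0.0, 0.0, 0.0), p, "closed_form")]

    # E1: transmitters only (N = I = 0)
    s1 = _safe_div(p.gamma2 + p.mu, p.alpha2)
    t1 = _safe_div(p.mu, p.gamma2 + p.mu) - _safe_div(p.mu, p.alpha2)
    pts.append(_make_point("E1", (s1, 0.0, 0.0, t1), p, "closed_form"))

    # E2: infected only (N = T = 0); printed with alpha2/gamma2 rates
    s2 = _safe_div(p.gamma2 + p.mu, p.alpha2)
    i2 = _safe_div(
        p.mu * (p.alpha2 - p.gamma2 - p.mu), p.alpha2 * (p.gamma2 + p.mu)
    )
    pts.append(_make_point("E2", (s2, 0.0, i2, 0.0), p, "closed_form"))

    # E3: neglected only (I = T = 0)
    s3 = _safe_div(p.beta3 + p.mu, p.alpha3)
    n3 = _safe_div(p.mu * (p.alpha3 - p.beta3 - p.mu), p.alpha3 * (p.beta3 + p.mu))
    pts.append(_make_point("E3", (s3, n3, 0.0, 0.0), p, "closed_form"))

    # E4: infected and transmitters coexist (N = 0)
    s4 = _safe_div(p.epsilon + p.gamma1 + p.mu, p.alpha1)
    den4 = p.alpha1 * (p.gamma2 + p.mu - p.alpha2 * s4) + p.alpha2 * p.epsilon
    common4 = _safe_div(p.mu * (1.0 - s4), s4) if s4 not in (0.0,) else np.nan
    i4 = common4 * _safe_div(p.gamma2 + p.mu - p.alpha2 * s4, den4)
    t4 = common4 * _safe_div(p.epsilon, den4)
    pts.append(_make_point("E4", (s4, 0.0, i4, t4), p, "closed_form"))

    # E5: neglected and transmitters coexist (I = 0)
    den5 = (
        p.alpha3 * p.gamma2 + p.alpha3 * p.mu + p.mu * p.beta2
        - p.alpha2 * p.beta3 - p.alpha2 * p.mu
    )
    s5 = _safe_div(p.mu * p.beta2, den5)
    n5 = _safe_div(p.gamma2 + p.mu - p.alpha2 * s5, p.beta2)
    t5 = _safe_div(p.alpha3 * s5 - p.beta3 - p.mu, p.beta2)
    pts.append(_make_point("E5", (s5, n5, 0.0, t5), p, "closed_form"))

    # E6: all three compartments coexist — printed with unsubscripted
    # S, N in the N6/T6/I6 lines; transcribed with S6, N6 substituted.
    den6 = p.beta1 * p.alpha2 - p.beta2 * p.alpha1 + p.epsilon * p.alpha3
    s6 = _safe_div(
        p.epsilon * (p.beta3 + p.mu + p.beta2)
        + p.beta1 * (p.gamma2 + p.mu)
        - p.beta2 * (p.epsilon + p.gamma1 + p.mu),
        den6,
    )
    n6 = _safe_div(p.epsilon + p.gamma1 + p.mu - p.alpha1 * s6, p.beta1)
    t6 = (
        p.epsilon * p.beta1 * (p.gamma2 + p.mu - p.alpha2 * s6 - p.beta2 * n6)
        + p.beta2 * p.epsilon * (p.alpha3 * s6 - p.beta3 - p.mu)
    )
    i6 = _safe_div(p.gamma2 + p.mu - p.alpha2 * s6 - p.beta2 * n6, p.epsilon) * t6
    pts.append(_make_point("E6", (s6, n6, i6, t6), p, "closed_form"))
    return pts


def find_equilibrium_numeric(
    params: SnitrParameters,
    guess,
    tol: float = ROOT_TOL,
    label: str | None = None,
) -> EquilibriumPoint:
    """Find a root of the reduced vector field near ``guess``.

    Returns a point with ``source="numeric"``; ``converged`` is False
    (and the residual reported as-is) when the solver fails to push the
    residual below ``tol``.
    """
    guess = np.asarray(guess, dtype=float)
    if guess.shape != (4,):
        raise ValueError(f"guess must have 4 components, got shape {guess.shape}")
    if np.any(guess < 0) or np.any(guess > 1):
        raise ValueError(f"guess must lie in [0, 1]^4, got {guess}")
    sol = root(lambda x: rhs_reduced(x, params), guess, method="hybr", tol=1e-13)
    residual = float(np.max(np.abs(rhs_reduced(sol.x, params))))
    converged = bool(sol.success) and residual < tol
    point = _make_point(
        label or "numeric", sol.x, params, "numeric", converged=converged
    )
    return point


def _occupancy_label(point: np.ndarray, zero_tol: float = 1e-6) -> str:
    """Label a root by which of N, I, T are (numerically) nonzero,
    matching the occupancy patterns of the published E0–E6."""
    n, i, t = (abs(point[1]) > zero_tol, abs(point[2]) > zero_tol,
               abs(point[3]) > zero_tol)
    return {
        (False, False, False): "E0",
        (False, False, True): "E1",
        (False, True, False): "E2",
        (True, False, False): "E3",
        (False, True, True): "E4",
        (True, False, True): "E5",
        (True, True, True): "E6",
    }[(n, i, t)]


def find_all_numeric(
    params: SnitrParameters,
    n_grid: int = 5,
    tol: float = ROOT_TOL,
    dedup_tol: float = 1e-6,
) -> list[EquilibriumPoint]:
    """Multi-start root search over a simplex grid plus the closed-form
    candidates; distinct feasible roots, labeled by occupancy pattern."""
    guesses = [np.array([1.0, 0.0, 0.0, 0.0])]
    grid = np.linspace(0.05, 0.9, n_grid)
    for s in grid:
        for x in (0.0, 0.1, 0.3):
            for pattern in ((x, 0, 0), (0, x, 0), (0, 0, x), (x, x, x)):
                g = np.array([s, *pattern], dtype=float)
                if g.sum() <= 1.0:
                    guesses.append(g)
    for cf in closed_form_equilibria(params):
        if cf.defined and cf.feasible:
            guesses.append(np.clip(cf.to_array(), 0, 1))
    roots: list[EquilibriumPoint] = []
    for g in guesses:
        pt = find_equilibrium_numeric(params, g, tol=tol)
        if not (pt.converged and pt.feasible):
            continue
        arr = pt.to_array()
        if any(np.max(np.abs(arr - r.to_array())) < dedup_tol for r in roots):
            continue
        roots.append(
            EquilibriumPoint(
                _occupancy_label(arr), *arr, source="numeric",
                residual=pt.residual, feasible=True,
            )
        )
    return roots


def consistency_report(params: SnitrParameters, residual_tol: float = 1e-8) -> pd.DataFrame:
    """Confront each defined closed-form candidate with the numeric roots.

    Returns one row per defined closed-form point with its coordinates,
    residual, whether it is a genuine root of the reduced system
    (residual below ``residual_tol``), and the max-norm distance to the
    nearest numerically confirmed root (NaN when no root was found).
    """
    numeric = find_all_numeric(params)
    rows = []
    for cf in closed_form_equilibria(params):
        if not cf.defined:
            continue
        arr = cf.to_array()
        if numeric:
            dists = [float(np.max(np.abs(arr - r.to_array()))) for r in numeric]
            k = int(np.argmin(dists))
            nearest, dist = numeric[k].label, dists[k]
        else:
            nearest, dist = None, np.nan
        rows.append(
            {
                "label": cf.label,
                "S": cf.s,
                "N": cf.n,
                "I": cf.i,
                "T": cf.t_dens,
                "feasible": cf.feasible,
                "residual": cf.residual,
                "is_root": bool(cf.residual < residual_tol),
                "nearest_numeric": nearest,
                "distance": dist,
            }
        )
    return pd.DataFrame(rows)
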