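"""Reproduction numbers, local stability, and empirical global stability.

The threshold analysis follows the next-generation-matrix construction:
linearising the rumor-bearing compartments (I, T, N) at the rumor-free
state splits the dynamics into new "infections" F and transitions V, and
the spectral radius of K = F V^-1 gives the outbreak threshold.  K is
lower-triangular here, so its eigenvalues are the three diagonal ratios

    R01 = alpha1 / (epsilon + gamma1 + mu)     (infected pathway)
    R02 = alpha2 / (gamma2 + mu)               (transmitter pathway)
    R03 = alpha3 / (beta3 + mu)                (neglected pathway)

Local stability at an equilibrium is read off the eigenvalues of the
analytic Jacobian of the reduced system, cross-checked against the
Routh–Hurwitz determinants of the characteristic polynomial.  Global
convergence to the rumor-free state is checked empirically by
integrating from many random starts on the simplex and monitoring a
quadratic Lyapunov-style distance function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import EquilibriumPoint, FEASIBILITY_TOL
from .model import integrate, rhs_reduced
from .params import SnitrParameters, StateVector

__all__ = [
    "ReproductionNumbers",
    "NextGenMatrices",
    "CharPoly",
    "StabilityReport",
    "reproduction_numbers",
    "next_generation_matrices",
    "jacobian",
    "char_poly",
    "hurwitz_determinants",
    "classify_stability",
    "global_convergence_check",
    "GlobalCheckResult",
]


@dataclass(frozen=True)
class ReproductionNumbers:
    """The three pathway reproduction numbers and their maximum."""

    r01: float
    r02: float
    r03: float

    @property
    def r0(self) -> float:
        return max(self.r01, self.r02, self.r03)

    def all_below_one(self) -> bool:
        return self.r0 < 1.0


def reproduction_numbers(params: SnitrParameters) -> ReproductionNumbers:
    """Closed-form reproduction numbers of the three spreading pathways."""
    p = params
    d1 = p.epsilon + p.gamma1 + p.mu
    d2 = p.gamma2 + p.mu
    d3 = p.beta3 + p.mu
    for name, d in (("epsilon+gamma1+mu", d1), ("gamma2+mu", d2), ("beta3+mu", d3)):
        if d == 0.0:
            raise ZeroDivisionError(f"reproduction-number denominator {name} is zero")
    return ReproductionNumbers(p.alpha1 / d1, p.alpha2 / d2, p.alpha3 / d3)


@dataclass(frozen=True)
class NextGenMatrices:
    """New-infection matrix F, transition matrix V and K = F V^-1 at the
    rumor-free state, in compartment order (I, T, N)."""

    f_matrix: np.ndarray
    v_matrix: np.ndarray
    k_matrix: np.ndarray


def next_generation_matrices(params: SnitrParameters) -> NextGenMatrices:
    """Build F, V and K = F V^-1 at the rumor-free equilibrium.

    K is lower-triangular with diagonal (R01, R02, R03) and a single
    off-diagonal entry alpha2*epsilon / ((epsilon+gamma1+mu)(gamma2+mu))
    coupling the infected pathway into the transmitter one.
    """
    p = params
    f = np.diag([p.alpha1, p.alpha2, p.alpha3])
    v = np.array(
        [
            [p.epsilon + p.gamma1 + p.mu, 0.0, 0.0],
            [-p.epsilon, p.gamma2 + p.mu, 0.0],
            [0.0, 0.0, p.beta3 + p.mu],
        ]
    )
    det = np.linalg.det(v)
    if abs(det) < 1e-300:
        raise np.linalg.LinAlgError("transition matrix V is singular")
    k = f @ np.linalg.inv(v)
    return NextGenMatrices(f_matrix=f, v_matrix=v, k_matrix=k)


def _point_array(point) -> np.ndarray:
    if isinstance(point, EquilibriumPoint):
        return point.to_array()
    if isinstance(point, StateVector):
        return point.to_array4()
    arr = np.asarray(point, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"expected a 4-component point, got shape {arr.shape}")
    return arr


def jacobian(params: SnitrParameters, point) -> np.ndarray:
    """Analytic 4x4 Jacobian of the reduced vector field at a point.

    Differentiated directly from the vector field (the dynamics are
    bilinear, so the entries are exact).
    """
    s, n, i, t = _point_array(point)
    if np.any([c < -FEASIBILITY_TOL or c > 1 + FEASIBILITY_TOL for c in (s, n, i, t)]):
        raise ValueError(f"point components must lie in [0, 1]: {(s, n, i, t)}")
    p = params
    return np.array(
        [
            [
                -p.alpha1 * i - p.alpha2 * t - p.alpha3 * n - p.mu,
                -p.alpha3 * s,
                -p.alpha1 * s,
                -p.alpha2 * s,
            ],
            [
                p.alpha3 * n,
                p.alpha3 * s - p.beta1 * i - p.beta2 * t - p.beta3 - p.mu,
                -p.beta1 * n,
                -p.beta2 * n,
            ],
            [
                p.alpha1 * i,
                p.beta1 * i,
                p.alpha1 * s + p.beta1 * n - p.epsilon - p.gamma1 - p.mu,
                0.0,
            ],
            [
                p.alpha2 * t,
                p.beta2 * t,
                p.epsilon,
                p.alpha2 * s + p.beta2 * n - p.gamma2 - p.mu,
            ],
        ]
    )


@dataclass(frozen=True)
class CharPoly:
    """Coefficients of lambda^4 + a3 l^3 + a2 l^2 + a1 l + a0."""

    a3: float
    a2: float
    a1: float
    a0: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a3, self.a2, self.a1, self.a0)


def char_poly(matrix: np.ndarray) -> CharPoly:
    """Characteristic polynomial (monic, degree 4) of a real 4x4 matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {matrix.shape}")
    coeffs = np.poly(matrix)  # [1, a3, a2, a1, a0]
    return CharPoly(*[float(c) for c in coeffs[1:]])


def hurwitz_determinants(cp: CharPoly) -> tuple[float, float, float, float]:
    """Routh–Hurwitz determinants of a monic quartic.

    All four positive iff every root has negative real part:
    D1 = a3, D2 = a3 a2 - a1, D3 = a3 a2 a1 - a3^2 a0 - a1^2, D4 = a0 D3.
    """
    a3, a2, a1, a0 = cp.as_tuple()
    d1 = a3
    d2 = a3 * a2 - a1
    d3 = a3 * a2 * a1 - a3**2 * a0 - a1**2
    d4 = a0 * d3
    return (d1, d2, d3, d4)


@dataclass(frozen=True)
class StabilityReport:
    """Local stability diagnosis at an equilibrium point."""

    point: EquilibriumPoint
    eigenvalues: np.ndarray
    char_poly: CharPoly
    hurwitz: tuple[float, float, float, float]
    classification: str  # "stable" | "unstable" | "marginal"
    reproduction: ReproductionNumbers
    hurwitz_agrees: bool


def classify_stability(
    params: SnitrParameters,
    point,
    force: bool = False,
    eig_tol: float = 1e-9,
    residual_tol: float = 1e-8,
) -> StabilityReport:
    """Eigenvalue-based local stability at an equilibrium.

    The point must be a genuine equilibrium (reduced-field residual
    below ``residual_tol``) unless ``force`` is set.  Classification is
    "stable" when every eigenvalue real part is below ``-eig_tol``,
    "unstable" when some real part exceeds ``+eig_tol``, and "marginal"
    in the band between.  The Routh–Hurwitz determinants provide an
    independent cross-check, reported as ``hurwitz_agrees``.
    """
    arr = _point_array(point)
    residual = float(np.max(np.abs(rhs_reduced(arr, params))))
    if residual > residual_tol and not force:
        raise ValueError(
            f"point residual {residual:.3g} exceeds {residual_tol:.1g}; "
            "not an equilibrium (pass force=True to classify anyway)"
        )
    if not isinstance(point, EquilibriumPoint):
        point = EquilibriumPoint(
            "point", *arr, source="numeric", residual=residual,
            feasible=bool(np.all((arr >= -FEASIBILITY_TOL) & (arr <= 1 + FEASIBILITY_TOL))),
        )
    jac = jacobian(params, arr)
    eig = np.linalg.eigvals(jac)
    re = eig.real
    if np.all(re < -eig_tol):
        classification = "stable"
    elif np.any(re > eig_tol):
        classification = "unstable"
    else:
        classification = "marginal"
    cp = char_poly(jac)
    hur = hurwitz_determinants(cp)
    all_hurwitz_pos = all(d > 0 for d in hur)
    hurwitz_agrees = (
        classification == "marginal" or all_hurwitz_pos == (classification == "stable")
    )
    return StabilityReport(
        point=point,
        eigenvalues=eig,
        char_poly=cp,
        hurwitz=hur,
        classification=classification,
        reproduction=reproduction_numbers(params),
        hurwitz_agrees=hurwitz_agrees,
    )


@dataclass(frozen=True)
class GlobalCheckResult:
    """Outcome of the multi-start convergence check toward the
    rumor-free state."""

    fraction_converged: float
    n_starts: int
    lyapunov_eventually_decreasing: float
    distances: np.ndarray


def _random_simplex_starts(n: int, rng: np.random.Generator) -> np.ndarray:
    # Dirichlet(1,...,1) is uniform on the 5-simplex; keep (S,N,I,T).
    return rng.dirichlet(np.ones(5), size=n)


def global_convergence_check(
    params: SnitrParameters,
    n_starts: int = 50,
    seed: int = 0,
    t_end: float = 400.0,
    k0: float = 1.0,
    k1: float = 1.0,
    dist_tol: float = 1e-4,
    starts: np.ndarray | None = None,
) -> GlobalCheckResult:
    """Empirical check of global convergence to the rumor-free state.

    Integrates from ``n_starts`` seeded uniform draws on the density
    simplex and reports the fraction whose reduced state ends within
    ``dist_tol`` (max-norm) of (1, 0, 0, 0).  Along each trajectory the
    quadratic distance function ``0.5*(k0*I^2 + k1*(1-S)^2)`` — the
    distance-to-equilibrium analogue of the Lyapunov candidate
    ``0.5*(k0*I^2 + k1*S^2)`` — is evaluated, and the fraction of
    trajectories on which it is non-increasing over the final half of
    the horizon is reported.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    if starts is None:
        rng = np.random.default_rng(seed)
        starts = _random_simplex_starts(n_starts, rng)
    else:
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
        n_starts = len(starts)
    target = np.array([1.0, 0.0, 0.0, 0.0])
    distances = np.empty(n_starts)
    decreasing = 0
    for j, full in enumerate(starts):
        traj = integrate(params, StateVector.from_array(full), t_end, n_points=801)
        distances[j] = np.max(np.abs(traj.states[-1, :4] - target))
        v = 0.5 * (k0 * traj.i**2 + k1 * (1.0 - traj.s) ** 2)
        tail = v[len(v) // 2:]
        if np.all(np.diff(tail) <= 1e-12):
            decreasing += 1
    return GlobalCheckResult(
        fraction_converged=float(np.mean(distances < dist_tol)),
        n_starts=n_starts,
        lyapunov_eventually_decreasing=decreasing / n_starts,
        distances=distances,
    )
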