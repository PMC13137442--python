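"""Least-squares estimation of SNITR rates from a binned I+T series.

The observable is the combined density of infected and transmitter
users — the model analogue of binned repost counts divided by the
engaged population.  Estimation minimises the sum of squared residuals
between the model's I(t)+T(t) and the observations over a fitting
window, with every rate box-bounded to [0.001, 0.999], via bounded
trust-region least squares restarted from seeded Latin-hypercube draws.

The initial compartment state is co-estimated on the density simplex
through a stick-breaking parameterisation (S0 first, then N0, I0, T0
as fractions of what remains; R0 is the remainder), unless pinned.

"Fit coefficient" here is the coefficient of determination

    R^2 = 1 - SS_res / SS_tot

computed on a stated window (fitting or validation).  With only the
I+T aggregate observed the ten-rate model is not fully identifiable, so
quality is judged on curve recovery, not on recovering individual rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import Trajectory, rhs
from .params import PARAM_NAMES, SnitrParameters, StateVector

__all__ = [
    "ObservedSeries",
    "FitConfig",
    "FitResult",
    "fit_snitr",
    "goodness_of_fit",
    "fit_and_validate",
]


@dataclass(frozen=True)
class ObservedSeries:
    """A binned I+T observation series with window metadata.

    ``values`` are densities (counts already divided by ``population``).
    ``times`` are bin midpoints and must be strictly increasing.  The
    fitting window is ``[0, fit_window_end]``; the validation window is
    ``(fit_window_end, validation_end]``.
    """

    times: np.ndarray
    values: np.ndarray
    bin_width: float
    fit_window_end: float
    validation_end: float
    population: int = 12_372

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("observed densities must be non-negative")
        if not self.fit_window_end < self.validation_end:
            raise ValueError("fit_window_end must precede validation_end")

    @property
    def fit_mask(self) -> np.ndarray:
        return self.times <= self.fit_window_end

    @property
    def validation_mask(self) -> np.ndarray:
        return (self.times > self.fit_window_end) & (self.times <= self.validation_end)


@dataclass(frozen=True)
class FitConfig:
    """Controls for the multi-start bounded least-squares fit.

    ``n_samples`` Latin-hypercube candidates are screened by objective
    value; the best ``n_starts`` are refined with bounded trust-region
    least squares (``max_nfev`` objective evaluations each); the best
    refined start is then polished in two stages with progressively
    smaller finite-difference steps (``polish_max_nfev`` each).  The
    finite-difference step must stay well above the relative integration
    tolerance or the gradients drown in solver noise — hence the fairly
    tight ``rtol`` default.
    """

    bounds: tuple[float, float] = (0.001, 0.999)
    n_starts: int = 16
    n_samples: int = 64  # Latin-hypercube candidates screened before refinement
    seed: int = 1234
    fixed_params: dict[str, float] | None = None
    pinned_init: StateVector | None = None
    rtol: float = 1e-8
    atol: float = 1e-10
    diff_step: float = 1e-6
    max_nfev: int = 300
    polish: bool = True
    polish_max_nfev: int = 1500


@dataclass(frozen=True)
class FitResult:
    """Best fit over all starts."""

    params_hat: SnitrParameters
    init_hat: StateVector
    rss: float
    fit_coefficient: float  # R^2 on the fitting window
    n_starts: int
    seed: int
    converged: bool
    predicted: Trajectory = field(repr=False)
    start_objectives: np.ndarray = field(repr=False)


def goodness_of_fit(predicted, observed) -> float:
    """Coefficient of determination R^2 = 1 - SS_res/SS_tot."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be 1-D arrays of equal length")
    if len(observed) < 2:
        raise ValueError("need at least 2 points to score a fit")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed series has zero variance; R^2 undefined")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _simulate_i_plus_t(
    params_vec: np.ndarray,
    init5: np.ndarray,
    times: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Model I+T at the requested times; large residual signal on failure."""
    mu, a1, a2, a3, b1, b2, b3, g1, g2, eps = (float(v) for v in params_vec)

    def field(_t, y):
        s, n, i, t, r = y
        return (
            mu - a1 * i * s - a2 * t * s - a3 * s * n - mu * s,
            a3 * n * s - b1 * i * n - b2 * t * n - b3 * n - mu * n,
            a1 * s * i + b1 * n * i - (eps + g1 + mu) * i,
            a2 * s * t + b2 * n * t + eps * i - (g2 + mu) * t,
            g1 * i + g2 * t + b3 * n - mu * r,
        )

    sol = solve_ivp(
        field,
        (0.0, float(times[-1])),
        init5,
        method="RK45",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or sol.y.shape[1] != len(times):
        return np.full(len(times), 1e3)
    return sol.y[2] + sol.y[3]


def _sticks_to_init(sticks: np.ndarray) -> np.ndarray:
    """Stick-breaking map [0,1]^4 -> (S,N,I,T,R) on the simplex."""
    s0 = sticks[0]
    n0 = (1 - s0) * sticks[1]
    i0 = (1 - s0 - n0) * sticks[2]
    t0 = (1 - s0 - n0 - i0) * sticks[3]
    r0 = 1 - s0 - n0 - i0 - t0
    return np.array([s0, n0, i0, t0, max(r0, 0.0)])


def _init_to_sticks(init: StateVector) -> np.ndarray:
    arr = init.to_array()
    sticks = np.empty(4)
    rem = 1.0
    for k in range(4):
        sticks[k] = arr[k] / rem if rem > 1e-12 else 0.0
        rem -= arr[k]
    return np.clip(sticks, 0.0, 1.0)


def fit_snitr(observed: ObservedSeries, config: FitConfig = FitConfig()) -> FitResult:
    """Estimate rates (and optionally the initial state) from an I+T series.

    Screens ``n_samples`` seeded Latin-hypercube candidates by their
    residual sum of squares, refines the best ``n_starts`` of them with
    bounded least squares, and returns the best refined fit.  The result
    is deterministic given the config seed.  If no start converges, the
    best partial result is returned with ``converged=False``.
    """
    fit_times = observed.times[observed.fit_mask]
    fit_values = observed.values[observed.fit_mask]
    if len(fit_times) < 20:
        raise ValueError(
            f"need at least 20 observations in the fitting window, got {len(fit_times)}"
        )
    lo, hi = config.bounds
    fixed = dict(config.fixed_params or {})
    unknown = sorted(set(fixed) - set(PARAM_NAMES))
    if unknown:
        raise ValueError(f"fixed_params refers to unknown rates: {unknown}")
    free_names = [n for n in PARAM_NAMES if n not in fixed]
    estimate_init = config.pinned_init is None
    n_free = len(free_names) + (4 if estimate_init else 0)

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pv = np.empty(len(PARAM_NAMES))
        for k, name in enumerate(PARAM_NAMES):
            pv[k] = fixed[name] if name in fixed else theta[free_names.index(name)]
        if estimate_init:
            init5 = _sticks_to_init(theta[len(free_names):])
        else:
            init5 = config.pinned_init.to_array()
        return pv, init5

    def residuals(theta: np.ndarray) -> np.ndarray:
        pv, init5 = unpack(theta)
        return _simulate_i_plus_t(pv, init5, fit_times, config.rtol, config.atol) - fit_values

    sampler = qmc.LatinHypercube(d=n_free, seed=config.seed)
    candidates = sampler.random(config.n_samples)
    # rates live in the box; init sticks use the full unit cube
    thetas = np.empty_like(candidates)
    thetas[:, : len(free_names)] = lo + (hi - lo) * candidates[:, : len(free_names)]
    if estimate_init:
        thetas[:, len(free_names):] = candidates[:, len(free_names):]
    start_rss = np.array([float(np.sum(residuals(t) ** 2)) for t in thetas])
    order = np.argsort(start_rss)[: config.n_starts]

    lower = np.concatenate(
        [np.full(len(free_names), lo), np.zeros(4)] if estimate_init
        else [np.full(len(free_names), lo)]
    )
    upper = np.concatenate(
        [np.full(len(free_names), hi), np.ones(4)] if estimate_init
        else [np.full(len(free_names), hi)]
    )
    def refine(theta0, diff_step, max_nfev):
        return least_squares(
            residuals,
            theta0,
            bounds=(lower, upper),
            method="trf",
            x_scale="jac",
            diff_step=diff_step,
            xtol=3e-16,
            ftol=3e-16,
            gtol=1e-15,
            max_nfev=max_nfev,
        )

    best_theta, best_rss, any_converged = None, np.inf, False
    for idx in order:
        try:
            res = refine(thetas[idx], config.diff_step, config.max_nfev)
        except Exception:  # solver blow-up on a pathological start
            continue
        rss = float(2 * res.cost)
        if rss < best_rss:
            best_theta, best_rss = res.x, rss
            any_converged = any_converged or bool(res.success)
    if best_theta is None:  # every refinement failed; fall back to screening
        best_theta = thetas[order[0]]
        best_rss = float(start_rss[order[0]])
    elif config.polish:
        # deepen convergence along the objective's flat valley with
        # progressively smaller finite-difference steps
        for step in (config.diff_step, config.diff_step / 10):
            try:
                res = refine(best_theta, step, config.polish_max_nfev)
            except Exception:
                break
            rss = float(2 * res.cost)
            if rss <= best_rss:
                best_theta, best_rss = res.x, rss
    pv, init5 = unpack(best_theta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params_hat = SnitrParameters(**dict(zip(PARAM_NAMES, pv)))
    init_hat = StateVector.from_array(np.clip(init5, 0, 1), tol=1e-6)
    horizon = max(observed.validation_end, float(observed.times[-1]))
    grid = np.linspace(0.0, horizon, 1301)
    sol = solve_ivp(
        lambda _t, y: rhs(y, params_hat),
        (0.0, horizon),
        init_hat.to_array(),
        method="RK45",
        t_eval=grid,
        rtol=1e-8,
        atol=1e-10,
    )
    predicted = Trajectory(times=grid, states=np.clip(sol.y.T, 0, 1), params=params_hat)
    model_fit = _simulate_i_plus_t(pv, init5, fit_times, 1e-8, 1e-10)
    return FitResult(
        params_hat=params_hat,
        init_hat=init_hat,
        rss=best_rss,
        fit_coefficient=goodness_of_fit(model_fit, fit_values),
        n_starts=int(len(order)),
        seed=config.seed,
        converged=any_converged,
        predicted=predicted,
        start_objectives=start_rss[order],
    )


def fit_and_validate(
    observed: ObservedSeries, config: FitConfig = FitConfig()
) -> dict:
    """Fit on the fitting window, then score R^2 on the held-out window.

    Returns ``{"fit": FitResult, "validation_fit_coefficient": float}``.
    """
    if not np.any(observed.validation_mask):
        raise ValueError("validation window contains no observations")
    fit = fit_snitr(observed, config)
    val_times = observed.times[observed.validation_mask]
    val_values = observed.values[observed.validation_mask]
    pv = np.array([getattr(fit.params_hat, n) for n in PARAM_NAMES])
    predicted = _simulate_i_plus_t(pv, fit.init_hat.to_array(), val_times, 1e-8, 1e-10)
    return {
        "fit": fit,
        "validation_fit_coefficient": goodness_of_fit(predicted, val_values),
    }
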