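"""Synthetic binned repost series from known SNITR ground truth.

Emulates the structure of the real validation data — repost counts of
rumor posts aggregated into 10-minute bins over 65 hours, split into a
30-hour fitting window and a 35-hour validation window, from an engaged
population of 12,372 reposting users — so the fitting pipeline is fully
testable without any external download.  Model time maps to hours 1:1
by default (the model itself is dimensionless).

Count noise options:

``"none"``
    Exact model densities at bin midpoints.
``"poisson"``
    Counts drawn as Poisson(population * density), rescaled to density.
``"gaussian"``
    Additive zero-mean Gaussian noise on the density, clipped at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .fitting import ObservedSeries
from .model import IntegrationError, Trajectory, rhs
from .params import DEFAULT_INIT, SnitrParameters, StateVector
from .presets import FIT_TRUTH, PRESETS, SWEEPS

__all__ = ["GeneratorConfig", "generate_series", "make_fixture_suite"]

#: Fraction of the horizon used for fitting (30 h of 65 h).
FIT_FRACTION = 30.0 / 65.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and observation design for one synthetic series."""

    params: SnitrParameters = field(default_factory=lambda: FIT_TRUTH)
    init: StateVector = DEFAULT_INIT
    population: int = 12_372
    bin_width: float = 1.0 / 6.0  # 10-minute bins, hours as time unit
    duration: float = 65.0
    noise: str = "none"  # "none" | "poisson" | "gaussian"
    noise_scale: float = 0.01  # std of the gaussian option, density units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.population < 1:
            raise ValueError("population must be at least 1")
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def generate_series(config: GeneratorConfig) -> tuple[ObservedSeries, Trajectory]:
    """Integrate the ground truth and sample noisy I+T at bin midpoints.

    Returns the observed series together with the ground-truth
    trajectory (sampled on a fine uniform grid over the same horizon).
    The fitting window ends at ``FIT_FRACTION * duration``; validation
    runs to ``duration``.  Identical configs (including seed) give
    identical output.
    """
    n_bins = int(np.floor(config.duration / config.bin_width))
    if n_bins < 2:
        raise ValueError("duration must cover at least two bins")
    midpoints = (np.arange(n_bins) + 0.5) * config.bin_width
    # one integration sampled on the union of a fine uniform grid and the
    # bin midpoints, so the returned trajectory contains the midpoints
    # exactly (noiseless values match it to machine precision)
    fine = np.linspace(0.0, config.duration, max(2001, 4 * n_bins + 1))
    grid = np.unique(np.concatenate([fine, midpoints]))
    sol = solve_ivp(
        lambda _t, y: rhs(y, config.params),
        (0.0, config.duration),
        config.init.to_array(),
        method="RK45",
        t_eval=grid,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise IntegrationError(f"ground-truth integration failed: {sol.message}")
    traj = Trajectory(times=grid, states=np.clip(sol.y.T, 0.0, 1.0), params=config.params)
    idx = np.searchsorted(grid, midpoints)
    exact = traj.i_plus_t[idx]
    rng = np.random.default_rng(config.seed)
    if config.noise == "none":
        values = exact
    elif config.noise == "poisson":
        counts = rng.poisson(config.population * exact)
        values = counts / config.population
    else:
        values = np.clip(exact + rng.normal(0.0, config.noise_scale, n_bins), 0.0, None)
    series = ObservedSeries(
        times=midpoints,
        values=values,
        bin_width=config.bin_width,
        fit_window_end=FIT_FRACTION * config.duration,
        validation_end=config.duration,
        population=config.population,
    )
    return series, traj


def make_fixture_suite(out_dir) -> list[Path]:
    """Write the canonical parameter and series fixtures used by tests.

    Emits one JSON file per preset configuration (including the sweep
    bases and the data-derived ground truth), a noiseless series and a
    Poisson-noise series generated from the ground truth, each with a
    JSON sidecar of window metadata.  Regeneration is byte-identical.
    """
    from .io import save_params, write_series

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    all_params = {**PRESETS, "fit_truth": FIT_TRUTH}
    all_params.update({f"sweep_{k}_base": v.base for k, v in SWEEPS.items()})
    for name, p in sorted(all_params.items()):
        path = out / f"params_{name}.json"
        save_params(p, path)
        written.append(path)
    for label, noise in (("noiseless", "none"), ("poisson", "poisson")):
        cfg = GeneratorConfig(noise=noise, seed=42)
        series, _ = generate_series(cfg)
        path = out / f"series_{label}.csv"
        write_series(series, path)
        written.append(path)
        written.append(path.with_suffix(".json"))
    manifest = out / "MANIFEST.json"
    manifest.write_text(
        json.dumps({"files": [p.name for p in written]}, indent=1) + "\n"
    )
    written.append(manifest)
    return written
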