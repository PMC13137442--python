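"""Named parameter configurations for the simulation studies.

Each preset is a rate configuration under which the model settles into a
particular steady-state regime, named for which compartments survive:

``rumor_free``
    All three reproduction numbers below one; every trajectory returns
    to the rumor-free state (S, N, I, T) = (1, 0, 0, 0).
``infected_endemic``
    Transmitter-free regime: infected users persist, transmitters die out.
``neglected_endemic``
    Rumor-free but neglected users persist (epsilon = 0 here: infected
    users never convert to transmitters).
``transmitter_endemic`` / ``transmitter_neglected``
    Infection-free regimes where transmitters (and possibly neglected
    users) persist.
``coexistence_it`` / ``coexistence_full``
    Infected and transmitter users coexist; in the second, neglected
    users survive as well.

``SWEEPS`` holds the parameter-sweep studies: a base configuration, the
swept rate with its printed range, and the compartment whose peak
density the sweep tracks.

``FIT_TRUTH`` is the rate configuration estimated from a real binned
repost series (Weibo rumor reposts aggregated at 10-minute intervals);
it is the default ground truth for the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SnitrParameters, StateVector

__all__ = ["PRESETS", "SWEEPS", "FIT_TRUTH", "INTERVENTION_BASE",
           "INTERVENTION_INIT", "SweepSpec", "get_preset"]


def _p(alpha1, alpha2, alpha3, mu, beta1, beta2, beta3, epsilon, gamma1, gamma2):
    # argument order follows the printed parameter tables
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SnitrParameters(
            mu=mu,
            alpha1=alpha1,
            alpha2=alpha2,
            alpha3=alpha3,
            beta1=beta1,
            beta2=beta2,
            beta3=beta3,
            gamma1=gamma1,
            gamma2=gamma2,
            epsilon=epsilon,
        )


PRESETS: dict[str, SnitrParameters] = {
    "rumor_free": _p(0.25, 0.35, 0.28, 0.28, 0.30, 0.35, 0.30, 0.30, 0.30, 0.30),
    "infected_endemic": _p(0.20, 0.46, 0.25, 0.18, 0.25, 0.30, 0.15, 0.40, 0.15, 0.05),
    "neglected_endemic": _p(0.60, 0.18, 0.18, 0.18, 0.50, 0.05, 0.15, 0.00, 0.05, 0.15),
    "transmitter_endemic": _p(0.30, 0.25, 0.38, 0.18, 0.30, 0.30, 0.05, 0.20, 0.15, 0.15),
    "transmitter_neglected": _p(0.50, 0.24, 0.24, 0.18, 0.45, 0.20, 0.05, 0.08, 0.05, 0.15),
    "coexistence_it": _p(0.20, 0.36, 0.38, 0.18, 0.20, 0.32, 0.05, 0.08, 0.15, 0.05),
    "coexistence_full": _p(0.46, 0.25, 0.17, 0.18, 0.25, 0.35, 0.05, 0.08, 0.05, 0.05),
}

#: Base configuration for the intervention-timing study: a rumor that
#: genuinely spreads while truth-telling is switched off (alpha1 well
#: above gamma1 + mu) and a transmitter pathway strong enough to
#: suppress it once activated.  Entry-timing runs start with zero
#: transmitter density (see INTERVENTION_INIT).
INTERVENTION_BASE = _p(0.60, 0.25, 0.10, 0.05, 0.30, 0.30, 0.10, 0.10, 0.10, 0.10)

#: Initial state for entry-timing runs: transmitters absent until the
#: intervention seeds them.
INTERVENTION_INIT = StateVector(0.90, 0.04, 0.06, 0.0, 0.0)

#: Rates estimated by least squares from the real repost series
#: (the only data-derived configuration; default synthetic ground truth).
FIT_TRUTH = _p(
    0.3553, 0.1168, 0.4315, 0.001, 0.4772, 0.0700, 0.2351, 0.0951, 0.4984, 0.0023
)


@dataclass(frozen=True)
class SweepSpec:
    """One parameter-sweep study: base rates, swept rate and its range,
    and the compartment whose peak density the sweep monitors."""

    base: SnitrParameters
    name: str
    low: float
    high: float
    compartment: str  # "I" or "T"

    def values(self, n: int = 5) -> np.ndarray:
        return np.linspace(self.low, self.high, n)


SWEEPS: dict[str, SweepSpec] = {
    # peak infected density responds to the infection pathways
    "infected_alpha1": SweepSpec(
        _p(0.45, 0.15, 0.15, 0.18, 0.25, 0.35, 0.05, 0.08, 0.05, 0.05),
        "alpha1", 0.25, 0.65, "I",
    ),
    "infected_beta1": SweepSpec(
        _p(0.55, 0.20, 0.15, 0.18, 0.35, 0.35, 0.05, 0.05, 0.05, 0.05),
        "beta1", 0.15, 0.55, "I",
    ),
    "infected_epsilon": SweepSpec(
        _p(0.55, 0.20, 0.15, 0.18, 0.25, 0.35, 0.05, 0.15, 0.05, 0.05),
        "epsilon", 0.05, 0.25, "I",
    ),
    # peak transmitter density responds to the truth-spreading pathways
    "transmitter_alpha2": SweepSpec(
        _p(0.15, 0.40, 0.15, 0.18, 0.25, 0.35, 0.05, 0.08, 0.05, 0.05),
        "alpha2", 0.20, 0.60, "T",
    ),
    "transmitter_beta2": SweepSpec(
        _p(0.30, 0.66, 0.38, 0.18, 0.20, 0.25, 0.05, 0.08, 0.15, 0.05),
        "beta2", 0.15, 0.35, "T",
    ),
    "transmitter_epsilon": SweepSpec(
        _p(0.70, 0.35, 0.20, 0.18, 0.40, 0.20, 0.15, 0.09, 0.05, 0.05),
        "epsilon", 0.05, 0.13, "T",
    ),
}


def get_preset(name: str) -> SnitrParameters:
    """Look up a preset configuration by name (presets and sweep bases)."""
    if name in PRESETS:
        return PRESETS[name]
    if name in SWEEPS:
        return SWEEPS[name].base
    if name == "fit_truth":
        return FIT_TRUTH
    if name == "intervention":
        return INTERVENTION_BASE
    raise KeyError(
        f"unknown preset {name!r}; available: "
        f"{sorted(PRESETS) + sorted(SWEEPS) + ['fit_truth']}"
    )
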